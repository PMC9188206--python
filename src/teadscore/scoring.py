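"""Per-sample YAP1-TEAD activity scoring: fractional ranks and the deR score.

The score
---------
Within each sample the measured effector genes are ranked (ascending,
ties get the mean of their integer ranks) and the ranks are divided by
the number of measured values, giving *fractional ranks* in (0, 1].
The activity score is

    deR = Rp - Rn

where Rp is the mean fractional rank of the positive effectors and Rn
that of the negative effectors.  deR measures the average separation of
the two effector sets inside one sample: with ranking restricted to the
effector union it lies in [-0.5, +0.5], reaching +0.5 exactly when every
positive effector exceeds every negative effector.  Because it depends
only on within-sample ranks, deR is invariant under any strictly
increasing transform of a sample's abundances — no normalization step
is needed.

Usage follows the statsmodels pattern::

    res = DeRActivity(matrix, signature).fit()
    res.scores                       # per-sample Rp, Rn, deR, coverage
    res.compare_groups(labels, "mutant", "wildtype")
    res.group_summary(labels)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ScoringError, UsageError
from .io import ExpressionMatrix
from .signature import Signature

__all__ = [
    "fractional_ranks",
    "der_score_sample",
    "DeRActivity",
    "DeRActivityResults",
    "der_score_matrix",
    "compare_groups",
    "group_summary",
    "rank_cohorts",
    "GroupComparison",
]


def fractional_ranks(values) -> pd.Series:
    """Fractional ranks of one sample's measured abundances.

    Ascending mean-tie ranks divided by the number of measured values;
    all values lie in (0, 1] and their mean is (N+1)/(2N).  Missing
    (NaN) entries are excluded before ranking.
    """
    s = pd.Series(values, dtype=float)
    s = s.dropna()
    if len(s) < 2:
        raise ScoringError(
            f"fractional ranks need >=2 measured values, got {len(s)}"
        )
    ranks = stats.rankdata(s.to_numpy(), method="average") / len(s)
    return pd.Series(ranks, index=s.index)


def der_score_sample(ranks: pd.Series, sig: Signature):
    """Rp, Rn and deR for one sample from its fractional ranks.

    Rp and Rn are arithmetic means over the *measured* members of each
    set only; a direction with no measured member is a scoring error.
    Returns ``(Rp, Rn, deR, n_pos_used, n_neg_used)``.
    """
    pos = [g for g in ranks.index if g in sig.positive]
    neg = [g for g in ranks.index if g in sig.negative]
    missing = []
    if not pos:
        missing.append(f"no positive effectors measured (need any of "
                       f"{sorted(sig.positive)[:10]})")
    if not neg:
        missing.append(f"no negative effectors measured (need any of "
                       f"{sorted(sig.negative)[:10]})")
    if missing:
        raise ScoringError("; ".join(missing))
    # Fractional ranks are multiples of 1/(2n): recover the exact doubled
    # integer ranks and form deR with one correctly-rounded division, so
    # the +/-0.5 perfect-separation boundary is hit exactly.
    n = len(ranks)
    r2 = np.rint(ranks.to_numpy() * 2 * n)
    idx = {g: i for i, g in enumerate(ranks.index)}
    s_pos = float(sum(r2[idx[g]] for g in pos))
    s_neg = float(sum(r2[idx[g]] for g in neg))
    k_pos, k_neg = len(pos), len(neg)
    rp = s_pos / (2 * n * k_pos)
    rn = s_neg / (2 * n * k_neg)
    der = (s_pos * k_neg - s_neg * k_pos) / (2 * n * k_pos * k_neg)
    return rp, rn, der, k_pos, k_neg


class DeRActivity:
    """deR activity model for a cohort expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Samples x genes abundances; missing values are dropped per sample.
    signature : Signature
    rank_universe : {"effectors", "all-genes"}
        Ranks are computed over the measured effector genes only
        (default — this fixes the deR range at [-0.5, 0.5]) or over all
        measured genes (sensitivity mode).
    min_coverage : float
        Warn when fewer than this fraction of either effector set is
        present in the matrix at all (default 0.5).
    """

    def __init__(self, matrix: ExpressionMatrix, signature: Signature,
                 rank_universe: str = "effectors", min_coverage: float = 0.5):
        if rank_universe not in ("effectors", "all-genes"):
            raise UsageError(f"unknown rank_universe {rank_universe!r}")
        self.matrix = matrix
        self.signature = signature
        self.rank_universe = rank_universe
        self.min_coverage = min_coverage
        genes = set(matrix.gene_ids)
        n_pos = len(signature.positive & genes)
        n_neg = len(signature.negative & genes)
        if n_pos == 0 or n_neg == 0:
            raise UsageError(
                "signature/matrix coverage: an effector direction has zero "
                f"genes in the matrix (positive {n_pos}/{len(signature.positive)}, "
                f"negative {n_neg}/{len(signature.negative)})"
            )
        for label, found, total in (("positive", n_pos, len(signature.positive)),
                                    ("negative", n_neg, len(signature.negative))):
            if found < min_coverage * total:
                warnings.warn(
                    f"only {found}/{total} {label} effectors present in the "
                    f"matrix (coverage floor {min_coverage:.0%})",
                    stacklevel=2)

    def fit(self) -> "DeRActivityResults":
        sig = self.signature
        data = self.matrix.data
        if self.rank_universe == "effectors":
            cols = [g for g in data.columns if g in sig.genes]
            data = data[cols]
        records, errors = [], {}
        values = data.to_numpy(dtype=float)
        col_index = data.columns
        complete = not np.isnan(values).any()
        if complete:
            # fast path: vectorised ranking across the whole cohort
            n = values.shape[1]
            # doubled mean-tie integer ranks are exact integers; a single
            # division keeps the +/-0.5 separation boundary exact
            r2 = stats.rankdata(values, method="average", axis=1) * 2
            pos_mask = np.asarray([g in sig.positive for g in col_index])
            neg_mask = np.asarray([g in sig.negative for g in col_index])
            k_pos, k_neg = int(pos_mask.sum()), int(neg_mask.sum())
            s_pos = r2[:, pos_mask].sum(axis=1)
            s_neg = r2[:, neg_mask].sum(axis=1)
            scores = pd.DataFrame(
                {
                    "n_pos_used": k_pos,
                    "n_neg_used": k_neg,
                    "Rp": s_pos / (2 * n * k_pos),
                    "Rn": s_neg / (2 * n * k_neg),
                    "deR": (s_pos * k_neg - s_neg * k_pos) / (2 * n * k_pos * k_neg),
                },
                index=data.index,
            )
            return DeRActivityResults(self, scores, errors)
        for sample_id, row in data.iterrows():
            try:
                fr = fractional_ranks(row)
                rp, rn, der, np_used, nn_used = der_score_sample(fr, sig)
            except ScoringError as exc:
                errors[sample_id] = str(exc)
                records.append((sample_id, 0, 0, np.nan, np.nan, np.nan))
                continue
            records.append((sample_id, np_used, nn_used, rp, rn, der))
        scores = pd.DataFrame(
            records,
            columns=["sample_id", "n_pos_used", "n_neg_used", "Rp", "Rn", "deR"],
        ).set_index("sample_id")
        return DeRActivityResults(self, scores, errors)


class DeRActivityResults:
    """Per-sample deR scores with group-level summaries and comparisons.

    ``scores`` is a DataFrame indexed by sample id with columns
    ``n_pos_used``, ``n_neg_used``, ``Rp``, ``Rn``, ``deR``; samples
    that could not be scored carry NaN and their reason sits in
    ``errors``.
    """

    def __init__(self, model: DeRActivity, scores: pd.DataFrame, errors: dict):
        self.model = model
        self.scores = scores
        self.errors = errors

    @property
    def deR(self) -> pd.Series:
        return self.scores["deR"]

    def summary(self) -> pd.DataFrame:
        return self.scores.copy()

    def compare_groups(self, labels, group_a, group_b) -> "GroupComparison":
        return compare_groups(self.deR, labels, group_a, group_b)

    def group_summary(self, labels, ci_method: str = "t",
                      n_boot: int = 2000, seed=None) -> pd.DataFrame:
        return group_summary(self.deR, labels, ci_method=ci_method,
                             n_boot=n_boot, seed=seed)

    def rank_cohorts(self, cohort_labels) -> pd.DataFrame:
        return rank_cohorts(self.deR, cohort_labels)

    def plot_groups(self, labels, ax=None):
        """Mean deR per group with 95% confidence-limit error bars."""
        import matplotlib.pyplot as plt

        summ = self.group_summary(labels)
        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(summ))
        yerr = np.vstack([summ["mean"] - summ["ci_low"],
                          summ["ci_high"] - summ["mean"]])
        ax.errorbar(x, summ["mean"], yerr=yerr, fmt="o", capsize=4)
        ax.set_xticks(x, summ["group"])
        ax.set_ylabel("deR")
        return ax


def der_score_matrix(matrix: ExpressionMatrix, sig: Signature,
                     rank_universe: str = "effectors",
                     min_coverage: float = 0.5) -> pd.DataFrame:
    """Functional wrapper: fit :class:`DeRActivity` and return the score table."""
    return DeRActivity(matrix, sig, rank_universe=rank_universe,
                       min_coverage=min_coverage).fit().scores


@dataclass(frozen=True)
class GroupComparison:
    statistic: float          # Mann-Whitney U for group A
    pvalue: float             # two-sided
    median_difference: float  # median(A) - median(B)
    n_a: int
    n_b: int
    method: str


def compare_groups(scores, labels, group_a, group_b) -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum comparison of deR between two groups.

    Exact enumeration is used when both groups have n <= 8 and the pooled
    values carry no ties; otherwise the tie-corrected normal
    approximation.  A rank-based test is the coherent choice for a
    rank-based score.
    """
    scores = pd.Series(scores).dropna()
    labels = pd.Series(labels)
    a = scores[labels.reindex(scores.index) == group_a].to_numpy(dtype=float)
    b = scores[labels.reindex(scores.index) == group_b].to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise UsageError(
            f"both groups need n >= 3 (got {group_a!r}: {len(a)}, "
            f"{group_b!r}: {len(b)})"
        )
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = len(a) <= 8 and len(b) <= 8 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        median_difference=float(np.median(a) - np.median(b)),
        n_a=len(a), n_b=len(b), method=method,
    )


def group_summary(scores, labels, ci_method: str = "t",
                  n_boot: int = 2000, seed=None) -> pd.DataFrame:
    """Per-group n, mean deR, 95% confidence limits and median.

    The default interval is the Student-t CI on the group mean
    (symmetric, matching 95% confidence-limit error bars); a bootstrap
    percentile interval is available with ``ci_method="bootstrap"``.
    Groups of n = 1 report a point estimate with the CI flagged
    undefined (NaN).
    """
    if ci_method not in ("t", "bootstrap"):
        raise UsageError(f"unknown ci_method {ci_method!r}")
    scores = pd.Series(scores).dropna()
    labels = pd.Series(labels).reindex(scores.index)
    rows = []
    rng = np.random.default_rng(seed)
    for group, vals in scores.groupby(labels):
        x = vals.to_numpy(dtype=float)
        n = len(x)
        if n == 0:
            raise UsageError(f"group {group!r} is empty")
        mean = float(x.mean())
        if n == 1:
            lo = hi = np.nan
        elif ci_method == "t":
            sem = x.std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(0.975, df=n - 1)
            lo, hi = mean - tcrit * sem, mean + tcrit * sem
        else:
            means = rng.choice(x, size=(n_boot, n), replace=True).mean(axis=1)
            lo, hi = np.percentile(means, [2.5, 97.5])
        rows.append({"group": group, "n": n, "mean": mean,
                     "ci_low": float(lo), "ci_high": float(hi),
                     "median": float(np.median(x))})
    return pd.DataFrame(rows)


def rank_cohorts(scores, cohort_labels) -> pd.DataFrame:
    """Cohorts ordered by descending mean deR (ties broken by label)."""
    scores = pd.Series(scores).dropna()
    labels = pd.Series(cohort_labels).reindex(scores.index)
    if labels.nunique() < 2:
        raise UsageError("cohort ranking needs >= 2 cohorts")
    agg = scores.groupby(labels).agg(["mean", "median", "count"])
    agg = agg.rename(columns={"count": "n", "mean": "mean_deR",
                              "median": "median_deR"})
    agg = agg.reset_index().rename(columns={agg.index.name or "index": "cohort"})
    agg.columns = ["cohort", "mean_deR", "median_deR", "n"]
    agg = agg.sort_values(["mean_deR", "cohort"],
                          ascending=[False, True], ignore_index=True)
    agg.insert(0, "rank", np.arange(1, len(agg) + 1))
    return agg
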