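"""Derivation of a two-part (positive/negative) effector signature from
oriented perturbation differential-expression experiments.

The model behind the signature: a set of perturbation experiments each
modulates YAP1-TEAD activity in a known direction (knocking out YAP1
decreases it; knocking out an upstream Hippo kinase, or expressing a
constitutively active YAP1, increases it).  A gene whose RNA tracks the
activity should therefore move with the perturbation in a predictable,
orientable direction.  Genes significantly modulated in the expected
direction in enough independent experiments are retained as *positive
effectors* (RNA up when activity is up) or *negative effectors* (RNA
down when activity is up).

The central estimator is :class:`SignatureDerivation`, used like a
statsmodels model::

    res = SignatureDerivation(experiments, alpha=0.01, min_support=2).fit()
    res.signature          # the retained Signature
    res.summary()          # per-gene support table

A functional wrapper :func:`derive_signature` exists for pipeline use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import UsageError, ValidationError

__all__ = [
    "DEExperiment",
    "Signature",
    "SignatureDerivation",
    "SignatureDerivationResults",
    "derive_signature",
    "orient_effects",
]


@dataclass(frozen=True)
class Signature:
    """A two-part effector gene signature.

    Parameters
    ----------
    positive : frozenset of str
        Genes whose RNA level rises with YAP1-TEAD activity.
    negative : frozenset of str
        Genes whose RNA level falls with YAP1-TEAD activity.
    name : str
        Signature label, used as the GMT set-name stem on disk.
    provenance : pandas.DataFrame, optional
        Per-gene support bookkeeping produced by derivation (columns
        ``gene``, ``direction``, ``support``, ``experiments``); ``None``
        for signatures read from file.
    """

    positive: frozenset
    negative: frozenset
    name: str = "signature"
    provenance: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "positive", frozenset(self.positive))
        object.__setattr__(self, "negative", frozenset(self.negative))
        overlap = self.positive & self.negative
        if overlap:
            raise ValidationError(
                f"positive and negative effector sets overlap: {sorted(overlap)}"
            )

    @property
    def genes(self) -> frozenset:
        return self.positive | self.negative

    def __len__(self) -> int:
        return len(self.positive) + len(self.negative)


@dataclass(frozen=True)
class DEExperiment:
    """One perturbation contrast's differential-expression table.

    ``perturbation_sign`` is +1 when the intervention is expected to
    *increase* YAP1-TEAD activity (Hippo-gene KO, constitutively active
    YAP1) and -1 when it is expected to decrease it (YAP1/TAZ/TEAD KO).
    ``table`` has one row per gene with columns ``gene``, ``effect``
    (signed log fold change, perturbed vs control) and ``p``.
    """

    experiment_id: str
    perturbation_sign: int
    table: pd.DataFrame = field(compare=False)
    tissue: str = ""

    def __post_init__(self):
        if self.perturbation_sign not in (+1, -1):
            raise ValidationError(
                f"{self.experiment_id}: perturbation_sign must be +1 or -1, "
                f"got {self.perturbation_sign!r}"
            )
        tbl = self.table
        missing = {"gene", "effect", "p"} - set(tbl.columns)
        if missing:
            raise ValidationError(
                f"{self.experiment_id}: DE table missing columns {sorted(missing)}"
            )
        if tbl["gene"].duplicated().any():
            dups = tbl.loc[tbl["gene"].duplicated(), "gene"].unique()
            raise ValidationError(
                f"{self.experiment_id}: duplicated genes in DE table: {list(dups)[:5]}"
            )
        p = tbl["p"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
            raise ValidationError(
                f"{self.experiment_id}: p-values must lie in [0, 1]"
            )


def orient_effects(exp: DEExperiment) -> pd.DataFrame:
    """Map each gene's raw effect to its orientation with respect to activity.

    A gene is a *candidate positive effector* (oriented direction +1) when
    its expression moved the same way the perturbation moved activity, and
    a candidate negative effector (-1) when it moved opposite; a zero
    effect orients to 0.  Formally ``direction = perturbation_sign *
    sign(effect)``: e.g. in a YAP1 KO (sign -1) a gene that went *down*
    (effect < 0) orients to +1, as positive effectors should fall when
    activity falls.

    Returns a DataFrame with columns ``gene``, ``direction``, ``p``.
    """
    eff = exp.table["effect"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "gene": exp.table["gene"].to_numpy(),
            "direction": exp.perturbation_sign * np.sign(eff).astype(int),
            "p": exp.table["p"].to_numpy(dtype=float),
        }
    )


class SignatureDerivation:
    """Consensus signature estimator over oriented DE experiments.

    A gene is retained as a positive (resp. negative) effector when it is
    significant at ``alpha`` with oriented direction +1 (resp. -1) in at
    least ``min_support`` experiments.  Under the default ``strict``
    conflict policy a single significant observation in the opposite
    direction disqualifies the gene; under ``majority`` it is retained as
    long as concordant significant observations outnumber discordant ones
    (support still >= ``min_support``).

    Parameters
    ----------
    experiments : sequence of DEExperiment
    alpha : float
        Per-experiment significance threshold on the raw p-value
        (default 0.01; no multiplicity adjustment at this step).
    min_support : int
        Minimum number of concordant significant experiments (default 2).
    conflict_policy : {"strict", "majority"}
    """

    def __init__(self, experiments, alpha: float = 0.01, min_support: int = 2,
                 conflict_policy: str = "strict"):
        experiments = list(experiments)
        if not experiments:
            raise UsageError("at least one DEExperiment is required")
        if not (0 < alpha < 1):
            raise UsageError(f"alpha must lie in (0, 1), got {alpha}")
        if min_support < 1:
            raise UsageError(f"min_support must be >= 1, got {min_support}")
        if conflict_policy not in ("strict", "majority"):
            raise UsageError(
                f"conflict_policy must be 'strict' or 'majority', got {conflict_policy!r}"
            )
        ids = [e.experiment_id for e in experiments]
        if len(set(ids)) != len(ids):
            raise ValidationError("experiment_ids must be unique")
        self.experiments = experiments
        self.alpha = alpha
        self.min_support = min_support
        self.conflict_policy = conflict_policy

    def _support_counts(self) -> pd.DataFrame:
        """Per-gene significant-concordant counts in each direction.

        Genes absent from an experiment's table contribute nothing; a zero
        effect counts toward neither direction even when significant.
        """
        rows = {}
        for exp in self.experiments:
            oriented = orient_effects(exp)
            sig = oriented[(oriented["p"] < self.alpha) & (oriented["direction"] != 0)]
            for gene, direction in zip(sig["gene"], sig["direction"]):
                rec = rows.setdefault(gene, {"pos": [], "neg": []})
                rec["pos" if direction > 0 else "neg"].append(exp.experiment_id)
        out = pd.DataFrame(
            [
                {
                    "gene": g,
                    "pos_support": len(r["pos"]),
                    "neg_support": len(r["neg"]),
                    "pos_experiments": tuple(sorted(r["pos"])),
                    "neg_experiments": tuple(sorted(r["neg"])),
                }
                for g, r in rows.items()
            ],
            columns=["gene", "pos_support", "neg_support",
                     "pos_experiments", "neg_experiments"],
        )
        return out.sort_values("gene", ignore_index=True)

    def fit(self, name: str = "signature") -> "SignatureDerivationResults":
        counts = self._support_counts()
        pos, neg = [], []
        for rec in counts.itertuples(index=False):
            if self.conflict_policy == "strict":
                keep_pos = rec.pos_support >= self.min_support and rec.neg_support == 0
                keep_neg = rec.neg_support >= self.min_support and rec.pos_support == 0
            else:  # majority
                keep_pos = (rec.pos_support >= self.min_support
                            and rec.pos_support > rec.neg_support)
                keep_neg = (rec.neg_support >= self.min_support
                            and rec.neg_support > rec.pos_support)
            if keep_pos:
                pos.append(rec.gene)
            elif keep_neg:
                neg.append(rec.gene)
        if not pos and not neg:
            raise UsageError(
                "no effectors retained: no gene reached "
                f"min_support={self.min_support} concordant experiments at "
                f"alpha={self.alpha} under the {self.conflict_policy} policy"
            )
        retained = set(pos) | set(neg)
        prov = counts[counts["gene"].isin(retained)].copy()
        prov["direction"] = np.where(prov["gene"].isin(pos), 1, -1)
        prov["support"] = np.where(prov["direction"] > 0,
                                   prov["pos_support"], prov["neg_support"])
        signature = Signature(frozenset(pos), frozenset(neg), name=name,
                              provenance=prov.reset_index(drop=True))
        return SignatureDerivationResults(self, signature, counts)


class SignatureDerivationResults:
    """Fitted signature plus the full support bookkeeping.

    Attributes
    ----------
    signature : Signature
    counts : pandas.DataFrame
        Support counts for *every* gene significant at least once, not
        only the retained ones (useful for threshold diagnostics).
    """

    def __init__(self, model: SignatureDerivation, signature: Signature,
                 counts: pd.DataFrame):
        self.model = model
        self.signature = signature
        self.counts = counts

    def summary(self) -> pd.DataFrame:
        """Per-retained-gene report: direction, support, supporting experiments."""
        prov = self.signature.provenance
        out = pd.DataFrame(
            {
                "gene": prov["gene"],
                "direction": prov["direction"],
                "support": prov["support"],
                "experiments": [
                    p if d > 0 else n
                    for d, p, n in zip(prov["direction"],
                                       prov["pos_experiments"],
                                       prov["neg_experiments"])
                ],
            }
        )
        return out.sort_values(["direction", "gene"],
                               ascending=[False, True], ignore_index=True)

    @property
    def n_positive(self) -> int:
        return len(self.signature.positive)

    @property
    def n_negative(self) -> int:
        return len(self.signature.negative)


def derive_signature(experiments, alpha: float = 0.01, min_support: int = 2,
                     conflict_policy: str = "strict",
                     name: str = "signature") -> Signature:
    """One-call wrapper: fit :class:`SignatureDerivation` and return the Signature."""
    return SignatureDerivation(
        experiments, alpha=alpha, min_support=min_support,
        conflict_policy=conflict_policy,
    ).fit(name=name).signature
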