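"""Genetic-alteration calling, prevalence, and association with the deR score.

A gene is *altered* in a sample when its thresholded copy-number call is
a deep deletion (-2) or an amplification (+2), or when the sample
carries a non-synonymous mutation in the gene.  Shallow events (+/-1)
never qualify on their own.  Prevalence is reported per gene (fraction
of evaluable samples altered, optionally stratified) and per panel
(fraction of samples with at least one altered panel gene).

:class:`AlterationAssociation` ranks genetic events by how strongly
their carriers' deR activity scores differ from an unaltered reference
group (Mann-Whitney rank-sum per event, Benjamini-Hochberg across
events) — the analysis behind statements like "loss of an upstream
Hippo gene is the best predictor of the activity score".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import UsageError, ValidationError
from .io import MAF_NONSYNONYMOUS, MAF_CLASSES, CopyNumberTable, MutationTable

__all__ = [
    "call_alteration",
    "classify_nonsynonymous",
    "AlterationMatrix",
    "gene_prevalence",
    "panel_prevalence",
    "AlterationAssociation",
    "AssociationResults",
    "rank_predictors",
]


def classify_nonsynonymous(variant_classification: str,
                           dialect: str = "maf") -> bool:
    """True iff the variant class alters the protein product.

    Membership follows the MAF dialect (missense, nonsense, nonstop,
    frameshift, in-frame indel, splice site, translation start site).
    Unknown classes are conservatively treated as not protein-altering,
    with a warning.
    """
    if dialect != "maf":
        raise ValueError(f"unknown dialect {dialect!r}")
    vc = str(variant_classification).strip()
    if vc in MAF_NONSYNONYMOUS:
        return True
    if vc not in MAF_CLASSES:
        warnings.warn(
            f"unknown variant classification {vc!r}: treated as not "
            "non-synonymous", stacklevel=2)
    return False


def call_alteration(cn, mutated_nonsyn: bool) -> bool:
    """Altered iff deep deletion (cn = -2), amplification (cn = +2), or a
    non-synonymous mutation.  ``cn`` may be None/NaN (missing)."""
    if cn is None or (isinstance(cn, float) and np.isnan(cn)):
        return bool(mutated_nonsyn)
    if cn not in (-2, -1, 0, 1, 2):
        raise ValidationError(f"copy-number value {cn!r} outside {{-2..+2}}")
    return cn in (-2, 2) or bool(mutated_nonsyn)


class AlterationMatrix:
    """Joint per-sample, per-gene alteration state.

    Built from a thresholded copy-number table and/or a mutation table;
    holds three aligned samples x genes frames:

    ``cn``         float with NaN for missing calls,
    ``mutated``    bool, sample carries >=1 non-synonymous mutation,
    ``altered``    bool, the derived alteration call,
    ``evaluable``  bool, cn present OR the sample is mutation-profiled.

    Samples that appear in the mutation table's coverage but have no row
    for a gene count as wildtype for that gene, not as unprofiled.
    """

    def __init__(self, cn: CopyNumberTable | None = None,
                 mutations: MutationTable | None = None,
                 samples=None, genes=None):
        if cn is None and mutations is None:
            raise UsageError("need a copy-number table, a mutation table, or both")
        sample_ids = list(samples) if samples is not None else None
        gene_ids = list(genes) if genes is not None else None
        if sample_ids is None:
            ids = []
            if cn is not None:
                ids += cn.sample_ids
            if mutations is not None:
                ids += sorted(mutations.samples)
            sample_ids = list(dict.fromkeys(ids))
        if gene_ids is None:
            ids = []
            if cn is not None:
                ids += cn.gene_ids
            if mutations is not None:
                ids += sorted(set(mutations.rows["gene_symbol"]))
            gene_ids = list(dict.fromkeys(ids))

        self.cn = pd.DataFrame(np.nan, index=sample_ids, columns=gene_ids)
        if cn is not None:
            common_s = [s for s in sample_ids if s in cn.data.index]
            common_g = [g for g in gene_ids if g in cn.data.columns]
            self.cn.loc[common_s, common_g] = cn.data.loc[common_s, common_g]

        self.mutated = pd.DataFrame(False, index=sample_ids, columns=gene_ids)
        mut_profiled = frozenset()
        if mutations is not None:
            mut_profiled = mutations.samples
            rows = mutations.rows
            nonsyn = rows["variant_classification"].map(
                lambda v: v in MAF_NONSYNONYMOUS)
            for s, g in zip(rows.loc[nonsyn, "sample_id"],
                            rows.loc[nonsyn, "gene_symbol"]):
                if s in self.mutated.index and g in self.mutated.columns:
                    self.mutated.loc[s, g] = True
        self.mutation_profiled = mut_profiled

        cn_vals = self.cn.to_numpy()
        self.altered = pd.DataFrame(
            np.isin(cn_vals, (-2.0, 2.0)) | self.mutated.to_numpy(),
            index=sample_ids, columns=gene_ids)
        prof = np.asarray([s in mut_profiled for s in sample_ids])[:, None]
        self.evaluable = pd.DataFrame(
            np.isfinite(cn_vals) | prof, index=sample_ids, columns=gene_ids)

    @property
    def sample_ids(self) -> list:
        return list(self.cn.index)

    @property
    def gene_ids(self) -> list:
        return list(self.cn.columns)


def gene_prevalence(alt: AlterationMatrix, strata=None) -> pd.DataFrame:
    """Per-gene alteration prevalence over evaluable samples.

    Returns a long-format table with one row per gene per stratum (a
    synthetic stratum ``"all"`` always included) carrying the exact
    counts alongside the fraction.
    """
    frames = []
    groups = {"all": pd.Series(True, index=alt.cn.index)}
    if strata is not None:
        strata = pd.Series(strata).reindex(alt.cn.index)
        for g, members in strata.groupby(strata):
            groups[g] = pd.Series(alt.cn.index.isin(members.index),
                                  index=alt.cn.index)
    for name, mask in groups.items():
        ev = alt.evaluable.loc[mask.to_numpy()]
        al = alt.altered.loc[mask.to_numpy()] & ev
        n_alt = al.sum(axis=0)
        n_ev = ev.sum(axis=0)
        with np.errstate(invalid="ignore"):
            frac = n_alt / n_ev.replace(0, np.nan)
        frames.append(pd.DataFrame({
            "gene": alt.gene_ids, "stratum": name,
            "n_altered": n_alt.to_numpy(dtype=int),
            "n_evaluable": n_ev.to_numpy(dtype=int),
            "prevalence": frac.to_numpy(dtype=float),
        }))
    return pd.concat(frames, ignore_index=True)


def panel_prevalence(alt: AlterationMatrix, panel) -> float:
    """Fraction of samples with >=1 alteration in any panel gene."""
    panel = list(panel)
    missing = [g for g in panel if g not in alt.altered.columns]
    if missing:
        raise UsageError(f"panel genes absent from the matrix: {missing}")
    hit = (alt.altered[panel] & alt.evaluable[panel]).any(axis=1)
    return float(hit.mean())


def _event_mask(alt: AlterationMatrix, gene: str, event_type: str) -> pd.Series:
    cn = alt.cn[gene]
    mut = alt.mutated[gene]
    if event_type == "any":
        return cn.isin([-2.0, 2.0]) | mut
    if event_type == "deletion":
        return (cn == -2.0) | mut
    if event_type == "amplification":
        return (cn == 2.0) | mut
    raise UsageError(f"unknown event_type {event_type!r}")


class AlterationAssociation:
    """Rank genetic events by association with the deR activity score.

    For each tested gene, carriers of the event are compared with an
    unaltered reference group by a two-sided Mann-Whitney test on deR.
    Under the default ``strict`` reference policy the reference is
    copy-number exactly 0 *and* no non-synonymous mutation, and samples
    with shallow events (cn +/-1) are excluded from the comparison
    altogether ("diploid, wildtype" reference); the ``inclusive`` policy
    uses every not-altered sample instead.

    ``event_type`` controls what counts as the event: ``"any"``
    (cn +/-2 or mutation, the general alteration call), ``"deletion"``
    (cn -2 or mutation — the natural definition for a tumor-suppressor
    "mutation or deletion" event) or ``"amplification"``; pass a dict
    ``{gene: type}`` to vary it per event.
    """

    def __init__(self, alterations: AlterationMatrix, scores, events,
                 reference_policy: str = "strict",
                 event_type="any", min_group: int = 3):
        if reference_policy not in ("strict", "inclusive"):
            raise UsageError(f"unknown reference_policy {reference_policy!r}")
        self.alterations = alterations
        self.scores = pd.Series(scores).dropna()
        self.events = list(events)
        self.reference_policy = reference_policy
        self.event_type = event_type
        self.min_group = min_group
        missing = [g for g in self.events
                   if g not in alterations.altered.columns]
        if missing:
            raise UsageError(f"event genes absent from alterations: {missing}")

    def _type_for(self, gene: str) -> str:
        if isinstance(self.event_type, dict):
            return self.event_type.get(gene, "any")
        return self.event_type

    def fit(self) -> "AssociationResults":
        shared = [s for s in self.alterations.sample_ids
                  if s in self.scores.index]
        rows, skipped = [], {}
        for gene in self.events:
            ev = _event_mask(self.alterations, gene,
                             self._type_for(gene)).reindex(shared)
            cn = self.alterations.cn[gene].reindex(shared)
            mut = self.alterations.mutated[gene].reindex(shared)
            if self.reference_policy == "strict":
                ref = (cn == 0.0) & ~mut
            else:
                ref = ~ev & self.alterations.evaluable[gene].reindex(shared)
            altered_scores = self.scores.loc[[s for s in shared if ev[s]]]
            ref_scores = self.scores.loc[[s for s in shared if ref[s] and not ev[s]]]
            if len(altered_scores) < self.min_group:
                skipped[gene] = (f"only {len(altered_scores)} altered samples "
                                 f"(need {self.min_group})")
                continue
            if len(ref_scores) < self.min_group:
                reason = ("no reference group" if len(ref_scores) == 0 else
                          f"only {len(ref_scores)} reference samples "
                          f"(need {self.min_group})")
                skipped[gene] = reason
                continue
            res = stats.mannwhitneyu(altered_scores, ref_scores,
                                     alternative="two-sided")
            rows.append({
                "gene": gene,
                "n_altered": len(altered_scores),
                "n_reference": len(ref_scores),
                "median_difference": float(np.median(altered_scores)
                                           - np.median(ref_scores)),
                "pvalue": float(res.pvalue),
            })
        if not rows:
            raise UsageError(
                "no event testable: " + "; ".join(
                    f"{g}: {r}" for g, r in skipped.items()))
        table = pd.DataFrame(rows)
        table["qvalue"] = multipletests(table["pvalue"], method="fdr_bh")[1]
        order = table.sort_values(
            by=["pvalue", "median_difference", "gene"],
            key=lambda c: -c.abs() if c.name == "median_difference" else c,
            ignore_index=True)
        order.insert(0, "rank", np.arange(1, len(order) + 1))
        return AssociationResults(self, order, skipped)


class AssociationResults:
    """Ranked association table plus skip bookkeeping.

    ``table`` columns: rank, gene, n_altered, n_reference,
    median_difference, pvalue, qvalue — ordered by ascending p, ties by
    descending \\|median difference\\|, then gene name.
    """

    def __init__(self, model: AlterationAssociation, table: pd.DataFrame,
                 skipped: dict):
        self.model = model
        self.table = table
        self.skipped = skipped

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    @property
    def best_predictor(self) -> str:
        return str(self.table.iloc[0]["gene"])


def rank_predictors(alterations: AlterationMatrix, scores, events,
                    reference_policy: str = "strict",
                    event_type="any", min_group: int = 3) -> AssociationResults:
    """Functional wrapper around :class:`AlterationAssociation`."""
    return AlterationAssociation(
        alterations, scores, events, reference_policy=reference_policy,
        event_type=event_type, min_group=min_group,
    ).fit()
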