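"""Synthetic cohorts, perturbation experiments and alteration tables.

These generators produce every input the pipeline consumes, with the
statistical structure its analyses assume, so the whole chain
(derive -> score -> compare -> associate) is testable without any
external download:

* :func:`simulate_cohort` — a samples x genes expression matrix driven
  by a latent per-sample activity level: each effector gene's abundance
  is shifted by ``effect_size`` within-gene SD units per activity unit
  (positive effectors up, negative effectors down) on top of gene
  baselines and Gaussian noise.
* :func:`simulate_experiments` — oriented perturbation DE tables with
  planted positive/negative effectors: planted genes get large,
  orientation-consistent signed effects and small p-values, null genes
  get centred effects and Uniform(0,1) p-values.
* :func:`simulate_alterations` — per-gene Bernoulli deep-deletion /
  amplification / mutation events; genes listed in ``coupling`` shift
  the latent activity of their carriers by a stated amount *before*
  expression is generated (use :func:`simulate_altered_cohort` for the
  enforced order).

All generators are pure functions of (config, seed): repeat runs are
bit-identical.  The latent activity lives on a standard-normal scale
and effect sizes are in within-gene SD units, which keeps recovery
thresholds unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._errors import UsageError
from .io import CopyNumberTable, ExpressionMatrix, MutationTable
from .signature import DEExperiment, Signature

__all__ = [
    "CohortSimConfig",
    "ExperimentSimConfig",
    "AlterationSimConfig",
    "CohortSim",
    "ExperimentSim",
    "AlterationSim",
    "AlteredCohortSim",
    "simulate_cohort",
    "simulate_experiments",
    "simulate_alterations",
    "simulate_altered_cohort",
]


@dataclass(frozen=True)
class CohortSimConfig:
    """Expression-cohort generator settings.

    ``effect_size`` is the per-unit-activity shift of each effector
    gene's mean, in units of the within-gene noise SD (positive
    effectors shift up, negative effectors down).
    """

    n_samples: int = 200
    n_genes: int = 1000
    n_pos_effectors: int = 50
    n_neg_effectors: int = 50
    activity_mean: float = 0.0
    activity_sd: float = 1.0
    effect_size: float = 1.0
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0

    def __post_init__(self):
        if self.n_pos_effectors + self.n_neg_effectors > self.n_genes:
            raise UsageError("effector counts exceed n_genes")
        if self.n_pos_effectors < 1 or self.n_neg_effectors < 1:
            raise UsageError("need >=1 effector in each direction")
        if self.activity_sd <= 0 or self.noise_sd <= 0:
            raise UsageError("activity_sd and noise_sd must be positive")
        if self.n_samples < 1:
            raise UsageError("n_samples must be >= 1")


@dataclass(frozen=True)
class ExperimentSimConfig:
    """Perturbation-experiment generator settings.

    ``perturbation_signs`` defaults to half activity-decreasing (-1) and
    half activity-increasing (+1) experiments.  ``planted_p`` is the
    p-value model for planted effectors: ``("beta", a, b)`` draws
    Beta(a, b) (default (0.5, 20) — small but with a realistic tail) or
    ``("uniform", lo, hi)`` for uniformly tiny p-values (strong
    planting).  Null genes always draw Uniform(0, 1).
    """

    n_experiments: int = 6
    perturbation_signs: tuple = None
    n_genes: int = 1000
    n_pos_effectors: int = 50
    n_neg_effectors: int = 50
    effect_magnitude: float = 2.5
    effect_sd: float = 0.5
    null_effect_sd: float = 0.3
    planted_p: tuple = ("beta", 0.5, 20.0)

    def __post_init__(self):
        if self.n_experiments < 1:
            raise UsageError("need >= 1 experiment")
        signs = self.perturbation_signs
        if signs is None:
            half = self.n_experiments // 2
            signs = (-1,) * (self.n_experiments - half) + (+1,) * half
        signs = tuple(int(s) for s in signs)
        if len(signs) != self.n_experiments or any(s not in (-1, 1) for s in signs):
            raise UsageError(
                "perturbation_signs must give one sign in {-1,+1} per experiment")
        object.__setattr__(self, "perturbation_signs", signs)
        if self.n_pos_effectors + self.n_neg_effectors > self.n_genes:
            raise UsageError("effector counts exceed n_genes")
        if self.planted_p[0] not in ("beta", "uniform"):
            raise UsageError(f"unknown planted_p model {self.planted_p[0]!r}")


@dataclass(frozen=True)
class AlterationSimConfig:
    """Alteration generator settings.

    ``gene_probs`` maps gene -> (p_deep_deletion, p_amplification,
    p_nonsyn_mutation); ``coupling`` maps gene -> latent-activity shift
    applied to carriers of any alteration in that gene (e.g. an
    NF2-like tumor suppressor: deletion/mutation raises YAP1-TEAD
    activity, shift +1.5 SD).  ``shallow_prob`` is the chance of a
    shallow (+/-1) call when no deep event occurred.
    """

    gene_probs: dict = field(default_factory=dict)
    coupling: dict = field(default_factory=dict)
    shallow_prob: float = 0.0

    def __post_init__(self):
        for g, probs in self.gene_probs.items():
            if len(probs) != 3 or any(not (0 <= p <= 1) for p in probs):
                raise UsageError(
                    f"gene {g!r}: probabilities must be a (del, amp, mut) "
                    "triple in [0, 1]")
        unknown = set(self.coupling) - set(self.gene_probs)
        if unknown:
            raise UsageError(
                f"coupling references genes without probabilities: {sorted(unknown)}")
        if not (0 <= self.shallow_prob <= 1):
            raise UsageError("shallow_prob must lie in [0, 1]")


class CohortSim(NamedTuple):
    expression: ExpressionMatrix
    activity: pd.Series          # ground-truth latent activity per sample
    signature: Signature         # planted effector sets


class ExperimentSim(NamedTuple):
    experiments: list            # list of DEExperiment
    signature: Signature         # planted ground truth


class AlterationSim(NamedTuple):
    copy_number: CopyNumberTable
    mutations: MutationTable
    activity: pd.Series          # latent activity after coupling shifts
    events: pd.DataFrame         # samples x genes bool, ground-truth carriers


def _gene_names(cfg) -> tuple:
    pos = [f"POS{i + 1:04d}" for i in range(cfg.n_pos_effectors)]
    neg = [f"NEG{i + 1:04d}" for i in range(cfg.n_neg_effectors)]
    null = [f"G{i + 1:05d}" for i in
            range(cfg.n_genes - cfg.n_pos_effectors - cfg.n_neg_effectors)]
    return pos, neg, null


def simulate_cohort(cfg: CohortSimConfig, seed, activity=None) -> CohortSim:
    """Generate an expression cohort driven by latent activity.

    ``expression[s, g] = baseline_g + direction_g * effect_size *
    activity_s + N(0, noise_sd)``, with direction +1/-1/0 for
    positive/negative/null genes.  Pass ``activity`` (array of length
    ``n_samples``) to override the latent draw — used when alteration
    events have already shifted activity.
    """
    rng = np.random.default_rng(seed)
    pos, neg, null = _gene_names(cfg)
    genes = pos + neg + null
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    if activity is None:
        act = rng.normal(cfg.activity_mean, cfg.activity_sd, size=cfg.n_samples)
    else:
        act = np.asarray(activity, dtype=float)
        if act.shape != (cfg.n_samples,):
            raise UsageError(
                f"activity override must have length {cfg.n_samples}")
    direction = np.concatenate([
        np.ones(len(pos)), -np.ones(len(neg)), np.zeros(len(null))])
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_samples, len(genes)))
    values = (baseline[None, :]
              + cfg.effect_size * cfg.noise_sd * act[:, None] * direction[None, :]
              + noise)
    expr = ExpressionMatrix(pd.DataFrame(values, index=samples, columns=genes))
    sig = Signature(frozenset(pos), frozenset(neg), name="planted")
    return CohortSim(expr, pd.Series(act, index=samples, name="activity"), sig)


def _planted_p(rng, model, size):
    if model[0] == "beta":
        return rng.beta(model[1], model[2], size=size)
    lo, hi = model[1], model[2]
    return rng.uniform(lo, hi, size=size)


def simulate_experiments(cfg: ExperimentSimConfig, seed) -> ExperimentSim:
    """Generate oriented perturbation DE tables with planted effectors.

    In an experiment with perturbation sign ``s``, a planted effector of
    direction ``d`` receives effect ``s * d * (magnitude + |N(0,
    effect_sd)|)`` — always orientation-consistent — and a p-value from
    the planted model; null genes receive N(0, null_effect_sd) effects
    and Uniform(0, 1) p-values.
    """
    rng = np.random.default_rng(seed)
    pos, neg, null = _gene_names(cfg)
    genes = np.asarray(pos + neg + null)
    direction = np.concatenate([
        np.ones(len(pos)), -np.ones(len(neg)), np.zeros(len(null))])
    planted = direction != 0
    experiments = []
    for i, sign in enumerate(cfg.perturbation_signs):
        effect = rng.normal(0.0, cfg.null_effect_sd, size=len(genes))
        mag = cfg.effect_magnitude + np.abs(
            rng.normal(0.0, cfg.effect_sd, size=planted.sum()))
        effect[planted] = sign * direction[planted] * mag
        p = rng.uniform(0.0, 1.0, size=len(genes))
        p[planted] = _planted_p(rng, cfg.planted_p, planted.sum())
        label = "KO" if sign < 0 else "activation"
        experiments.append(DEExperiment(
            experiment_id=f"EXP{i + 1:02d}_{label}",
            perturbation_sign=sign,
            table=pd.DataFrame({"gene": genes, "effect": effect, "p": p}),
        ))
    sig = Signature(frozenset(pos), frozenset(neg), name="planted")
    return ExperimentSim(experiments, sig)


def simulate_alterations(cfg: AlterationSimConfig, base_activity: pd.Series,
                         seed) -> AlterationSim:
    """Draw per-sample alteration events and apply activity coupling.

    Events are independent Bernoulli draws per gene (deep deletion,
    amplification, non-synonymous mutation; mutually compatible).
    Carriers of a coupled gene's alteration get that gene's stated
    shift added to their latent activity; the returned ``activity`` must
    be fed back into :func:`simulate_cohort` so expression reflects the
    shifted activity (see :func:`simulate_altered_cohort`).
    """
    rng = np.random.default_rng(seed)
    samples = list(base_activity.index)
    genes = list(cfg.gene_probs)
    n = len(samples)
    cn = pd.DataFrame(0.0, index=samples, columns=genes)
    mut_rows = []
    events = pd.DataFrame(False, index=samples, columns=genes)
    for g in genes:
        p_del, p_amp, p_mut = cfg.gene_probs[g]
        u = rng.uniform(size=n)
        deep_del = u < p_del
        amp = (u >= p_del) & (u < p_del + p_amp)
        mutated = rng.uniform(size=n) < p_mut
        col = np.zeros(n)
        col[deep_del] = -2.0
        col[amp] = 2.0
        if cfg.shallow_prob > 0:
            shallow = (~deep_del & ~amp
                       & (rng.uniform(size=n) < cfg.shallow_prob))
            col[shallow] = rng.choice([-1.0, 1.0], size=int(shallow.sum()))
        cn[g] = col
        events[g] = deep_del | amp | mutated
        for s in np.asarray(samples)[mutated]:
            mut_rows.append((s, g, "Missense_Mutation"))
    activity = base_activity.astype(float).copy()
    for g, shift in cfg.coupling.items():
        activity[events[g].to_numpy()] += shift
    mutations = MutationTable(
        pd.DataFrame(mut_rows, columns=["sample_id", "gene_symbol",
                                        "variant_classification"]),
        samples=frozenset(samples))
    return AlterationSim(CopyNumberTable(cn), mutations, activity, events)


class AlteredCohortSim(NamedTuple):
    expression: ExpressionMatrix
    activity: pd.Series
    signature: Signature
    copy_number: CopyNumberTable
    mutations: MutationTable
    events: pd.DataFrame


def simulate_altered_cohort(cohort_cfg: CohortSimConfig,
                            alt_cfg: AlterationSimConfig,
                            seed) -> AlteredCohortSim:
    """Full multi-omic cohort with the pipeline order enforced.

    Draw base latent activity, draw alteration events, apply coupling
    shifts to activity, *then* generate expression from the shifted
    activity.  Sub-streams are spawned from ``seed`` so the three draws
    are independent but jointly reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_act, s_alt, s_expr = ss.spawn(3)
    rng = np.random.default_rng(s_act)
    base = pd.Series(
        rng.normal(cohort_cfg.activity_mean, cohort_cfg.activity_sd,
                   size=cohort_cfg.n_samples),
        index=[f"S{i + 1:04d}" for i in range(cohort_cfg.n_samples)],
        name="activity")
    alt = simulate_alterations(alt_cfg, base, s_alt)
    cohort = simulate_cohort(cohort_cfg, s_expr, activity=alt.activity.to_numpy())
    return AlteredCohortSim(cohort.expression, alt.activity, cohort.signature,
                            alt.copy_number, alt.mutations, alt.events)
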