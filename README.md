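# teadscore

Rank-based scoring of YAP1-TEAD transcriptional activity from bulk
expression data, with the surrounding analysis pipeline: consensus
derivation of the effector signature from perturbation experiments,
genetic-alteration prevalence in tumor cohorts, genotype–score
association ranking, and the exact arithmetic of xenograft efficacy and
qPCR readouts.

## Who this is for

The Hippo pathway (NF2 → LATS1/2) normally restrains the transcriptional
co-activators YAP1/TAZ; when Hippo regulators are lost — as in most
malignant pleural mesothelioma (MPM) tumors — nuclear YAP1 binds the
TEAD transcription factors and drives a proliferative program. Groups
studying Hippo-driven cancers need a *per-sample* readout of YAP1-TEAD
activity that works across platforms and normalizations, both to
stratify tumor cohorts by genotype and to track pharmacodynamic response
to TEAD inhibitors. `teadscore` provides that readout and the analyses
built on it, plus a simulator that generates every input with known
ground truth so the whole chain is testable offline.

## The statistic

Let *P* and *N* be disjoint sets of **positive** and **negative effector
genes** — genes whose RNA level rises, respectively falls, with
YAP1-TEAD activity. Within one sample, the measured effector genes are
converted to **fractional ranks**: ascending ranks with mean-tie
resolution, divided by the number of measured values, so each rank lies
in (0, 1]. The activity score is the **difference of effector ranks**

        deR = R_p − R_n

where R_p is the mean fractional rank over *P* and R_n over *N*. With
ranking restricted to the effector union, deR ∈ [−0.5, +0.5], reaching
+0.5 exactly when every positive effector exceeds every negative
effector. Because deR depends only on within-sample ranks it is
invariant under any strictly increasing transform of a sample's
abundances — no cross-sample normalization is required.

The signature itself is derived from oriented perturbation experiments
(YAP1/TAZ/TEAD knockouts decrease activity; Hippo-gene knockouts and
constitutively active YAP1 increase it): a gene is retained as an
effector when it is significantly modulated (p < 0.01) in the expected
direction in at least 2 experiments, with a strict policy that discards
genes showing any significant discordant observation.

Downstream, a sample is called **genetically altered** in a gene when
its GISTIC-thresholded copy number is −2 (deep deletion) or +2
(amplification) or it carries a non-synonymous mutation; events are
ranked as predictors of deR by per-event Mann-Whitney tests against a
diploid-wildtype reference with Benjamini-Hochberg adjustment.

## Worked example

```python
import numpy as np
from scipy import stats
from teadscore import (AlterationMatrix, AlterationSimConfig, CohortSimConfig,
                       DeRActivity, ExperimentSimConfig, derive_signature,
                       rank_predictors, simulate_altered_cohort,
                       simulate_experiments)

# 1. derive a signature from six oriented perturbation experiments
exp_sim = simulate_experiments(
    ExperimentSimConfig(n_experiments=6, n_genes=1000,
                        n_pos_effectors=50, n_neg_effectors=50,
                        planted_p=("uniform", 0.0, 1e-4)),
    seed=1)
sig = derive_signature(exp_sim.experiments, alpha=0.01, min_support=2)
print(f"signature: {len(sig.positive)} positive, {len(sig.negative)} negative effectors")

# 2. score a simulated tumor cohort whose NF2 alterations raise activity
cohort_cfg = CohortSimConfig(n_samples=200, n_genes=120,
                             n_pos_effectors=40, n_neg_effectors=40)
alt_cfg = AlterationSimConfig(
    gene_probs={"NF2": (0.2, 0.0, 0.125),
                **{f"NULL{i:02d}": (0.08, 0.04, 0.08) for i in range(19)}},
    coupling={"NF2": 1.5})
sim = simulate_altered_cohort(cohort_cfg, alt_cfg, seed=2)
res = DeRActivity(sim.expression, sim.signature).fit()
rho = stats.spearmanr(res.deR, sim.activity).statistic
print(f"deR range: [{res.deR.min():+.3f}, {res.deR.max():+.3f}], "
      f"Spearman vs latent activity: {rho:.3f}")

# 3. compare carriers of an NF2 deletion/mutation with wildtype
labels = np.where(sim.events["NF2"], "NF2_altered", "NF2_wt")
cmp = res.compare_groups(dict(zip(res.scores.index, labels)),
                         "NF2_altered", "NF2_wt")
print(f"NF2 altered vs wildtype: U={cmp.statistic:.0f}, p={cmp.pvalue:.2e}, "
      f"median deR difference {cmp.median_difference:+.3f}")

# 4. rank all 20 genetic events as predictors of the score
alt = AlterationMatrix(sim.copy_number, sim.mutations)
ranking = rank_predictors(alt, res.deR, list(alt_cfg.gene_probs))
print(ranking.table.head(3).to_string(index=False))
```

prints

```
signature: 50 positive, 51 negative effectors
deR range: [-0.430, +0.499], Spearman vs latent activity: 0.993
NF2 altered vs wildtype: U=6676, p=1.41e-14, median deR difference +0.321
 rank   gene  n_altered  n_reference  median_difference       pvalue       qvalue
    1    NF2         53          147           0.320625 1.407981e-14 2.815963e-13
    2 NULL08         34          166          -0.080937 1.158276e-01 8.457166e-01
    3 NULL00         48          152           0.069687 1.815854e-01 8.457166e-01
```

Reading the output: derivation recovered the planted 50+50 effector sets
(one extra false positive), the per-sample deR scores stay inside the
theoretical [−0.5, 0.5] band and track the latent activity almost
perfectly, carriers of the activity-coupled NF2 event score about 0.32
deR units above wildtype samples, and the association ranking places NF2
first among the twenty tested events by a wide margin — the nineteen
uncoupled events are statistically quiet after multiple-testing
adjustment.

The same pipeline runs from the shell: `teadscore simulate | derive |
score | compare | prevalence | associate | metrics` (see
`teadscore --help`).

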