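# Methods

This note documents the models and procedures `teadscore` implements,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic cohorts do and do not establish about real data.

## The deR activity score

Given a two-part signature — positive effectors *P* (RNA up with
YAP1-TEAD activity) and negative effectors *N* (RNA down) — each
sample's measured effector abundances are transformed to fractional
ranks: ascending ranks with ties assigned the mean of their integer
ranks, divided by the number of measured values. The score is
deR = R_p − R_n, the difference of the mean fractional ranks of the two
sets. Its assumptions are deliberately weak: abundances need only be
*comparable within a sample* on a monotone scale, so counts, TPM and
array intensities all work, and no cross-sample normalization is
needed. What deR measures is a transcriptional correlate of YAP1-TEAD
activity, not YAP1 protein state.

**Rank universe.** By default ranks are computed over the measured
effector genes only, which fixes the range at [−0.5, +0.5] with the
extremes attained exactly at perfect separation of the two sets. An
`all-genes` universe is available for sensitivity analysis; it widens
neither interpretability nor power in our simulations and is not the
default.

**Numerical exactness.** Fractional ranks are multiples of 1/(2n), so
deR is computed from the exact doubled integer rank sums with a single
final division. This makes the ±0.5 boundary, the antisymmetry under
swapping *P* and *N*, and invariance under monotone transforms exact in
floating point, not merely approximate — the property tests assert
equality, not closeness.

**Missing data.** Missing values are dropped per sample before ranking;
`n_pos_used`/`n_neg_used` are reported per sample so coverage is
auditable. A sample in which either direction has no measured member is
unscorable: it is reported with a reason rather than silently dropped,
and matrix-level scoring continues for the remaining samples. A
signature direction with under half its genes present in the matrix
triggers a warning. Ties are exact-value ties only (no epsilon
snapping); input that was rounded upstream will therefore tie, which is
the intended behavior.

## Signature derivation

Each perturbation experiment carries an orientation: −1 when the
intervention should lower YAP1-TEAD activity (YAP1/TAZ/TEAD knockout),
+1 when it should raise it (Hippo-gene knockout, constitutively active
YAP1). A gene's oriented direction in an experiment is
`perturbation_sign × sign(logFC)`; zero effects orient to neither
direction even when nominally significant. A gene is retained as a
positive (negative) effector when it is significant at `alpha = 0.01`
(raw p-values — no multiplicity adjustment at this step, by design)
with oriented direction +1 (−1) in at least `min_support = 2`
experiments.

**Conflict policy.** "Consistently modulated" is read strictly by
default: one significant discordant observation disqualifies a gene. A
`majority` policy (concordant > discordant, support still ≥
min_support) is provided because strictness is a judgement call on
heterogeneous public experiments. Note a consequence: under the strict
policy, *raising* alpha can disqualify a previously retained gene by
promoting a discordant observation to significance, so
retention is monotone in the thresholds only on conflict-free inputs —
the property test states it in that form.

**Experiment granularity.** The unit of support is the `DEExperiment`
the caller supplies. A study series that perturbs several genes can be
entered as one contrast or several; the derivation does not second-guess
that choice, it only requires unique experiment ids. Genes absent from
an experiment's table contribute neither support nor conflict. An empty
result (no gene retained in either direction) raises an explicit
error — a silent empty signature would propagate confusingly far.

## Group statistics

Group comparisons of deR use the two-sided Mann-Whitney rank-sum test —
a rank-based test is the coherent companion to a rank-based score —
with exact enumeration when both groups have n ≤ 8 and the pooled
scores are tie-free, and the tie-corrected normal approximation
otherwise. Group summaries report mean, median and a Student-t 95%
confidence interval on the mean (symmetric limits; a bootstrap
percentile interval is available by flag; n = 1 groups flag their CI as
undefined rather than fabricating one). Cohort ranking orders groups by
mean deR, breaking ties lexicographically so output is deterministic.

## Alteration calling and association

A sample is altered in a gene iff its thresholded copy-number call is
−2 or +2, or it carries a non-synonymous mutation. The non-synonymous
MAF classes are: Missense_Mutation, Nonsense_Mutation,
Nonstop_Mutation, Frame_Shift_Del, Frame_Shift_Ins, In_Frame_Del,
In_Frame_Ins, Splice_Site, Translation_Start_Site; anything else —
including unknown strings, which additionally warn — is treated as not
protein-altering. Shallow events (±1) never qualify on their own.
Evaluability: a sample counts in a gene's denominator when it has a
copy-number call or is covered by mutation profiling; with both absent
it is excluded. When a mutation table is supplied, its `samples` set
declares profiling coverage (defaulting to the samples with rows), so a
profiled sample without mutations is wildtype, not missing.

Association ranking tests each event's carriers against a reference by
Mann-Whitney on deR, adjusts across events with Benjamini-Hochberg, and
ranks by ascending p, then descending |median difference|, then gene
name. The default `strict` reference is "diploid, wildtype": copy
number exactly 0 and no non-synonymous mutation, with shallow-event
samples excluded from the comparison entirely; an `inclusive` policy
(reference = all not-altered) trades purity for power. The event
definition is configurable per gene (`any`, `deletion` = cn −2 or
mutation, `amplification`), since "mutation or deletion" is the natural
event for a tumor suppressor while amplification is for an oncogene.
Events with fewer than 3 carriers or 3 reference samples are skipped
with a recorded reason.

## Study arithmetic

Tumor volume from caliper diameters is V = d²·D/2 (mm³) with d ≤ D
enforced. TGI is defined here as 100·(1 − mean treated Δvolume / mean
control Δvolume) on changes from baseline (an endpoint-volume variant is
available by flag); it is undefined when the control group itself
regressed. Regression is per-animal, 100·(baseline − current)/baseline,
summarized by the group median; growth appears as negative regression.
qPCR quantification follows the comparative-Ct method:
RQ = 2^(−ΔΔCt) with ΔCt = Ct_target − Ct_reference per sample and ΔΔCt
taken against a calibrator, which gives the reciprocal identity
RQ(A,B)·RQ(B,A) = 1 exactly. These definitions are declared, not
universal: published TGI/regression percentages are computed many ways.

## Synthetic data: what it emulates, what it does not

The cohort generator draws a latent per-sample activity a ~ N(0, 1) and
sets each gene's abundance to
`baseline_g + direction_g · effect_size · noise_sd · a + N(0, noise_sd²)`,
i.e. `effect_size` is in within-gene SD units per activity unit
(default 1.0), with gene baselines N(5, 2²) and noise SD 1. Defaults:
200 samples, 1000 genes, 50 positive + 50 negative effectors. The
experiment generator plants orientation-consistent effects of magnitude
2.5 + |N(0, 0.5²)| on effector genes across 6 experiments (half
activity-down, half up) with planted p-values drawn Beta(0.5, 20) by
default — small but with a realistic tail of insignificance — or
Uniform(0, 10⁻⁴) in the strong-planting mode the recovery analyses use;
null genes draw Uniform(0,1) p-values and N(0, 0.3²) effects. The
alteration generator draws independent Bernoulli deep-deletion /
amplification / mutation events per gene (an NF2-like coupled event
uses deletion 0.2 + mutation 0.125, i.e. 30% combined prevalence,
shifting carriers' activity by +1.5 SD), and
`simulate_altered_cohort` enforces the causal order: events shift
latent activity *before* expression is generated.

What this does **not** emulate: RNA-seq count noise (negative binomial,
library-size effects), tumor purity and stromal contamination, clonal
structure, co-occurrence and mutual exclusivity between alterations,
batch effects, or the ortholog mapping needed for mouse perturbation
series. Passing recovery tests on these cohorts therefore demonstrates
that the pipeline's inference is correct *when its model assumptions
hold*, and that its null behavior is calibrated; it does not certify
performance on any particular real platform.

All generators are pure functions of (config, seed); sub-streams are
spawned from a `SeedSequence` so multi-stage simulations are jointly
reproducible, and the CLI requires an explicit `--seed`.

## Problem sizes in the checks

The acceptance analyses use 500 random instances for oracle agreement,
1000 for the bound/antisymmetry properties, 100 for monotone
invariance; 1000-gene experiment collections for derivation recovery;
n = 200 cohorts for activity recovery; and 100 coupled plus 500 null
cohorts (n = 200 / 120, 120 genes, 20 events) for the predictor-ranking
study — sizes at which the binomial/rank statistics involved are stable
to well within the asserted margins while the whole suite stays fast.

## Known limitations

* Gene identifiers are matched as case-sensitive exact strings; alias
  or ortholog resolution is the caller's concern.
* The derivation consumes precomputed DE tables; it does not run
  differential expression, batch correction, or survival analysis.
* The association test treats samples as exchangeable; no covariate
  adjustment (histology, purity) is available.
* Exact Mann-Whitney enumeration is disabled in the presence of ties
  (the tie-corrected asymptotic form is used instead), so very small
  tied groups get approximate p-values.
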