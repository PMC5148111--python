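# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the design decisions taken where the published
method descriptions leave the details open.

## Study design and data model

The pipeline targets a 2×2 factorial ("migrant") design: two breeds, each
reared at high and low altitude, giving four cells conventionally labelled
TH, TL, DH, DL (breed initial × altitude initial). Expression is a
probe × sample matrix of log2 intensities from a one-color oligo array,
with a present/absent (P/A) detection flag per cell and a probe → gene
annotation that is redundant (several probes per gene). Probe ids are the
primary keys throughout; gene symbols attach at reporting time.

## Preprocessing

* **Detection calls.** A probe is present in a sample when its raw signal
  exceeds `background_mean + k·background_sd` (default `k = 2`). This
  reproduces the scanner semantics of flagging a signal that does not
  exceed background; `k` is configurable.
* **Expression filter.** Probes flagged present in **at least one** sample
  are kept; the filter is idempotent and precedes normalization, because
  flags are defined on raw signals.
* **Normalization.** Quantile normalization across samples (reference =
  mean of per-sample order statistics; ties share the average reference
  value of the tied ranks), followed by log2 for raw-scale input. RMA in
  the strict sense is a multi-probe summarization for a different platform
  family; for a single-probe one-color array quantile normalization + log2
  is the standard equivalent, and that is what `normalize` implements.

## Differential expression

Per probe, the two-way fixed-effects model
`y_ijk = mu + S_i + R_j + (S.R)_ij + e_ijk` is fitted by least squares.
Sums of squares are Type II (`SS(S|R)`, `SS(R|S)`, `SS(S.R|S,R)`), which
coincides with the sequential decomposition in the balanced case; F uses
the full-model residual mean square. The implementation is a vectorized
model-comparison via QR projections shared across probes, and is checked
against `statsmodels` OLS + Type-II ANOVA to 1e-8 in the tests.

Degenerate probes are guarded explicitly: with zero residual variance,
p = 0 for an effect with positive sum of squares and p = 1 otherwise, so a
constant probe reports p = 1 for all effects rather than NaN.

FDR control is Benjamini–Hochberg per effect across probes (the field
default where only "FDR" is specified; backed by
`statsmodels.stats.multitest`). **DEG rule:** a probe is differentially
expressed when *both* `q_breed < alpha` and `q_interaction < alpha`
(default `alpha = 1e-4`); the altitude main effect is computed and
reported but not used for selection. The scientific rationale: the
contrast of interest is a breed difference that itself responds to
altitude. Gene-level collapse keeps, per gene, the probe with the smallest
`max(p_breed, p_interaction)` — the binding constraint of the joint rule —
with lexicographic probe id as tie-break.

## PIF and differential PIF

For the TH-vs-DH contrast, per probe: `e1`, `e2` are group means,
`a = (e1+e2)/2`, `de = e1-e2`, `PIF = a·de`. PIF is antisymmetric under
group swap and monotone in |de| at fixed a and in a at fixed de.

"Differential PIF" is operationalized as the same two-way ANOVA + BH
machinery applied to abundance-weighted per-sample values
`w_ik = ybar_i · y_ik` (`ybar_i` the probe grand mean), with the same
joint selection rule. A caveat worth stating plainly: per-probe F
statistics are invariant to any positive per-probe rescaling, so this
test selects exactly the DEG set. The abundance weighting is carried in
the reported tables (where PIF ranks genes very differently from de
alone), not in the per-probe significance calls; the published
description of the procedure ("the same method as for DEGs") does not
admit a per-probe test in which abundance changes the calls, and we chose
fidelity to the stated procedure over inventing a different test. The
count invariant (differential-PIF calls ≥ DEG calls) holds with equality.

## PCIT

Within one sample group, Pearson correlations are computed over the
analysis universe — the union of gene-collapsed DEG representatives,
differential-PIF representatives and regulator probes, which keeps the
O(n³) trio scan tractable and matches the content of the downstream
networks. For every trio (x, y, z), with first-order partial correlations
`r_xy.z = (r_xy − r_xz·r_yz)/sqrt((1−r_xz²)(1−r_yz²))` etc., the local
tolerance is

    eps = 1/3 (r_xy.z/r_xy + r_xz.y/r_xz + r_yz.x/r_yz)

and edge (x, y) is non-significant if some z satisfies
`|r_xy| < |eps·r_xz|` and `|r_xy| < |eps·r_yz|`. Numerical choices:

* correlations of magnitude 1 off the diagonal (inevitable at n = 2 per
  group) are clamped to ±(1 − 1e-12) with a loud warning;
* tolerance ratio terms with denominator |r| < 1e-12 are dropped from the
  trio average; a trio with no remaining term is skipped;
* fewer than 3 genes: no trio exists, all edges survive with a warning.

The vectorized implementation (per-conditioner broadcasting, O(n²) memory)
is verified to agree exactly with an exhaustive scalar triple-loop oracle
on random matrices in the tests and the acceptance script. The hard
threshold |r| ≥ 0.95 is applied to the **raw** within-group correlation of
PCIT-surviving edges; the surviving pairs with their r and group tag form
the edge set.

## RIF

For regulator j and DE gene i (one representative probe per gene;
the regulator side is probe-level, matching practice on redundant
arrays): `r1_ij`, `r2_ij` are Pearson correlations within TH and DH,
`dw = r1 − r2`, and

    RIF1_j = 1/n Σ_i a_i de_i dw_ij²
    RIF2_j = 1/n Σ_i (e1_i r1_ij)² − (e2_i r2_ij)²

Pairings with undefined correlation (zero within-group variance) are
excluded from the average; a regulator with no valid pairing is reported
unscored (NaN), never as 0. z-scores use the sample (n−1) standard
deviation over scored regulators; a zero-s.d. score vector is an error.
Top-k positive/negative selections (default k = 5) break ties by
descending |z| then lexicographic probe id, so output order is
deterministic. The RIF1 extreme is the "differential wiring" candidate;
the RIF2 extreme is the "predictor of DE-gene abundance" candidate.

## Networks

Seeds are the top-k positive and negative regulators by RIF1 and by RIF2
(merged by default; either alone selectable). Retained nodes are the
seeds plus their edge-set partners that are DEG or differential-PIF
genes; retained edges are all edge-set edges among retained nodes
(configurable to regulator-incident edges only). Seed regulators with no
retained partner remain as isolated nodes so that "unconnected
regulators" are a visible, countable outcome. Output formats are SIF
(relation token `co`; isolated nodes as single-token lines) and GraphML
with node `type` ∈ {TR, DEG, PIF, DEG+PIF} and edge `weight`/`group`
attributes; nodes and edges are written sorted so files are byte-stable.

## Enrichment

`Expected = REF · |list| / N`, `fold = Count / Expected`; the raw p-value
is the exact hypergeometric tail (upper for Count ≥ Expected, lower
otherwise), with Bonferroni (`min(1, m·p)`) and BH adjustments over the m
tested terms. The hypergeometric tail was chosen over the binomial
approximation some web tools use because it is exact at this scale; the
Expected/fold arithmetic — the part validated against the published
table — is identical under both. One published row (chemokine activity)
prints fold 4.91 where its own REF/Count/Expected give 12/2.44 = 4.92;
this is rounding in the source and that row is excluded from exact
assertions.

## Synthetic data generator

`simulate_dataset(SimConfig)` emits expression, flags, design, probe
annotation, a regulator list and a ground-truth record. The model, all on
the log2 scale:

* per-probe baseline ~ N(`baseline_mean` = 8, `baseline_sd` = 1.5),
  constant across samples;
* residual noise sd `noise_sd` = 0.5, independent per probe and sample;
* **breed-DE genes** (`frac_de_breed` = 0.05): + `effect_size_breed` (= 2)
  for the Tibetan-like breed at both altitudes;
* **interaction-DE genes** (`frac_de_interaction` = 0.05): +
  `effect_size_interaction` (= 2) in the TH cell only — an interaction of
  2 plus a breed main effect of 1;
* **both-effects genes** (`frac_de_both`, default 0): both shifts at full
  size; members of both truth sets;
* **wired regulators** (`n_regulators`): each has a standard-normal latent
  signal; its target genes take core
  `r·z_reg + sqrt(1−r²)·noise` with `r = wiring_r_group1` (= 0.9) for TH
  samples and `wiring_r_group2` (= 0) elsewhere, so the expected
  within-group correlation is exactly r. Target sets are disjoint across
  regulators (a target is wired to exactly one regulator) and drawn from
  the interaction-DE pool first so DE calls overlap them;
* **null regulators** (`n_null_regulators`): on the regulator list, no
  wiring — the background for recovery experiments;
* **absent probes** (`frac_absent`): values from the background
  distribution N(3, 0.3) truncated at the detection threshold, so their
  flags are "A" everywhere and flags/values are self-consistent with
  `call_detection`;
* `probes_per_gene` = 2 by default, emulating the array's probe→gene
  redundancy; probes of a gene share its systematic signal (effects,
  wiring latent) and have independent residual noise.

Defaults are fixed once: `n_per_group` = 8 for testability (within-group
correlations over the real study's n = 2 can only be ±1; n = 2 remains
allowed and triggers the PCIT clamping warning), effect sizes of 2 log2
units (a 4-fold change, typical of a strong array hit), noise 0.5.

**What the generator does not emulate:** probe-sequence hybridization
effects, dye/scanner physics, spatially correlated noise, heavy-tailed or
intensity-dependent variance, and correlated biological replicates.
Recovery results on this generator certify the statistical machinery
under its stated assumptions, not performance on any real array.

A related point: the recovery experiments feed the generator's matrix —
which is analysis-ready by construction (common baseline distribution
across samples) — to the filter and ANOVA stages directly. Re-running
quantile normalization on such data is harmless under the null but
attenuates planted effects when a sizable gene fraction is shifted in one
group (a known property of quantile normalization under asymmetric global
DE), so the end-to-end facade applies it while the recovery experiments
measure the DE machinery on the generator's own scale.

## Acceptance scenarios (problem sizes)

The acceptance tests and `scripts/acceptance.py` use these fixed
scenarios:

* **Enrichment arithmetic:** the published table's printed REF/Count at
  its implied list fraction 35007/659400 ≈ 0.0531, realized as explicit
  gene sets and pushed through `enrich`.
* **PCIT oracle:** 50 random correlation matrices of 10–25 genes vs the
  exhaustive trio oracle, exact equality.
* **ANOVA oracle:** 200 random balanced/unbalanced designs (2–6 per
  cell) vs statsmodels Type-II, |Δ| < 1e-8; type-I calibration on a
  5000-probe null at alpha = 0.05 within the 99% binomial band.
* **Regulator recovery:** 1 wired regulator (0.9 → 0) among 100 null
  regulators, 600 genes, n = 20/group, 20 targets, 50 replicates; the
  planted regulator must top |RIF1 z| in ≥ 90% of replicates.
* **DEG recovery:** 2000 genes × 2 probes, n = 8/cell, 5% breed-only and
  5% both-effects genes at effect 2.0, sd 0.5; selection at FDR < 1e-3;
  mean sensitivity ≥ 0.9 and mean FDP ≤ 0.1 over 50 replicates for the
  both-effects class. (The interaction-only class, whose breed component
  is e/2, is recovered at ~0.85 under the same settings — a power
  statement about the rule requiring both effects, documented rather than
  hidden.)
* **Determinism:** one 250-gene run fitted and saved twice,
  byte-compared.

## Known limitations

* PCIT is O(n³) in the analysis universe; the universe restriction (DEG ∪
  differential-PIF ∪ regulators) is load-bearing for large arrays.
* Differential-PIF significance coincides with DEG significance (see
  above); the PIF ranking, not the call set, carries the abundance
  information.
* No moderated variance estimation, covariates or mixed effects; the
  ANOVA assumes independent Gaussian errors per probe.
* Enrichment treats terms independently (no ontology-graph propagation).
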