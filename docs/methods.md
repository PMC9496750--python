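# Methods

## Statistical model of the knockdown contrast

Each cohort contains one control group (non-targeting siRNA) and two
targeting-siRNA groups with *n* replicates each (default 3), optionally
over several independent experiments. All inference happens on log2 LFQ
intensities; experiments are pooled at the replicate level after the
detection filter (a protein must have at least one quantified value per
group per experiment, in every experiment).

For protein *i* and siRNA group *s* the test statistic is

    d_i = (mean log2 x_{i,s} − mean log2 x_{i,control}) / (se_i + s0)

with `se_i` the pooled-variance (Student) or Welch standard error. With
`s0 = 0` this is the classical unpaired t, and the reported two-sided
p-value is exact under normality. With `s0 > 0` the statistic is the
regularized d familiar from significance analysis of microarrays: at
n = 3 the per-protein variance estimate is so noisy that the plain t's
null distribution has heavy tails (proteins with accidentally tiny sample
variance dominate), and a fudge constant in the denominator restores a
stable ranking. `s0 = 'auto'` (the pipeline default) applies the
published selection rule: candidate values are percentiles of the se
distribution, and the one minimizing the coefficient of variation of the
MAD-based spread of d across 100 se-quantile bins is chosen. The p-value
column under `s0 > 0` uses the t distribution on the regularized
statistic and is therefore conservative; q-values, not p-values, drive
the affected-protein calls.

### Permutation FDR

Labels are permuted between the control and the tested siRNA group only;
with 3 vs 3 replicates all C(6,3) = 20 balanced arrangements are
enumerated (random arrangements with a fixed seed otherwise, `n_perm`
configurable). For each observed cutoff c = |d_i|:

    q_i = pi0 * median_b #{ |d*_b| >= c } / #{ |d_obs| >= c },

clipped to [0, 1]. q-values are then monotonized as the minimum estimated
FDR over all cutoffs that would call the protein, making q non-increasing
in |d|. `pi0` is estimated as the fraction of observed statistics inside
the central quartiles of the pooled permutation distribution divided by
0.5, capped at 1 (fixable by configuration). The fudge constant resolved
on the observed labels is reused unchanged for every permutation.

### Calls, triage and catalogues

A protein is *negatively affected* when q < alpha (default 0.05, "below
5%") for **both** siRNAs and both fold changes are negative; *positively
affected* symmetrically; anything else is not significant. This
intersection-of-two-contrasts rule is the main guard against off-target
siRNA effects; its cost is that joint sensitivity is roughly the product
of the per-siRNA sensitivities (the shared control group induces ~0.5
correlation).

Candidate-component triage selects proteins with p < 0.01 and log2 fold
< −1 (i.e. more than 50% reduction; both thresholds exposed) for both
siRNAs in both a single- and a double-depletion dataset, intersected with
an interaction-partner list. Orphan subunits of heteromeric receptors are
degraded when their partner disappears, so true components show stronger
depletion than typical clients.

Client records keep only negatively affected proteins that carry a
targeting signal (SP or ≥1 TMH); the remainder are secondary effects.
Classification precedence: hairpin flag, then SP-bearing proteins
(no TMH → soluble SP; one TMH → type I; several → multi-spanning), then
SP-less proteins (≥2 TMH → multi-spanning; one TMH ending within
`tail_window` = 30 residues of the C-terminus → tail-anchored, else
single-span). The 30-residue tail window is the common operational
definition of a tail anchor; type II/III cannot be separated without
membrane orientation, which annotation tables usually lack. The first
TMH's position is 100·((start+end)/2)/length (kept fractional) and binned
[0,25] / (25,75) / [75,100]; position summaries report the arithmetic
mean and population standard deviation. Feature enrichment is the ratio
of feature fractions (affected vs background) with a one-sided
hypergeometric p — a deliberate plain-stand-in for the mHG-based GO
tooling used interactively in this field.

## Imputation

Missing LFQ values are left-censored. After the detection filter, each
missing cell in sample *s* is drawn from N(mu_s − 1.8 sigma_s,
(0.3 sigma_s)^2) on the log2 scale (per-sample observed mean/sd; both
parameters configurable) — the de-facto standard down-shift imputation
for MNAR proteomics data. Note that of these draws only ~70% fall below
the sample's 5th percentile (Phi((1.8−1.645)/0.3) ≈ 0.70); ≥95% fall
below mu − 0.9 sigma. Imputation adds genuine variance to heavily
censored proteins; this, not the statistic, limits recovery of
low-abundance clients.

## Targeting-signal metrics

* Kyte–Doolittle hydropathy and Zimmerman polarity are plain per-residue
  means; GP content is the Gly+Pro fraction; net charge is +1 per Lys/Arg
  and −1 per Asp/Glu with His and the termini contributing 0 (both
  configurable). All are invariant under sequence duplication.
* ΔG_app implements the biological-hydrophobicity model of
  translocon-mediated helix insertion: per-residue position-dependent
  Gaussian contributions over the helix (positions scaled to [−9, 9]),
  two extra symmetric interface Gaussians for Trp/Tyr, a hydrophobic-
  moment term (100°/residue, weight 0.27045) and a quadratic length
  correction (zero near L = 19). Constants are packaged verbatim in
  `scales.py` with the source citation. The annotated span is scored
  exactly (no sliding-window minimization), matching per-client single
  values; a scan mode exists. Supported window lengths are 9–40 residues.
  Substituting leucine into a window never raises ΔG_app except against
  Ile (center) and Trp (interface positions) — those residues are more
  insertion-favorable there under this scale.
* SP segmentation: the H-region core is the maximal-scoring contiguous
  length-6 Kyte–Doolittle window (starting no earlier than residue 2),
  extended while per-residue hydropathy stays positive; prefix = N-region
  (always contains residue 1), suffix = C-region (possibly empty).
  Absence of a positive-scoring core raises a flagged error. This is a
  documented heuristic stand-in for HMM-based predictors; externally
  computed segmentations can be ingested, and the derived features
  (N-region net charge; H-region length and hydropathy; C-region
  polarity) are computed identically on either path.
* Translation time: the first min(240, len) nucleotides of the CDS are
  split into codons (a terminal stop inside the window is dropped, a
  trailing partial codon is dropped with a warning) and the codon-specific
  elongation rates are inverted and summed. Distributions are compared
  with a two-sided Wilcoxon rank-sum test, exact by enumeration of all
  label assignments when n_a + n_b ≤ 10 (midranks for ties), otherwise a
  tie-corrected normal approximation with continuity correction.

## Synthetic cohorts: what they emulate, and what not

Per protein, log2 intensity = baseline + experiment intercept + group
effect + N(0, noise_sd). Defaults (the study conditions of all tests):
baseline N(25, 2) — a typical LFQ dynamic range; noise sd 0.25 log2;
5% clients with effect −1 applied identically to both siRNA groups
(attenuation configurable); 2% up-regulated proteins (+1); optional
direction-conflict decoys (−1 in siRNA-1, +1 in siRNA-2) for testing the
same-direction rule, off by default; experiment intercepts N(0, 0.1).
Missingness is MNAR — P(missing) = logistic(−(log2 x − 19)), i.e. a
detection limit three baseline-sd below the mean, the
bottom-of-dynamic-range censoring the down-shift imputation presumes —
plus 0.5% missing completely at random (~2% missing cells overall).
Annotation fractions default to 7% SP, 10% N-glycosylated, 14% membrane
(composition of a deeply quantified HeLa proteome), with membrane classes
25% type I / 20% single-span / 15% tail-anchored / 35% multi-spanning /
5% hairpin and TMH/SP intervals placed consistently with the class.
Sequences carry hydrophobic cores in TMH windows and tripartite SPs, so
the signal metrics see realistic inputs; an exact-count mode removes
binomial sampling of the composition.

Passing tests on these cohorts show that the statistical route is
calibrated and recovers planted effects under idealized, homoscedastic,
normally distributed noise with experiment-level intercepts as the only
batch structure. Real LFQ data additionally contain peptide-level
effects, correlated (ratio-compressed) fold changes, heavier-tailed
noise, annotation errors and era-specific annotation differences — none
of which the generator simulates, so quantitative recovery rates here do
not transfer to real cohorts.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere (UniProt convention);
  writers state this in their headers. MaxQuant dialect on input:
  intensity 0 ⇒ missing; `CON__`/`REV__` rows dropped and counted.
* Zero-variance sentinels: equal group means → t = 0, p = 1; unequal →
  t = ±inf with p floored at machine epsilon.
* Exhaustive permutation when the arrangement count does not exceed
  `n_perm`; fewer than two possible arrangements is an error.
* The TMH-center mean is kept fractional so bin boundaries (25.0 → N-
  terminal, 75.0 → C-terminal) are deterministic.
* Multi-category compartment annotations count by their first listed
  (primary) category.
* Determinism: one seeded generator drives each synthetic cohort;
  pipeline stages derive fixed offsets from the run seed; rerunning a
  pipeline with the same config and seed reproduces result tables
  byte-identically (the manifest timestamp lives outside the tables).
  Stage outputs can be resumed from cache for partial reruns.
* Test problem sizes: calibration uses 20 null cohorts of 2000 proteins;
  recovery uses the 2000-protein default cohort; enumeration oracles run
  at n ≤ 10 (rank-sum) and 20 proteins (hypergeometric) where exhaustive
  enumeration is exact.

## Known limitations

* The p-values under `s0 > 0` are conservative rankings, not exact tail
  probabilities; use q-values for inference (as the pipeline does).
* The permutation null is contaminated by planted/real effects under
  label mixing, making q-values mildly conservative near the threshold.
* The SP segmenter is a heuristic; for publication-grade region features
  ingest an external predictor's segmentation.
* Type II vs III single-spanners are not distinguished without
  orientation data; SP-bearing multi-spanners are labeled multi-spanning
  with `has_sp = True` and are counted in both SP and TMH tallies of the
  summary tables.
* The packaged codon-rate generator is synthetic (uniform 2–15 codons/s)
  and only exercises the machinery; supply a measured elongation-rate
  table for biological use.
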