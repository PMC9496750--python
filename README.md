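# erclients

Identification and characterization of ER targeting-pathway **clients** from
siRNA-knockdown label-free quantitative (LFQ) proteomics.

Protein import into the endoplasmic reticulum is directed by cleavable
signal peptides (SP) or transmembrane helices (TMH) that are read by
dedicated targeting machineries (SRP/SR, TRC/GET via Wrb–Caml, the
SRP-independent SND route, PEX19/PEX3). Depleting one receptor component
with siRNA lowers the steady-state abundance of the precursors that depend
on it; comparing whole-proteome LFQ intensities between knockdown and
control cells therefore reveals that pathway's client spectrum. This
package implements the complete computational route for such experiments,
for proteomics analysts who have MaxQuant-style `proteinGroups` output and
UniProt-derived annotations:

1. **Differential abundance.** For each targeting siRNA *s* and protein
   *i*, the log2 intensity ratio against the non-targeting control is
   tested with an unpaired two-sample statistic

   d_i = (x̄_i,s − x̄_i,c) / (se_i + s0),

   where `s0` is a small fudge constant regularizing the noisy 3-replicate
   variance estimates (`s0 = 0` gives the classical Student t;
   `s0='auto'` tunes it so the spread of d is independent of se, the
   significance-analysis-of-microarrays rule). Multiple testing is
   corrected with a **permutation FDR**: control/siRNA labels are permuted
   (exhaustively for 3 vs 3 — 20 arrangements), and for each observed
   cutoff c the q-value is π̂0 · median_b #{|d*_b| ≥ c} / #{|d| ≥ c},
   monotonized. A protein is *affected* only when q < α (default 0.05) for
   **both** siRNAs with the same sign of the fold change. Missing
   intensities (left-censored in LFQ data) are first imputed from a
   per-sample down-shifted Gaussian N(μ − 1.8σ, (0.3σ)²) on the log2
   scale, after requiring detection in every experiment.

2. **Client catalogues.** Negatively affected proteins carrying a
   targeting signal are classified (soluble SP / type I / single-span
   without SP / tail-anchored / hairpin / multi-spanning), the position of
   the first TMH is expressed as the central residue in percent of protein
   length and binned into N-terminal [0,25], central (25,75) and
   C-terminal [75,100], and SP/N-glycosylation/membrane enrichment over
   the quantified background is scored with fold ratios and one-sided
   hypergeometric p-values. Set algebra for double-knockdown-specific
   clients and pathway pooling is included.

3. **Candidate-component triage.** Proteins with strong, reproducible
   depletion (p < 0.01 and log2 fold < −1 for both siRNAs) in both a
   single- and a double-depletion dataset, intersected with an
   interaction-partner list — the logic that singles out missing receptor
   subunits.

4. **Targeting-signal metrics.** Kyte–Doolittle hydropathy, Gly/Pro
   content, Zimmerman polarity, net charge, ΔG_app of translocon-mediated
   membrane insertion (position-dependent biological-hydrophobicity model
   with hydrophobic-moment and length terms), heuristic N/H/C signal-
   peptide segmentation (with an ingest path for external segmentations),
   and translation-time estimates from codon-specific elongation rates
   (inverted and summed over the first 80 codons) with a Wilcoxon
   rank-sum comparison (exact by enumeration for small samples).

A first-class **synthetic-cohort generator** reproduces the experimental
design (one control + two targeting siRNAs, three replicates, optional
independent experiments, ~7% SP / ~10% N-glycosylated / ~14% membrane
proteins, intensity-dependent missingness) with a known ground-truth
ledger, so the whole pipeline is testable offline.

## Worked example

Simulate a knockdown cohort, call affected proteins, build the client
catalogue and summarize it:

```sh
$ erclients simulate --n-proteins 2000 --seed 7 --out demo/
wrote synthetic cohort (2000 proteins) to demo

$ erclients diff --lfq demo/lfq.tsv --design demo/design.tsv --seed 7 --out demo/calls.tsv
1998 detected; 68 negative, 30 positive affected at q < 0.05 (both siRNAs, same direction)

$ erclients clients --calls demo/calls.tsv --annotations demo/annotations.tsv \
      --pathway hSnd2 --out demo/clients.tsv
68 clients (hSnd2) written to demo/clients.tsv

$ erclients report --clients demo/clients.tsv --out demo/summary.tsv
summary for 1 pathway(s) written to demo/summary.tsv
```

`demo/summary.tsv` then contains (transposed):

```
pathway                    hSnd2
n_clients                     68
pct_sp                 38.235294
pct_tmh                79.411765
pct_multi_spanning     32.352941
pct_tail_anchored      13.235294
tmh_pos_mean           39.597825
tmh_pos_sd              33.71094
bin_n_terminal               0.5
bin_central             0.277778
bin_c_terminal          0.222222
...
```

Reading: of 1998 proteins detected in all samples, 68 were significantly
less abundant after the simulated knockdown in both siRNA treatments
(q < 0.05). 38% of those clients carry a cleavable SP and 79% at least one
TMH; the first TMH sits on average at 40% of the protein length, with half
of the TMH-bearing clients having N-terminal (≤25%) signals. The same
commands run on real exported LFQ tables; `erclients run` executes all
stages at once and writes a provenance manifest (config hash, seed,
per-stage protein counts).

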