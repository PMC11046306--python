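# Methods

`feshift` implements two analysis engines around a common biological
question — what happens to a cell when iron-sulfur (Fe-S) cluster supply is
restricted — together with synthetic-data generators that make both engines
testable against known ground truth without any external downloads.

## 1. Pooled CRISPR genetic-interaction screen

### Model

A knockout library of `n_genes x ~4` single-guide RNAs plus non-targeting
controls (NTCs) is introduced into two isogenic backgrounds: a control line
and a sensitized line (e.g. depleted for an Fe-S biogenesis factor). After a
selection phase, guide abundances are sequenced and compared with the
plasmid library.

Scoring follows the standard empirical-null recipe:

1. **Normalization.** Per sample, each guide's reads `r` out of total `R`
   become `log2(r / R * 1e6 + 1)` (reads per million, log2, pseudocount 1).
2. **Guide LFC.** Normalized abundance minus the same guide's normalized
   abundance in the plasmid library. Replicates are paired throughout.
3. **Gene LFC.** Unweighted mean over the gene's guides within each
   replicate, then the unweighted mean across replicates.
4. **Empirical null.** Genes with no detectable expression
   (log2 FPKM at the table floor, default −7) cannot have a knockout
   phenotype; their gene-LFC spread measures pure technical noise. Per arm,
   every gene's LFC is Z-transformed with the null genes' mean and sample SD
   (`ddof=1`; the estimator is configurable). By construction the null
   genes' Z values have mean 0 and sample SD 1 *exactly*, which the tests
   assert to 1e-12.
5. **Interaction score.** `delta_z = z_treat − z_ctrl`. Genes with
   `delta_z >= z_cut` (default 2) are *buffering* (less deleterious on the
   sensitized background), `<= −z_cut` *synthetic sick*. The cut is a
   reporting convenience, exposed as a parameter; ranking by `delta_z` is
   the primary output.

Genes with fewer than `min_guides` (default 2) detected guides are flagged,
not dropped. The comparison in `define_null_genes` is `<=` because the
printed threshold is the floor of the expression table.

### Synthetic screen generator

The generator is a selection model, not a read simulator. Plasmid abundances
are log-normal (`sigma = 0.5`). Each gene has a base per-doubling fitness
`f` and an interaction term `gamma` active only in the treated background;
each guide has a cutting efficiency `e ~ Beta(5, 1)`. Over `d` population
doublings the expected relative abundance of guide *i* is

    p_i  ∝  plasmid_i · 2^( d · e_i · (f_g + gamma_g · [treated]) )

and counts are drawn multinomially at fixed depth (column sums exact) or
negative-binomially (`var = mu + alpha·mu^2`) to emulate PCR/sequencing
overdispersion.

Default study conditions: 2,000 genes x 4 guides + 1,000 NTCs; 10%
essential (`f = −0.5`), 5% buffering (`f = −0.5`, `gamma = +0.5`), 5%
synthetic sick (`f = 0`, `gamma = −0.5`); 20% of neutral genes are flagged
non-expressed and populate the empirical null; `d = 10` doublings
(≈11 days of selection at a ~1-day doubling time); depth 1e7 reads/sample —
the screen's sequencing depth is not externally constrained, and 1e7 is a
typical bench-top figure giving ~1,100 reads/guide at this library size.
A `paper_scale_config()` preset reproduces the full Brunello composition
(76,441 targeting guides over 19,114 genes + 1,000 NTCs = 77,441). NTC
guides are grouped into pseudo-genes of 4 so they traverse gene-level
scoring and act as a second sanity null.

Two properties of the model worth knowing:

* **Composition offset.** Reads-per-million renormalization divides by the
  sample's mean fold-growth, so every neutral guide's LFC carries a common
  positive offset (−log2 of the mean fold-growth, ≈ +0.2 under the default
  class mix) — exactly as in real screens where essential-gene dropout
  inflates everyone else's share. The Z-transform absorbs the offset; raw
  NTC LFCs are offset-positive but tight (tested: 99th-percentile deviation
  from their median < 0.1 at 1e7 reads).
* **Noise-free oracle.** On expected counts (`expected_screen_dataset`)
  with a zero pseudocount, guide LFC minus the LFC of any NTC guide equals
  `d·e·f` (+`d·e·gamma` when treated) to machine precision: the NTC term is
  exactly the composition offset. This closed form is the pipeline's
  correctness oracle and holds to 1e-9 in the tests.
* **Heteroskedastic calls.** Strongly depleted genes retain few reads, so
  their LFC noise exceeds the null's; at `z_cut = 2` a fraction of plain
  essential genes crosses the cut in either direction. Recovery of *true*
  interaction genes is therefore checked as a ranking property (mean AUROC
  of `delta_z` ≥ 0.9 over 20 simulated screens; in practice ≈ 1.0).

## 2. TMT proteome quantification and gene-set shift

### Quantification

Input is a peptide-level table of reporter-ion signal-to-noise (SN) per
channel with a duplicate control / treated design. Steps:

1. **Impurity correction.** Reagent isotope impurities mix a fraction of
   each channel's signal into neighboring channels. With the
   column-stochastic impurity matrix `M` (entry `(i, j)` = fraction of
   reagent *j* observed in channel *i*), the observed row is `M @ true`;
   the correction solves that system per peptide row. Negative solutions
   (possible with noise) are clipped to zero and counted for QC; clipping
   at exactly zero never fires in the forward-simulated noise-free case,
   where the inversion is exact (tested to 1e-9). Because `M` is
   column-stochastic, total signal is conserved by the correction whenever
   nothing is clipped.
2. **Rollup and filter.** Peptide SN sums to proteins; proteins with total
   summed SN below 100 across all channels are removed (boundary retained).
   The filter is applied after correction by default (configurable — the
   ordering is not externally fixed).
3. **Loading normalization.** Channels are scaled so their protein-quantity
   column sums are equal (target = mean of the sums; any common target
   yields identical fold-changes). Within-channel rank order is unchanged.
4. **Fold-change.** Per replicate pair (ctrl/treat matched by declared
   order within each condition), `log10(treat / ctrl)`, then the replicate
   mean. Proteins with a zero quantity in a used channel are flagged
   `missing`, not silently dropped.

### Synthetic TMT generator

Each of `n_proteins` gets a log-normal baseline and `1 + Poisson(2)`
peptides with log-normal response factors. True fold-changes are
`N(0, sigma)` background draws (`sigma = 0.1` would be a strong treatment;
the default 0.05 emulates a mostly-unchanged proteome) plus a configured
log10 shift `delta` for members of designated sets — by default a 40-protein
"FES" set and a 30-protein "SSU" set at `delta = −0.2`, with a 30-protein
unshifted "LSU" control set. Per-channel measurement noise is multiplicative
log-normal at a 5% CV, and a tridiagonal impurity matrix with 2% adjacent-
channel spillover is applied.

Because a real TMT experiment labels an equal peptide mass per channel,
the generator balances total signal per condition: a single constant log10
offset is applied to the non-shifted background proteins so that noise-free
channel totals are exactly equal (the offset is ≈ +0.004 under the
defaults). Truth tables record the realized fold-changes. Without this, the
pipeline's loading normalization would (correctly) re-center all
fold-changes by a constant and no exact-recovery statement would be
possible. A consequence to keep in mind with real data: fold-changes after
loading normalization are relative to total protein signal, not absolute.

### Shift and enrichment statistics

* **Waterfall.** Stable ascending sort of fold-changes (rank 1 = most
  depleted); ties broken lexicographically by identifier.
* **Two-sample KS.** `D` is the exact supremum ECDF distance over the
  pooled sample. The p-value uses the exact permutation null when
  `min(n) <= 25` (it then equals full enumeration of label assignments, as
  the tests verify by brute force up to n = 8) and otherwise the asymptotic
  Kolmogorov distribution at `sqrt(n_a·n_b/(n_a+n_b))·D`, series truncated
  at k = 100. `D` is invariant under strictly monotone transforms (property
  tested).
* **Set-vs-background.** Each set's fold-changes are compared against all
  *other* detected proteins; excluding the set avoids self-overlap, which
  otherwise dilutes `D` for large sets. An inclusive mode reproduces the
  literal "versus all identified proteins" comparison. Reported per set:
  detected size, `D`, direction (sign of the median difference), `p`, and
  the number of members below zero. The null calibration of the reported
  p-values is checked by simulation (mean ≈ 1/2, rejection rate at or below
  nominal; the exact two-sample KS null is discrete, hence slightly
  conservative).
* **Over-representation.** One-sided upper-tail hypergeometric test of a
  hit list against each set within a stated universe (equal to exhaustive
  draw enumeration, verified for universes up to 12), with
  Benjamini-Hochberg adjustment across sets (`q >= p`, monotone).

A curated, editable GMT of ~50 human Fe-S cluster proteins plus
mitoribosomal SSU/LSU lists ships with the package
(`feshift.io.builtin_genesets()`) for use with real protein tables; the
synthetic pipelines build their own sets over simulated identifiers.

## 3. Assay utilities

Pure closed forms: `ddct_ratio` (relative qPCR quantification,
`eff^−ddCt`, efficiency fixed at 2 by default as in standard TaqMan
analysis, exposed as a parameter), `reference_normalize` (per-sample
division by a reference gene), `frip_enrichment`
(`(IP/input)/bait level`), and `fe_per_polypeptide` (molar ratio from
ICP-MS). Swapping test and control in `ddct_ratio` inverts the result
exactly; all are scale-covariant as dimensional analysis requires.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng(seed)`; identical
  config + seed reproduces outputs bitwise.
* Problem sizes in the test suite and the acceptance script are desk-scale
  (hundreds to a few thousand genes/proteins, 20–100 simulation seeds),
  chosen so the full validation runs in seconds while leaving the
  statistical assertions comfortable margins; the paper-scale library
  preset is exercised for composition, not for count drawing.
* The synthetic generators emulate selection, count noise, channel mixing
  and set shifts. They do not emulate guide off-target activity, copy-number
  artifacts, PCR chimeras, peptide-identification error, shared peptides or
  missing-value structure — passing tests demonstrate correctness of the
  scoring mathematics under the stated models, not robustness to those
  real-data pathologies.
* Impurity matrices are validated (column sums 1 ± 1e-9, non-negative)
  before inversion; singular matrices are rejected. QC clipping ignores
  negatives within 1e-9 of zero (solver dust).
* Gene/protein identifiers are matched uppercased everywhere; results are
  CSV, inputs TSV/GMT/YAML, all UTF-8.

## Known limitations

* The empirical null assumes non-expressed genes are phenotypically inert;
  genes silenced in the reference expression table but active in the
  screened line would inflate the null SD and deflate all Z scores.
* The interaction caller thresholds `delta_z` without modeling the
  LFC-dependent variance noted above; a variance-stabilized or
  moderated-variance score is a natural extension.
* The KS comparison treats proteins as exchangeable; correlated complexes
  (e.g. a whole ribosomal subunit co-depleting) violate independence, so
  p-values for such sets are anti-conservative in a way shared by the
  standard practice this package follows.
* `protein_log_fold_change` requires a balanced ctrl/treat design with an
  equal number of channels per condition.
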