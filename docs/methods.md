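# Methods

## Scientific setting

Rapidly inducible NF-κB target promoters and enhancers typically carry not a
single consensus κB element but a cluster of sites of widely varying
affinity: one strong site surrounded by several weak ones within roughly
150–200 bp, the span of a nucleosome-free regulatory region.  `kbsites`
implements the quantitative half of that observation as a reusable pipeline:
site designation by affinity lookup, cumulative cluster scores against ChIP
occupancy, a thermodynamic occupancy projection, and enrichment scoring of
DNA-pulldown proteomics that screens for cofactors.

## Site designation and classification

A 10-bp window of a scanned sequence is designated a κB site when its 10-mer
(on either strand) is present in an affinity Z-score table with a strictly
positive score *and* deviates from the degenerate consensus GGGRNNYYCC
(R = A/G, Y = C/T, N = any) at no more than 3 positions.  Sites with
Z ≥ 6 are classed strong, below 6 weak; the boundary value itself is
assigned to the strong class so the strong set is closed.  In the published
calibration, Z = 6 corresponds roughly to K_D ≈ 300 nM in vitro.

Decisions taken where the procedure was genuinely open:

* **Positivity requirement.**  Designation requires a table Z > 0; entries
  with Z ≤ 0 stay in the table but never produce sites.  This guarantees
  that cumulative window scores are non-decreasing in window length, which
  the correlation analysis relies on.
* **Strand collapse.**  When both strands of one window qualify, only the
  larger-Z strand is reported (tie → + strand), so a near-palindromic site
  is never counted twice.  Overlapping sites at *different* starts are all
  reported — the analysis counts sites, it does not tile the sequence.
* **Fixed width.**  Scanning is fixed 10-bp.  Shorter deviant elements
  (9-bp sites occur in nature) are out of scope; a table built from 10-mer
  probes cannot score them.
* **Coordinates** are 0-based half-open throughout; the site "center" is the
  midpoint start + 5 of the half-open interval.  BED export uses the same
  convention; the BED score column is the Z-score scaled by 50 and clipped
  to [0, 1000].

## Cluster analysis

Each peak region carries ±500 bp of sequence (1001 bp nominal) and an
occupancy score (`chip_score`) accepted as provided — tag-count
quantification upstream of this package is not re-derived.  The *anchor* is
the designated site with maximal Z; ties break by distance to the region
center, then by smaller start.  For a window length L (default grid
10–500 bp in steps of 10) the cumulative Z is the sum of Z-scores of sites
whose centers lie within ±L/2 of the anchor center, boundaries inclusive.
With `include_weak=False` weak sites contribute zero — the anchor itself is
always included and never re-selected, so the two curves share an anchor.

`correlation_curve` reports the Pearson r between occupancy scores and
cumulative Z per window length, for all sites and for strong sites only.
Zero-variance vectors yield an explicit NaN (flagged in the log), never a
silently dropped point.  Raw scores are correlated by default; a log1p
transform is available but off.

`compare_ranked_halves` ranks peaks by occupancy (ties broken by region id
so the split is deterministic; with odd n the extra peak goes to the bottom
half), counts weak sites within ±250 bp of each anchor, and compares the
halves with a two-sided pooled-variance Student t-test (Welch available via
`equal_var=False`).  Degenerate inputs (both halves constant and equal)
return t = 0, p = 1.

## Occupancy projection

`fraction_bound` evaluates f = C/(C + K_D) under the free-ligand
approximation (site concentration ≪ TF concentration), both arguments in
nM.  At C = 200 nM and K_D = 3 µM this gives 6.25% — the "about 6%"
projection for very weak sites at stimulated nuclear RelA levels.  No
ligand-depletion correction and no multi-site cooperativity are modelled;
the number is deliberately the back-of-envelope equilibrium bound.

## Pulldown enrichment

The pipeline order is fixed: (1) drop proteins with summed peptide count
< 5 over all pulldowns (a total of exactly 5 is kept); (2) divide each
pulldown column by its total peptide count; (3) Z-score each protein across
all experiments (sample s.d., n − 1; zero-variance rows become all-zero and
are flagged); (4) call a protein enriched when its mean Z over probe
pulldowns exceeds its mean Z over control-DNA pulldowns by strictly more
than 0.5.  Standardisation across *all* pulldowns (rather than per column or
within condition groups) is the default reading; per-column standardisation
is exposed as `across="proteins"` but non-default.  Replicate handling for
heatmap export averages raw counts per condition before normalisation
(`average_replicates` / `combine_replicates=True`).  Row clustering for
heatmaps is seeded k-means (k defaults to 4 — the published displays do not
state k, so it is a user parameter).

## Synthetic data: what it emulates and what it does not

The generators define the study conditions under which the pipeline is
validated; their defaults are fixed, not tuned per run.

* **Affinity table** (`gen_zscore_table`): n distinct 10-mers within 3
  mismatches of the consensus, Z ~ Gamma(1.5, 3) + 0.2 (positive,
  right-skewed: mostly weak entries with a strong tail), always containing
  the reference pair GGGAAATTCC → 14.0 and GGGAAGTTCC → 5.8.
* **Peak cohort** (`gen_peak_cohort`): per peak a 1001-bp i.i.d. background
  (GC 0.45, typical of murine promoter-proximal sequence), one strong-class
  table k-mer planted at the center and n_weak ~ U{2..8} weak-class k-mers
  planted uniformly within ±span/2 (default span 150 bp — the observed
  cluster span), non-overlapping with at most 1000 placement attempts.  The
  occupancy score is α·(planted cumulative Z) + N(0, noise_sd) floored at
  zero (α = 1, noise_sd = 5 by default, roughly 20% of a typical cumulative
  Z).  Background windows that happen to qualify for designation are
  *tolerated and tracked* as incidental sites, not rejected — rejection
  would bias the background composition.  The n_weak range stops at 8
  because ~9 non-overlapping 10-mers approach the packing limit of a 150-bp
  span and larger counts make placement failures likely.
* **Pulldown matrix** (`gen_pulldown`): per-protein Poisson rates
  Gamma(2, 10) + 1 (mean ≈ 21 peptides per pulldown), planted proteins
  multiplied by the effect size in experimental columns only.

All randomness flows from one seed through named substreams (sequence,
placement, noise), so regenerating a cohort with a different noise level
keeps its sequences byte-identical — used when the noise is calibrated to
half the cohort's mean cumulative Z.

What the generator does **not** emulate: repeat structure, CpG islands and
dinucleotide composition of real genomes; read-level ChIP-seq noise
(fragment-length, mappability and GC biases); correlated co-capture of
protein complexes in pulldowns.  Passing tests therefore demonstrate that
the pipeline recovers the statistical structure it assumes — not that real
promoters satisfy that structure.

## Numerical choices and problem sizes

Pearson r comes from `scipy.stats.pearsonr`; the t-test from
`scipy.stats.ttest_ind` with a degenerate-input guard; k-means from
scikit-learn with a seeded, multi-restart (capped at 100) fit.
Normalisation conserves column sums to 1 within 1e-12.  The validation
suite uses cohorts of 100 peaks × 10–20 seeds, 60-peak cohorts for the
ranked-halves power/type-I checks, and 200 random instances for the
scanner-vs-enumeration cross-check; these sizes give stable means (the
recovery statistics vary by < 0.03 across seeds) while keeping a full run
in seconds.

## Known limitations

* The affinity table maps 10-mers only; variable-length or gapped κB
  elements are not scored.
* No continuous Z → K_D mapping is provided (only the Z = 6 ≈ 300 nM
  boundary is documented), so occupancy projections take K_D directly.
* `chip_score` is whatever quantification the peak caller emitted; the
  package neither re-normalises nor models it.
* The enrichment margin (0.5) and count filter (5) are the published
  operating points, not estimated error rates; no multiple-testing control
  is layered on the pulldown selection.
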