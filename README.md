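# kbsites

Analysis toolkit for **clustered NF-κB binding sites**: designate strong and
weak κB elements in regulatory sequence by affinity Z-score, relate the
*cumulative* affinity of a site cluster to ChIP-seq occupancy, project
equilibrium site occupancy from binding constants, and score DNA-pulldown
proteomics for RelA cofactor candidates.

## The problem

Promoters and enhancers of rapidly inducible NF-κB target genes rarely
contain a single consensus κB site.  Instead they carry a cluster — one
strong site surrounded by several weak ones — within a ~150-bp span.  Each
weak site on its own binds NF-κB RelA poorly: at a stimulated nuclear dimer
concentration C ≈ 200 nM and a dissociation constant K_D ≈ 3 µM, the
equilibrium fraction bound

    f = C / (C + K_D) ≈ 0.06

is only ~6%.  Yet deleting weak sites measurably reduces RelA recruitment
and transcription.  `kbsites` provides the computational machinery to
quantify this: a 10-mer window is designated a κB site when it appears in a
protein-binding-microarray-style affinity table (Z-score > 0) and deviates
from the consensus GGGRNNYYCC at ≤ 3 positions; sites with Z ≥ 6 are strong,
below 6 weak.  For each ChIP peak, Z-scores of all sites within a dynamic
window of length L (10–500 bp) around the strongest motif are summed, and
the Pearson correlation r(L) between that cumulative Z and peak occupancy is
traced — with and without the weak sites' contribution.  A pooled-variance
t-test compares weak-site abundance between occupancy-ranked peak halves,
and a spectral-count pipeline (total-count ≥ 5 filter, per-pulldown
normalisation, per-protein Z-scores, mean-difference margin > 0.5 vs the
control DNA) flags proteins enriched in κB-probe pulldowns.

Everything runs on synthetic data with planted ground truth, so the whole
pipeline is testable without external downloads.

## Worked example

`examples/correlation_window.py` generates 100 synthetic peaks (one strong
site plus 2–8 weak sites planted within 150 bp; occupancy = cumulative
planted Z + Gaussian noise) and traces the correlation curve:

```
cohort: 100 peaks, planted span 150 bp, noise sd 10.0

window_bp  r_all   r_strong_only
       10  -0.050  -0.027
       50   0.277  -0.036
      150   0.481  -0.018
      300   0.471  -0.019
      500   0.471  -0.019

weak sites per peak: top half 5.46, bottom half 3.84 (t = 4.05, p = 0.0001)
```

`r_all` climbs until the analysis window covers the planted 150-bp cluster,
then plateaus — the occupancy signal lives in the cluster's summed affinity.
Excluding weak sites (`r_strong_only`) destroys the correlation, and
high-occupancy peaks carry significantly more weak sites than low-occupancy
peaks.  The other scripts in `examples/` demonstrate site scanning
(`scan_promoter.py`), the occupancy grid (`occupancy_projection.py`, which
prints the 6.25% projection above), and pulldown scoring
(`pulldown_enrichment.py`, which recovers exactly the 5 planted proteins
from a 50-protein matrix).

A thin CLI mirrors the library (`kbsites simulate|scan|correlate|occupancy|
pulldown|all`), e.g.:

```sh
kbsites all --outdir out --seed 7 --n-peaks 100
kbsites occupancy --conc-nm 200 --kd-nm 3000
```

Every run writes a `manifest.json` with parameters, seed and SHA-256
checksums; identical seeds give byte-identical outputs.

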