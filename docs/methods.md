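# Methods

`coopreg` implements the computational core of a paired ChIP-seq / knockdown
study of two cooperating transcription factors (TFs): chromatin-state
annotation of binding sites, classification of knockdown-responsive genes
into direct and indirect targets, quantification of two-TF co-occupancy, a
geometric test for cooperative regulation on paired fold-changes, and
mito-stress respirometry metrics. This note records the models, the defaults
and why they were chosen, and what the synthetic benchmark does and does not
demonstrate.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based closed) is converted at the reader boundary. Peak-to-gene distance
is anchored at the peak midpoint, the common convention for TSS-assignment
tools; the narrowPeak summit is available as an alternative anchor
(`anchor="summit"`). A TSS lying anywhere inside a peak gives distance 0.
Equidistant TSSs are resolved by smaller absolute distance, then
lexicographically smaller gene id, so assignments are deterministic across
platforms and peak orderings. Peak strand is ignored for overlap; gene strand
enters only through the TSS and metaprofile orientation. Many-vs-many
overlap queries use a per-chromosome interval tree (O((n+m) log(n+m))) and
are tested against the all-pairs brute force.

## Chromatin-state model

States are learned with a K-state hidden Markov model whose emissions are
products of independent Bernoulli variables, one per binarized mark — the
standard segmentation model for chromatin marks. Choices:

* **Binarization.** A bin is called present when its count reaches the
  Poisson upper-tail threshold at p = 1e-4 for the mark's genome-wide mean
  rate. No local control track is used. This is the widely documented
  default for this preprocessing step; tracks that are already 0/1 are
  passed through unchanged.
* **Learning.** Plain Baum–Welch EM with scaled forward–backward.
  Initialization is seeded: emissions ~ uniform(0.2, 0.8), transitions
  sticky (0.9 self-transition). Probabilities are floored at 1e-6 to avoid
  absorbing zeros. Convergence is declared when the per-bin log-likelihood
  improves by less than `tol` (default 1e-4); the likelihood trajectory is
  retained on the model and asserted non-decreasing in tests.
* **Decoding.** Per-bin posterior argmax by default (ties toward the lower
  state index); Viterbi behind a flag. Posterior decoding matches the
  convention of the common segmentation tool and maximizes per-bin accuracy.
* **K.** Free parameter, default 11 in the CLI to match common practice for
  mark-rich panels; the desk-scale benchmarks use K = 3 with two marks,
  which is the smallest configuration that exercises state matching
  non-trivially.
* **State labels** are opaque ("E1".."EK"). Biological grouping
  (promoter/enhancer/...) enters only through an explicit user-supplied
  `group_map`, since any mapping from learned states to element classes is a
  judgment call that should be visible in the analysis, not baked in.

Coverage of a peak set by the segmentation is computed per base pair:
fraction of total peak bp per state, with the genome-wide per-state bp
fraction as baseline. Overlapping peaks each contribute their own bp
(no merging) unless `merge=True`; this matches the "over the total length of
the peak set" definition and makes the fractions sum to exactly 1.

## Active elements and direct targets

A TF peak is an *active element* when it overlaps (≥ 1 bp) an H3K27ac peak
AND an RNA-PolII peak. Conjunction is the default because it is the natural
reading of "active element marked with both"; disjunction is available and
both counts are logged. Evidence is peak-level BED overlap, not a signal
threshold.

Active peaks are assigned to nearest-TSS genes (optionally capped by
`max_distance`, default unlimited); genes with at least one supporting peak
form the ChIP target set. A knockdown DEG (adjusted p ≤ 0.1, boundary
inclusive) is *direct* if it is in the ChIP target set, *indirect*
otherwise. Genes bound but not deregulated are ignored — direct means bound
AND deregulated. Tables carrying only raw p-values get Benjamini–Hochberg
adjustment at the reader, loudly, so adjusted and raw significance are never
silently mixed. Direct fractions are always reported with their explicit
numerator and denominator.

Cross-contrast coherence takes the direct sets of two cell lines/contrasts
and splits the intersection by fold-change sign agreement.

## Fold-change shrinkage

The cooperation geometry needs variance-stabilized fold-changes. A
self-contained normal–normal empirical-Bayes shrinker is used so the
pipeline has no external model dependency: prior N(0, τ²) with the moment
estimate τ² = max(0, var(raw) − mean(se²)); posterior mean
raw · τ²/(τ² + se²). Shrinkage never flips signs and never increases
magnitude, and on simulation dominates the raw estimates in MSE. Raw
fold-changes can be used instead (`--no-shrink`).

## Cooperation test

Both contrasts' shrunken fold-changes are standardized robustly (median
centered, scaled by MAD × 1.4826) so that planted outliers do not inflate
the null; the per-gene radius r = sqrt(x̃² + ỹ²) is compared with the
chi-square(df = 2) quantile, sqrt(χ²₁₋α(2)) ≈ 2.4477 at α = 0.05: under an
independent bivariate standard normal a fraction α of genes falls outside
the circle. A gene is called *cooperatively regulated* iff it is assigned
(nearest TSS) from a co-occupied region of the two TFs AND r exceeds the
threshold. Direction concordance is reported and can be required
(`require_concordance`, default off). The circle is a single geometric gate,
not a per-gene p-value, so no multiple-testing layer is added.

Known limitation: the circle flags any co-bound gene with a large joint
radius, including genes strongly affected by only one TF. When the
surrounding data contain many strong single-TF effects these also inflate
the MAD slightly (it is robust to, not immune to, 25–30% outliers), so
3σ cooperative genes near the boundary can be missed at full-study
conditions; the calibration and power guarantees in the test suite are
stated for the controlled setting (cooperative genes among nulls), which is
what the test's operating characteristics mean.

## Mito-stress (OCR) metrics

OCR values are divided by cell count first. Per phase the representative
value is the mean of that phase's measurements ("last point" available; the
two differ only under within-phase drift, and the default is logged):

    non_mito   = mean OCR after rotenone + antimycin A
    basal      = mean baseline OCR − non_mito
    maximal    = mean OCR after FCCP − non_mito
    atp_linked = mean baseline OCR − mean OCR after oligomycin

basal + non_mito reproduces the baseline mean by construction. KD/CTRL fold
changes are per-metric ratios; a zero control is reported as undefined,
never infinity.

## Synthetic benchmark

The generator plants a fully known truth and writes exactly the formats the
pipeline reads. Scale and defaults (the study conditions for all tests):

* 1 chromosome × 2 Mb, 200 non-overlapping genes (1–2 kb), 200-bp bins —
  every stage completes in seconds on one CPU.
* Hidden 3-state chain, 0.9 self-transition, emissions 0.9/0.1 on 2 marks —
  well-separated states so recovery failures indicate bugs, not ambiguity.
* 600 TF-A peaks (200–400 bp), 30% centered within ±500 bp of a TSS
  (about one per promoter, rejecting placements whose nearest TSS is not the
  intended gene so the proximal truth is exact), the rest uniform. Peaks are
  mutually exclusive within a 150-bp guard margin; the count was chosen so
  that this non-overlap guarantee packs comfortably into 2 Mb. Each A peak
  spawns one B peak, overlapping with probability 0.44 (the co-binding rate
  the pipeline should read back), otherwise placed in free background.
  Evidence marks cover exact planted fractions of A peaks (60% both marks,
  10% each single mark).
* DEG tables: constant per-gene SE of 0.5; affected genes (25% of genes,
  60% of them drawn from bound-and-active genes) get ±5σ shifts; 5% of genes
  are cooperative with correlated 3σ shifts in both contrasts; p-values from
  the two-sided normal model, BH-adjusted. Constant SE keeps the robust
  standardization of the cooperation test exactly calibrated, which is the
  property the null-calibration check measures.
* OCR: phase means (100, 40, 180, 20) pmol/min/well, Gaussian well noise
  (sd 4), 6 wells per condition, planted 1.5× fold on the mitochondrial
  components only.

Every generator is a pure function of (parameters, seed); rerunning
reproduces byte-identical files, and the CLI chain simulate → segment →
annotate → targets → cooperate is asserted byte-deterministic end to end.

What passing does **not** show: the generator has no read-level noise, no
peak-width/signal correlation, no GC or mappability structure, no correlated
gene expression, and gene density and peak spacing are far from genomic
reality. The benchmark validates the arithmetic and the operating
characteristics of the statistics under their stated assumptions — not
performance on real sequencing data.

## Numerical conventions

Probability floors at 1e-6 (HMM), MAD consistency factor 1.4826, co-occupancy
fractions rounded to 4 decimals in reports, interval ties broken by
(start, end, name), metaprofile bins split mirror-symmetrically about the
central bin so minus-strand reversal is exact, chromosome-edge windows drop
(never pad) missing positions, and all JSON output is key-sorted with fixed
float formatting for reproducibility.
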