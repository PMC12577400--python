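# coopreg

Multi-omics integration for mapping a transcription factor's regulatory
landscape: chromatin-state annotation of ChIP-seq peaks, direct-target
classification of knockdown DEGs, two-TF co-occupancy, a cooperative-
regulation test on shrunken fold-changes, and mito-stress respirometry
metrics — with a synthetic-data generator that plants ground truth for every
stage.

## Who this is for

Groups integrating TF ChIP-seq with knockdown RNA-seq who want the standard
analysis chain as tested, reusable code rather than one-off scripts:

1. **Chromatin states** — a K-state HMM over binarized marks (product-
   Bernoulli emissions, Baum–Welch EM, posterior decoding) and per-bp
   state-coverage profiles of peak sets against the genome-wide baseline.
2. **Active elements & direct targets** — peaks filtered to elements
   carrying H3K27ac and RNA-PolII evidence, assigned to nearest-TSS genes;
   knockdown DEGs (adjusted p ≤ 0.1) classified as *direct* (bound and
   deregulated) or *indirect*, with cross-cell-line coherence.
3. **TF cooperation** — co-occupancy of two peak sets; per-contrast log2FCs
   shrunk by a normal–normal empirical-Bayes model
   (ŷᵢ = yᵢ·τ²/(τ²+seᵢ²), τ² = max(0, var(y) − mean(se²))); each gene's
   robustly standardized radius r = √(x̃²+ỹ²) compared with the
   independence-null circle √(χ²₀.₉₅(2)) ≈ 2.4477 — co-bound genes outside
   the circle are called cooperatively regulated.
4. **OCR metrics** — basal, ATP-linked, maximal and non-mitochondrial
   respiration from mito-stress traces (oligomycin → FCCP →
   rotenone+antimycin A), normalized per cell, with KD/CTRL folds.

Formats: BED3/BED6/narrowPeak, ChromHMM-style segments.bed, bedGraph,
minimal GTF or a gene TSV, DEG TSVs, long-format OCR TSVs.

## Worked example

Generate a synthetic study (2 Mb genome, 200 genes, 600 TF-A peaks with a
planted 44% co-binding rate and 60% active fraction) and run the whole
pipeline:

```bash
coopreg simulate all --out data --seed 7
coopreg segment   --marks data/marks.yaml --k 3 --seed 7 --out seg
coopreg annotate  --tf data/peaks_a.bed --k27 data/k27.bed \
                  --pol2 data/pol2.bed --genes data/genes.tsv --out annot
coopreg targets   --deg data/deg_a.tsv --chip-map annot/target_map.tsv --out tgt
coopreg cooperate --peaks-a data/peaks_a.bed --peaks-b data/peaks_b.bed \
                  --deg-a data/deg_a.tsv --deg-b data/deg_b.tsv \
                  --genes data/genes.tsv --out coop
coopreg ocr       --traces data/ocr.tsv --out ocr
```

which prints:

```
retained 360/600 peaks (AND); 169 target genes
56 direct / 63 significant DEGs (88.89%)
269/600 co-occupied B peaks (44.83%); 61 cooperative genes
basal OCR fold (KD/CTRL): 1.464
```

Reading these numbers: exactly the planted 60% of peaks carry both activity
marks; 88.9% of significant DEGs are bound (nearest-TSS, no distance cap, so
most genes on the toy genome have a supporting peak); the measured 44.83%
co-occupancy sits inside the binomial band of the planted 44% rate; and the
planted 1.5× basal-respiration fold is recovered as 1.464 from 6 noisy wells
per condition. The same steps are available as library calls — see the
numbered drivers under `analysis/`, which write their tables to `results/`.

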