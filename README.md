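# metskip

Detection of **MET exon 14 skipping** (METΔ14) from RNA-seq reads with
neural networks, plus a discovery arm for non-canonical MET isoforms such
as the LINE1–MET fusion signature.

METΔ14 removes the juxtamembrane exon of the MET receptor tyrosine
kinase, stabilizing the receptor; it is a targetable oncogenic driver in
non-small-cell lung cancer (prevalence ≈ 2.5%). Rather than inferring
splice events from junction sequence, this package classifies *expression
patterns*: the reads overlapping the MET locus (chr7:116672196–116798377,
hg38) are partitioned into random non-overlapping **read groups** of a
fixed size n (default 1000), and each group is summarized as a
fixed-length vector — counts or frequencies of locus-derived k-mers
(k = 16 or 31), or per-base coverage (frequency) over a set of exons,
typically exons 13–15 flanking the skipped exon.

Three architectures operate on these vectors:

* **NN** — dense network `d → 256 → 256 → 128 → 128 → 1`, ReLU + dropout
  0.1 on hidden layers, sigmoid output;
* **CNN** — one 1-D convolution (64 filters, kernel size swept over
  {2, 5, 7, 10, 15, 50, 75, 100, 150, 200}), max-pool 2, dense 50, sigmoid
  output;
* **SCA** — a sparsely connected autoencoder whose latent nodes are the
  MET exons: input feature *i* connects to latent node *j* only if
  feature *i* belongs to exon *j* (mask-enforced at every update), so the
  latent space is a per-exon expression summary used for isoform
  discovery via clustering with a run-to-run stability score.

All models train with Adam (lr 0.01, β₁ 0.9, β₂ 0.999, ε 1e-8, no decay)
on mean-squared error. Cohort metrics follow the benchmark convention:
sensitivity = TP/P, overall specificity = (N−FP)/N, both **truncated** at
the printed precision.

A built-in paired-end (2×150) simulator generates wild-type, Δ14 and
"chimera" (intron-2-peak fusion-like) read sets with per-read truth
alignments, so the whole pipeline runs and is tested fully offline on a
synthetic 21-exon MET-like gene model.

## Worked example

```bash
python examples/classify_skipping.py
```

```
60 read groups of 1000 reads (486 coverage positions each)
held-out AUC: 1.0000
sensitivity: 100.0%  specificity: 100.0%
```

Sixty simulated 1000-read groups (30 wild-type, 30 skipped) are reduced
to 486-dimensional coverage-frequency vectors over exons 13–15; the dense
network separates them perfectly on held-out groups — the Δ14 class has
an identically empty exon-14 coverage block, which is the signal the
network learns.

`examples/benchmark_arithmetic.py` reproduces the published cohort
percentages from the published confusion counts (e.g. the
coverage-frequency NN: 18 predicted, 17 true events → sensitivity 100%,
specificity 99.8%), and `examples/discover_chimera.py` runs the SCA +
repeat-screen discovery arm (latent centroid gap 62.1 vs within-class
spread 1.2; every detected fusion point inside the intron-2 peak window).

A thin CLI wraps the same functions:

```bash
metskip simulate --regime delta14 --pairs 5000 --seed 7 --out d14 --bam
metskip extract --alignment d14.bam --min-reads 5000
metskip run --arch cnn --feature-kind kmer_freq --kernel 100 --outdir run1
```

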