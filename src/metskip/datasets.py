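"""Built-in reference data: a synthetic MET gene fixture and published counts.

The real MET exon table is not redistributable here, so the package ships a
*synthetic* MET-like gene model: 21 exons placed inside the published MET
locus (chr7:116672196-116798377, hg38, 1-based inclusive), with exon 14 at
its real length (141 nt) and an intron 2 wide enough to contain the
published intron-2 coverage-peak window.  The locus sequence is random
(seeded), so every derived quantity — spliced transcripts, k-mer
vocabularies, read simulations — is deterministic and self-contained.
Any operation in this package equally accepts a gene model loaded from a
real GFF3/GTF + FASTA via :func:`metskip.gene_model.load_gene_model`.
"""

from __future__ import annotations

import numpy as np

from .gene_model import ExonModel, GeneModel, GenomicInterval

#: MET locus on hg38, 1-based inclusive (user-facing convention).
MET_LOCUS_REGION = "chr7:116672196-116798377"

#: Intron-2 window where chimera-associated coverage peaks are observed.
INTRON2_PEAK_REGION = "chr7:116715690-116717329"

#: LINE-1 reference region used for the repeat screen (hg38); the shipped
#: screen fixture is a synthetic stand-in for this sequence.
LINE1_REGION = "chr1:62194249-62212928"

#: MET-locus read-pool sizes (reads) per cell line, from the published
#: benchmark table (printed in thousands of reads).
CELL_LINE_MET_READS = {
    "EBC-1": 1_447_000,     # amplified WT MET
    "Hs746T": 846_000,      # amplified MET delta-14
    "A549": 109_000,        # physiological WT MET
    "NCI-H596": 114_000,    # physiological MET delta-14
}

#: Cell-line ground-truth labels.
CELL_LINE_LABELS = {
    "EBC-1": "WT",
    "Hs746T": "delta14",
    "A549": "WT",
    "NCI-H596": "delta14",
}

#: Manually curated TCGA bronchus & lung benchmark: cohort size and number
#: of true exon-14 skipping events found by visual inspection.
BRONCHUS_LUNG_COHORT = {"total": 690, "positives": 17}

#: Reported confusion counts of each trained model on the 690-sample
#: bronchus & lung benchmark: predicted positives and how many of those
#: were true events.  Keys name the architecture and its input
#: representation (scope 13-15 means MET exons 13..15).
REPORTED_BENCHMARK_CALLS = {
    "nn_kmer_freq_full": {"predicted_positive": 4, "true_positive": 1},
    "nn_kmer_freq_13_15": {"predicted_positive": 138, "true_positive": 9},
    "nn_coverage_freq_13_15": {"predicted_positive": 18, "true_positive": 17},
    "cnn_kmer_count_full": {"predicted_positive": 10, "true_positive": 1},
    "cnn_kmer_freq_13_15": {"predicted_positive": 16, "true_positive": 16},
    "cnn_coverage_freq_13_15": {"predicted_positive": 8, "true_positive": 8},
}

# Synthetic MET-like exon layout.  Lengths are typical internal-exon sizes;
# exon 14 is 141 nt (the length of the skipped juxtamembrane exon) and the
# last exon is long (non-coding 3' end).  Intron lengths place intron 2
# around the published peak window and pin the last exon to the locus end.
_EXON_LENGTHS = [
    408, 249, 216, 174, 150, 132, 159, 120, 144, 126,
    117, 165, 129, 141, 216, 138, 153, 111, 126, 120,
]  # exons 1..20; exon 21 is pinned to the locus end
_INTRON_LENGTHS = [
    38897, 9251, 2600, 3100, 2200, 4100, 1800, 2900, 3400, 2100,
    2700, 1900, 3800, 2300, 4700, 2050, 3250, 1850, 2450,
]  # introns 1..19; intron 20 absorbs the remaining span
_LAST_EXON_LENGTH = 4200

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def synthetic_met_gene_model(seed: int = 20210419) -> GeneModel:
    """Build the synthetic 21-exon MET-like gene model (see module docstring).

    Exon/intron coordinates are fixed; only the locus sequence depends on
    ``seed``.  The model is on the plus strand; intron 2 contains the
    published intron-2 peak window, and the locus matches the published MET
    region exactly.
    """
    locus = GenomicInterval.from_region_string(MET_LOCUS_REGION)
    rng = np.random.default_rng(seed)
    locus_seq = _random_sequence(len(locus), rng)

    starts, pos = [], locus.start
    for exon_len, intron_len in zip(_EXON_LENGTHS, _INTRON_LENGTHS + [0]):
        starts.append(pos)
        pos += exon_len + intron_len
    last_start = locus.end - _LAST_EXON_LENGTH
    if last_start <= starts[-1] + _EXON_LENGTHS[-1]:
        raise AssertionError("synthetic layout overflow")
    starts.append(last_start)
    lengths = _EXON_LENGTHS + [_LAST_EXON_LENGTH]

    exons = []
    for ordinal, (s, n) in enumerate(zip(starts, lengths), start=1):
        iv = GenomicInterval(locus.chrom, s, s + n, "+")
        seq = locus_seq[s - locus.start : s + n - locus.start]
        exons.append(ExonModel(ordinal, iv, seq))
    model = GeneModel("MET", "MET-synthetic-201", locus, exons, locus_seq)

    peak = GenomicInterval.from_region_string(INTRON2_PEAK_REGION)
    if not model.intron(2).contains(peak):
        raise AssertionError("synthetic layout must keep the peak window inside intron 2")
    return model


def synthetic_line1_sequence(length: int = 2000, seed: int = 20210419) -> str:
    """Synthetic LINE-1-like repeat sequence for the chimera simulator and
    repeat screen.  A random stand-in for the real repeat consensus; any
    FASTA sequence can be passed to the screen instead."""
    rng = np.random.default_rng([seed, 1])
    return _random_sequence(length, rng)


def intron2_peak_window() -> GenomicInterval:
    """The published intron-2 coverage-peak window as an interval."""
    return GenomicInterval.from_region_string(INTRON2_PEAK_REGION)
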