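"""Paired-end RNA-seq read simulator for the MET locus.

Emulates the four training/test regimes of the benchmark cell lines
(amplified vs physiological expression of wild-type and exon-14-skipped
MET) plus the chimera false-positive class: a fusion-like transcript whose
reads pile up in an intron-2 window, on exon 6, and on the last exon —
the coverage signature attributed to a LINE1-MET fusion.

Fragments are drawn with uniform starts along the source transcript,
Gaussian fragment lengths, and a substitution-only per-base error model;
each read carries its truth genomic alignment through the transcript's
piecewise coordinate map.  Output is deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from . import datasets
from .errors import DataError
from .gene_model import GeneModel, GenomicInterval, reverse_complement
from .read_io import AlignedRead, ReadSet

logger = logging.getLogger(__name__)

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

#: One truth-map segment: transcript [tx_start, tx_end) maps onto a genomic
#: interval, or onto nothing (None) for sequence foreign to the locus.
Segment = tuple[int, int, GenomicInterval | None]


@dataclass
class TranscriptSpec:
    """A source transcript with abundance weight and truth coordinate map."""

    name: str
    sequence: str
    label: str  # WT | delta14 | chimera
    weight: float = 1.0
    truth_map: tuple[Segment, ...] = ()

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise DataError("transcript weight must be >= 0")
        if self.truth_map:
            pos = 0
            for s, e, _iv in self.truth_map:
                if s != pos or e <= s:
                    raise DataError(f"truth map of {self.name} is not contiguous from 0")
                pos = e
            if pos != len(self.sequence):
                raise DataError(f"truth map of {self.name} does not cover the sequence")

    def map_interval(self, a: int, b: int) -> list[tuple[int, int, GenomicInterval | None]]:
        """Pieces of transcript interval [a, b) with their genomic images."""
        out = []
        starts = [s for s, _e, _iv in self.truth_map]
        i = max(0, bisect_right(starts, a) - 1)
        for s, e, iv in self.truth_map[i:]:
            if s >= b:
                break
            lo, hi = max(a, s), min(b, e)
            if lo >= hi:
                continue
            if iv is None:
                out.append((lo, hi, None))
            else:
                off, ln = lo - s, hi - lo
                if iv.strand == "+":
                    g = GenomicInterval(iv.chrom, iv.start + off, iv.start + off + ln, "+")
                else:
                    g = GenomicInterval(iv.chrom, iv.end - off - ln, iv.end - off, "-")
                out.append((lo, hi, g))
        return out


@dataclass
class SimConfig:
    """Sequencing parameters: 2x150 paired-end by default."""

    n_read_pairs: int = 2500
    read_length: int = 150
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.fragment_mean:
            raise DataError("read_length must not exceed fragment_mean")
        if not 0 <= self.error_rate < 0.1:
            raise DataError("error_rate must be in [0, 0.1)")
        if self.n_read_pairs <= 0:
            raise DataError("n_read_pairs must be positive")


# ---------------------------------------------------------------------------
# transcript construction
# ---------------------------------------------------------------------------

def _exon_segments(model: GeneModel, ordinals: list[int]) -> tuple[Segment, ...]:
    segs, pos = [], 0
    for o in ordinals:
        e = model.exon(o)
        segs.append((pos, pos + len(e), e.interval))
        pos += len(e)
    return tuple(segs)


def wt_spec(model: GeneModel, weight: float = 1.0) -> TranscriptSpec:
    ordinals = [e.ordinal for e in model.exons]
    return TranscriptSpec(
        "WT", model.spliced_sequence(), "WT", weight, _exon_segments(model, ordinals)
    )


def delta14_spec(model: GeneModel, skip_exon: int = 14, weight: float = 1.0) -> TranscriptSpec:
    ordinals = [e.ordinal for e in model.exons if e.ordinal != skip_exon]
    return TranscriptSpec(
        f"delta{skip_exon}",
        model.skipped_transcript(skip_exon),
        "delta14",
        weight,
        _exon_segments(model, ordinals),
    )


def chimera_spec(
    model: GeneModel,
    line1_sequence: str | None = None,
    line1_prefix: int = 800,
    intron2_window: GenomicInterval | None = None,
    weight: float = 1.0,
) -> TranscriptSpec:
    """Fusion-like transcript: LINE1-like 5' segment, then the intron-2
    window, exon 6, and the last exon — so its reads reproduce the four
    observed coverage peaks while the LINE1 part stays locus-foreign.

    The fusion breakpoint is the start of ``intron2_window``; it defaults to
    the published peak window when that lies inside the model's intron 2,
    otherwise to the central half of intron 2.
    """
    if line1_sequence is None:
        line1_sequence = datasets.synthetic_line1_sequence()
    if line1_prefix > len(line1_sequence):
        raise DataError("line1_prefix longer than the repeat sequence")
    if intron2_window is None:
        intron2 = model.intron(2)
        published = datasets.intron2_peak_window()
        if intron2.contains(published):
            intron2_window = published
        else:
            quarter = max(1, len(intron2) // 4)
            intron2_window = GenomicInterval(
                intron2.chrom, intron2.start + quarter, intron2.end - quarter, intron2.strand
            )
    window_seq = model.locus_subsequence(intron2_window)
    exon6 = model.exon(6)
    last = model.exons[-1]
    seq = line1_sequence[:line1_prefix] + window_seq + exon6.sequence + last.sequence
    p = line1_prefix
    segs: list[Segment] = [(0, p, None)]
    for piece_len, iv in (
        (len(intron2_window), intron2_window),
        (len(exon6), exon6.interval),
        (len(last), last.interval),
    ):
        segs.append((p, p + piece_len, iv))
        p += piece_len
    return TranscriptSpec("chimera", seq, "chimera", weight, tuple(segs))


def build_transcript_specs(
    model: GeneModel,
    regime: str | dict[str, float],
    skip_exon: int = 14,
    line1_sequence: str | None = None,
    line1_prefix: int = 800,
    intron2_window: GenomicInterval | None = None,
) -> list[TranscriptSpec]:
    """Transcript specs for a regime: ``"WT"``, ``"delta14"``, ``"chimera"``,
    or a mixture given as ``{label: weight}``."""
    weights = {regime: 1.0} if isinstance(regime, str) else dict(regime)
    builders = {
        "WT": lambda w: wt_spec(model, w),
        "delta14": lambda w: delta14_spec(model, skip_exon, w),
        "chimera": lambda w: chimera_spec(model, line1_sequence, line1_prefix, intron2_window, w),
    }
    specs = []
    for label, w in weights.items():
        if label not in builders:
            raise DataError(f"unknown regime {label!r}; expected WT, delta14 or chimera")
        specs.append(builders[label](w))
    return specs


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

def _decode_rows(codes: np.ndarray) -> list[str]:
    flat = _DECODE[codes].tobytes().decode()
    L = codes.shape[1]
    return [flat[i * L : (i + 1) * L] for i in range(codes.shape[0])]


def _truth_for(spec: TranscriptSpec, a: int, b: int):
    """Genomic blocks + genome-forward soft clips for transcript slice [a,b)."""
    pieces = spec.map_interval(a, b)
    blocks = tuple(iv for _s, _e, iv in pieces if iv is not None)
    lead = 0
    trail = 0
    seen_block = False
    for s, e, iv in pieces:
        if iv is None:
            if not seen_block:
                lead += e - s
            else:
                trail += e - s
        else:
            seen_block = True
    return blocks, (lead, trail)


def simulate_reads(
    specs: list[TranscriptSpec],
    config: SimConfig,
    sample_id: str = "sim",
) -> ReadSet:
    """Draw ``n_read_pairs`` fragments across ``specs`` proportionally to
    their weights and sequence both ends (R1 5'-forward, R2 3'-reverse).

    Every read records its truth alignment blocks; reads wholly inside a
    locus-foreign segment are unaligned.  Deterministic for a fixed seed.
    """
    if not specs:
        raise DataError("no transcript specs given")
    w = np.array([s.weight for s in specs], dtype=float)
    if w.sum() <= 0:
        raise DataError("transcript weights must not all be zero")
    rl = config.read_length
    for s in specs:
        if len(s.sequence) < rl:
            raise DataError(f"transcript {s.name} shorter than a read ({len(s.sequence)} < {rl})")

    rng = np.random.default_rng(config.seed)
    spec_idx = rng.choice(len(specs), size=config.n_read_pairs, p=w / w.sum())

    reads: list[AlignedRead] = []
    for si, spec in enumerate(specs):
        pair_ids = np.nonzero(spec_idx == si)[0]
        m = pair_ids.size
        if m == 0:
            continue
        tcodes = _ENCODE[np.frombuffer(spec.sequence.encode(), dtype=np.uint8)]
        L = len(spec.sequence)
        frag = np.clip(
            np.rint(rng.normal(config.fragment_mean, config.fragment_sd, size=m)), rl, L
        ).astype(np.int64)
        starts = (rng.random(m) * (L - frag + 1)).astype(np.int64)
        ends = starts + frag

        offs = np.arange(rl)
        r1 = tcodes[starts[:, None] + offs]
        r2_fwd = tcodes[(ends - rl)[:, None] + offs]
        r2 = 3 - r2_fwd[:, ::-1]  # reverse complement in code space
        if config.error_rate > 0:
            for arr in (r1, r2):
                mask = rng.random(arr.shape) < config.error_rate
                shift = rng.integers(1, 4, size=arr.shape, dtype=np.uint8)
                arr[mask] = (arr[mask] + shift[mask]) % 4
        r1_seqs, r2_seqs = _decode_rows(r1), _decode_rows(r2)

        for j in range(m):
            name = f"{sample_id}:{spec.name}:{pair_ids[j]:07d}"
            a1, b1 = int(starts[j]), int(starts[j]) + rl
            a2, b2 = int(ends[j]) - rl, int(ends[j])
            blocks1, clips1 = _truth_for(spec, a1, b1)
            blocks2, clips2 = _truth_for(spec, a2, b2)
            span1 = (
                GenomicInterval(blocks1[0].chrom, blocks1[0].start, blocks1[-1].end)
                if blocks1
                else None
            )
            span2 = (
                GenomicInterval(blocks2[0].chrom, blocks2[0].start, blocks2[-1].end)
                if blocks2
                else None
            )
            reads.append(
                AlignedRead(name, r1_seqs[j], blocks1, span2, True, spec.label, clips1)
            )
            reads.append(
                AlignedRead(name, r2_seqs[j], blocks2, span1, False, spec.label, clips2)
            )
    label = specs[0].label if len(specs) == 1 else None
    return ReadSet(sample_id, reads, source=f"simulate(seed={config.seed})", label=label)


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def write_truth_sam(readset: ReadSet, model: GeneModel, path: str | Path) -> None:
    """Write simulated reads with their truth alignments as SAM.

    Plus-strand gene models only (the shipped fixture is plus-strand).
    Aligned R2 records carry the reverse flag with genome-forward sequence;
    locus-foreign read parts become soft clips, locus-foreign whole reads
    unmapped records placed at their mate when possible.
    """
    if model.strand != "+":
        raise DataError("truth SAM emission supports plus-strand gene models only")
    chrom = model.locus.chrom
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": model.locus.end + 1000}],
    }
    by_name: dict[str, dict[bool, AlignedRead]] = {}
    for r in readset.reads:
        by_name.setdefault(r.name, {})[r.is_first_in_pair] = r

    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, mates in by_name.items():
            for first in (True, False):
                r = mates.get(first)
                if r is None:
                    continue
                other = mates.get(not first)
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = name
                rec.is_paired = True
                rec.is_read1 = first
                rec.is_read2 = not first
                aligned = r.is_aligned
                mate_aligned = other is not None and other.is_aligned
                rec.is_proper_pair = aligned and mate_aligned
                if aligned:
                    # genome-forward: R2 was sequenced on the reverse strand
                    rec.is_reverse = not first
                    rec.reference_id = 0
                    rec.reference_start = r.blocks[0].start
                    seq = r.sequence if first else reverse_complement(r.sequence)
                    rec.query_sequence = seq
                    cig = []
                    lead, trail = r.soft_clips
                    if lead:
                        cig.append((4, lead))
                    prev_end = None
                    for blk in r.blocks:
                        if prev_end is not None and blk.start > prev_end:
                            cig.append((3, blk.start - prev_end))
                        cig.append((0, len(blk)))
                        prev_end = blk.end
                    if trail:
                        cig.append((4, trail))
                    rec.cigartuples = cig
                else:
                    rec.is_unmapped = True
                    rec.query_sequence = r.sequence
                    if mate_aligned:
                        rec.reference_id = 0
                        rec.reference_start = other.blocks[0].start
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(r.sequence))
                if other is not None:
                    if mate_aligned:
                        rec.next_reference_id = 0
                        rec.next_reference_start = other.blocks[0].start
                        rec.mate_is_reverse = other.is_aligned and first
                    else:
                        rec.mate_is_unmapped = True
                        if aligned:
                            rec.next_reference_id = 0
                            rec.next_reference_start = r.blocks[0].start
                out.write(rec)


def sort_and_index(sam_path: str | Path, bam_path: str | Path) -> Path:
    """Coordinate-sort a SAM/BAM and index the result."""
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return Path(bam_path)
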