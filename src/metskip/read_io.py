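"""Alignment-file input: locus read extraction, coverage filter, half-mapped pairs.

Reads are counted per primary alignment record; secondary and supplementary
records are excluded so multimappers are not double-counted.  A read
"overlaps" the locus when its alignment span shares at least one base with
the locus interval (the extraction region semantics of samtools/IGV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pysam

from .errors import DataError, MetskipError
from .gene_model import GenomicInterval

logger = logging.getLogger(__name__)

#: Minimum locus read count for a sample to enter the analysis.
DEFAULT_MIN_READS = 5000


@dataclass
class AlignedRead:
    """One sequencing read, optionally with its (truth or mapped) alignment.

    ``blocks`` are the match-consuming alignment intervals in genome-forward
    order; an empty tuple means unaligned.  ``mate_span`` is the approximate
    alignment span of the mate (None if the mate is unaligned or absent).
    ``sequence`` is stored as provided by the source (alignment files store
    genome-forward sequence; downstream k-mer matching is orientation-free).
    """

    name: str
    sequence: str
    blocks: tuple[GenomicInterval, ...] = ()
    mate_span: GenomicInterval | None = None
    is_first_in_pair: bool = True
    label: str | None = None
    #: unaligned bases before/after the aligned blocks, genome-forward order
    soft_clips: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"read {self.name!r} has an empty sequence")

    @property
    def is_aligned(self) -> bool:
        return len(self.blocks) > 0

    @property
    def span(self) -> GenomicInterval | None:
        """Full alignment span (first block start to last block end)."""
        if not self.blocks:
            return None
        first, last = self.blocks[0], self.blocks[-1]
        return GenomicInterval(first.chrom, first.start, last.end, first.strand)

    def overlaps(self, locus: GenomicInterval) -> bool:
        span = self.span
        return span is not None and span.overlaps(locus)


@dataclass
class ReadSet:
    """All reads of one sample (or one simulation), the unit the 5000-read
    minimum-coverage filter applies to."""

    sample_id: str
    reads: list[AlignedRead]
    source: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        keys = {(r.name, r.is_first_in_pair) for r in self.reads}
        if len(keys) != len(self.reads):
            raise DataError(f"duplicate (name, mate) read identities in sample {self.sample_id}")

    def __len__(self) -> int:
        return len(self.reads)


def passes_min_reads(readset: ReadSet, threshold: int = DEFAULT_MIN_READS) -> bool:
    """True iff the sample's locus read count reaches ``threshold``."""
    if threshold <= 0:
        raise DataError("threshold must be positive")
    return len(readset) >= threshold


def _merge_blocks(blocks, chrom: str) -> tuple[GenomicInterval, ...]:
    """Collapse abutting pysam match blocks into intervals."""
    merged: list[list[int]] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple(GenomicInterval(chrom, s, e) for s, e in merged if s < e)


def _to_aligned_read(rec: pysam.AlignedSegment) -> AlignedRead | None:
    seq = rec.query_sequence
    if not seq:
        return None
    blocks: tuple[GenomicInterval, ...] = ()
    clips = (0, 0)
    if not rec.is_unmapped:
        blocks = _merge_blocks(rec.get_blocks(), rec.reference_name)
        ct = rec.cigartuples or []
        lead = ct[0][1] if ct and ct[0][0] in (4, 5) else 0
        trail = ct[-1][1] if ct and ct[-1][0] in (4, 5) else 0
        clips = (lead, trail)
    mate_span = None
    if rec.is_paired and not rec.mate_is_unmapped and rec.next_reference_name is not None:
        # only the mate start is recorded in the record; span it by the read length
        mate_span = GenomicInterval(
            rec.next_reference_name, rec.next_reference_start, rec.next_reference_start + len(seq)
        )
    return AlignedRead(
        name=rec.query_name,
        sequence=seq,
        blocks=blocks,
        mate_span=mate_span,
        is_first_in_pair=(not rec.is_paired) or rec.is_read1,
        soft_clips=clips,
    )


def _open_indexed(alignment_path: str | Path) -> pysam.AlignmentFile:
    af = pysam.AlignmentFile(str(alignment_path))
    if not af.has_index():
        af.close()
        raise MetskipError(
            f"{alignment_path}: missing index — coordinate-sort and index the file first"
        )
    return af


def extract_locus_reads(
    alignment_path: str | Path,
    locus: GenomicInterval,
    sample_id: str | None = None,
) -> ReadSet:
    """Extract every primary-alignment read overlapping the locus by >= 1 base.

    Requires a coordinate-sorted, indexed BAM/CRAM.  Secondary and
    supplementary alignments are excluded; duplicate-marked reads are kept.
    """
    sample_id = sample_id or Path(alignment_path).stem
    reads: list[AlignedRead] = []
    skipped = 0
    with _open_indexed(alignment_path) as af:
        for rec in af.fetch(locus.chrom, locus.start, locus.end):
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            ar = _to_aligned_read(rec)
            if ar is None:
                skipped += 1
                continue
            reads.append(ar)
    if skipped:
        logger.warning("%s: skipped %d sequence-less records", alignment_path, skipped)
    return ReadSet(sample_id, reads, source=f"{alignment_path}:{locus.to_region_string()}")


def extract_half_mapped_pairs(
    alignment_path: str | Path,
    locus: GenomicInterval,
) -> list[tuple[AlignedRead, AlignedRead]]:
    """Collect read pairs where exactly one mate overlaps the locus.

    The non-locus mate may be unaligned or aligned elsewhere; these pairs
    are the raw material of the fusion-signature repeat screen.  Orphaned
    records (mate record absent from the file) are skipped and counted.
    """
    by_name: dict[str, dict[bool, tuple[AlignedRead, bool]]] = {}
    with pysam.AlignmentFile(str(alignment_path)) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary or not rec.is_paired:
                continue
            ar = _to_aligned_read(rec)
            if ar is None:
                continue
            by_name.setdefault(rec.query_name, {})[ar.is_first_in_pair] = (
                ar,
                ar.overlaps(locus),
            )
    pairs: list[tuple[AlignedRead, AlignedRead]] = []
    orphans = 0
    for name, mates in by_name.items():
        if len(mates) != 2:
            orphans += 1
            continue
        (r1, in1), (r2, in2) = mates[True], mates[False]
        if in1 != in2:
            locus_read, other = (r1, r2) if in1 else (r2, r1)
            pairs.append((locus_read, other))
    if orphans:
        logger.warning("%s: skipped %d orphaned mate records", alignment_path, orphans)
    return pairs


def write_locus_subset(
    alignment_path: str | Path,
    locus: GenomicInterval,
    out_path: str | Path,
) -> int:
    """Stream the primary locus-overlapping records into a new BAM/SAM.

    Returns the number of records written.  Output mode follows the
    ``out_path`` suffix (.bam binary, anything else SAM text).
    """
    mode = "wb" if str(out_path).endswith(".bam") else "w"
    n = 0
    with _open_indexed(alignment_path) as af:
        with pysam.AlignmentFile(str(out_path), mode, header=af.header) as out:
            for rec in af.fetch(locus.chrom, locus.start, locus.end):
                if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                    continue
                out.write(rec)
                n += 1
    return n


def write_readset_fastq(readset: ReadSet, r1_path: str | Path, r2_path: str | Path) -> int:
    """Write a paired read set as two FASTQ files (R1/R2 matched by name).

    Unpaired reads go to R1.  Returns the number of pairs written.
    """
    firsts = {r.name: r for r in readset.reads if r.is_first_in_pair}
    seconds = {r.name: r for r in readset.reads if not r.is_first_in_pair}
    n_pairs = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for name, r1 in firsts.items():
            f1.write(f"@{name}/1\n{r1.sequence}\n+\n{'I' * len(r1.sequence)}\n")
            r2 = seconds.get(name)
            if r2 is not None:
                f2.write(f"@{name}/2\n{r2.sequence}\n+\n{'I' * len(r2.sequence)}\n")
                n_pairs += 1
    return n_pairs
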