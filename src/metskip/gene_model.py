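"""Gene locus model: exon structure, sequences, and splice products.

Internally every interval is 0-based half-open on genome-forward
coordinates.  User-facing region strings (``chr7:116672196-116798377``)
are 1-based inclusive, the convention used by samtools/IGV.  Exon
sequences are stored transcript-oriented, i.e. reverse-complemented for
minus-strand genes, so splicing is plain concatenation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gffutils
import pyfaidx

from .errors import AnnotationNotFoundError, CoordinateError, DataError

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("chromosome name must be non-empty")
        if not self.start < self.end:
            raise DataError(f"interval start must precede end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise DataError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end), self.strand
        )

    def to_region_string(self) -> str:
        """1-based inclusive ``chrom:start-end`` string."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    @classmethod
    def from_region_string(cls, region: str, strand: str = "+") -> "GenomicInterval":
        """Parse a 1-based inclusive ``chrom:start-end`` region string."""
        m = re.fullmatch(r"(?P<chrom>[^:]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)", region.strip())
        if m is None:
            raise DataError(f"cannot parse region string {region!r}")
        start = int(m["start"].replace(",", ""))
        end = int(m["end"].replace(",", ""))
        return cls(m["chrom"], start - 1, end, strand)


@dataclass(frozen=True)
class ExonModel:
    """One exon: 1-based ordinal along the transcript, interval, sequence."""

    ordinal: int
    interval: GenomicInterval
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise DataError(
                f"exon {self.ordinal}: sequence length {len(self.sequence)} does not match "
                f"interval length {len(self.interval)}"
            )

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class GeneModel:
    """A gene locus with its ordered exons and derived splice products.

    ``exons`` are in transcript order (ordinal 1 first); on the minus
    strand ordinal 1 is the genomically rightmost exon.  ``locus_sequence``
    is the genome-forward sequence of ``locus`` and is optional; it is
    required only by operations that need intronic sequence (e.g. the
    chimera simulator).
    """

    gene_id: str
    transcript_id: str
    locus: GenomicInterval
    exons: list[ExonModel]
    locus_sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise DataError("gene model needs at least one exon")
        ordinals = [e.ordinal for e in self.exons]
        if ordinals != sorted(ordinals) or len(set(ordinals)) != len(ordinals):
            raise DataError("exon ordinals must be strictly increasing")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.interval.overlaps(b.interval):
                raise DataError(f"exons {a.ordinal} and {b.ordinal} overlap")
        for e in self.exons:
            if not self.locus.contains(e.interval):
                raise DataError(f"exon {e.ordinal} not contained in locus {self.locus}")
        if self.locus_sequence is not None and len(self.locus_sequence) != len(self.locus):
            raise DataError("locus_sequence length does not match locus interval")

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, ordinal: int) -> ExonModel:
        for e in self.exons:
            if e.ordinal == ordinal:
                return e
        raise DataError(f"no exon with ordinal {ordinal} (gene has {self.n_exons})")

    @property
    def introns(self) -> list[GenomicInterval]:
        """Genomic gaps between consecutive exons, in transcript order.

        Intron i separates exon i from exon i+1; on the minus strand the
        genomic coordinates of the gap are mirrored accordingly.
        """
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(GenomicInterval(self.locus.chrom, a.interval.end, b.interval.start, "+"))
            else:
                out.append(GenomicInterval(self.locus.chrom, b.interval.end, a.interval.start, "-"))
        return out

    def intron(self, ordinal: int) -> GenomicInterval:
        """Intron i lies between exon i and exon i+1 (1-based)."""
        if not 1 <= ordinal <= self.n_exons - 1:
            raise DataError(f"no intron with ordinal {ordinal}")
        return self.introns[ordinal - 1]

    def locus_subsequence(self, interval: GenomicInterval) -> str:
        """Genome-forward sequence of a sub-interval of the locus."""
        if self.locus_sequence is None:
            raise DataError("gene model carries no locus sequence")
        if not self.locus.contains(interval):
            raise CoordinateError(f"{interval} not contained in locus {self.locus}")
        off = interval.start - self.locus.start
        return self.locus_sequence[off : off + len(interval)]

    def spliced_sequence(self, exon_ordinals: Sequence[int] | None = None) -> str:
        """Concatenation of the named exons' sequences in transcript order."""
        if exon_ordinals is None:
            exon_ordinals = [e.ordinal for e in self.exons]
        ordinals = list(exon_ordinals)
        if ordinals != sorted(ordinals):
            raise DataError("exon ordinals must be ascending")
        return "".join(self.exon(o).sequence for o in ordinals)

    def skipped_transcript(self, skipped_ordinal: int = 14) -> str:
        """Full spliced transcript with one internal exon removed."""
        first, last = self.exons[0].ordinal, self.exons[-1].ordinal
        if skipped_ordinal in (first, last):
            raise DataError(
                f"exon {skipped_ordinal} is terminal; only internal exons can be skipped"
            )
        self.exon(skipped_ordinal)  # validates existence
        return self.spliced_sequence(
            [e.ordinal for e in self.exons if e.ordinal != skipped_ordinal]
        )

    def transcript_length(self) -> int:
        return sum(len(e) for e in self.exons)


# ---------------------------------------------------------------------------
# annotation / genome I/O
# ---------------------------------------------------------------------------

def _fasta_offset(record) -> int:
    """0-based offset declared in a FASTA header (``offset=N``), else 0.

    Locus-slice FASTA bundles written by :func:`write_gene_model` store the
    absolute genomic start of the slice this way, so that annotation
    coordinates stay absolute.
    """
    m = re.search(r"offset=(\d+)", getattr(record, "long_name", "") or "")
    return int(m.group(1)) if m else 0


def _fetch_sequence(fasta: pyfaidx.Fasta, interval: GenomicInterval) -> str:
    if interval.chrom not in fasta:
        raise CoordinateError(f"coordinate error: chromosome {interval.chrom!r} not in genome")
    rec = fasta[interval.chrom]
    off = _fasta_offset(rec)
    lo, hi = interval.start - off, interval.end - off
    if lo < 0 or hi > len(rec):
        raise CoordinateError(
            f"coordinate error: {interval.to_region_string()} outside available sequence "
            f"for {interval.chrom} (offset {off}, length {len(rec)})"
        )
    return str(rec[lo:hi]).upper()


def _exon_features(db: gffutils.FeatureDB, transcript_id: str):
    feats = []
    for f in db.features_of_type("exon"):
        attrs = f.attributes
        parents = [p.split(":")[-1] for p in attrs.get("Parent", [])]
        tids = [t.split(":")[-1] for t in attrs.get("transcript_id", [])]
        if transcript_id in parents or transcript_id in tids:
            feats.append(f)
    return feats


def load_gene_model(
    annotation_path: str | Path,
    genome_path: str | Path,
    gene_id: str,
    transcript_id: str,
    locus: GenomicInterval | None = None,
    keep_locus_sequence: bool = True,
) -> GeneModel:
    """Build a :class:`GeneModel` from a GFF3/GTF annotation and a FASTA genome.

    Only exon features belonging to ``transcript_id`` are used.  The locus
    defaults to the transcript span; pass ``locus`` to widen it (e.g. to a
    published locus definition).  Minus-strand exon sequences are returned
    reverse-complemented (transcript orientation) and ordinals follow
    transcript order.
    """
    db = gffutils.create_db(
        str(annotation_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    feats = _exon_features(db, transcript_id)
    if not feats:
        raise AnnotationNotFoundError(
            f"annotation not found: no exons for transcript {transcript_id!r} "
            f"(gene {gene_id!r}) in {annotation_path}"
        )
    strand = feats[0].strand if feats[0].strand in ("+", "-") else "+"
    ivals = sorted(
        (GenomicInterval(f.seqid, f.start - 1, f.end, strand) for f in feats),
        key=lambda iv: iv.start,
    )
    if len({iv.chrom for iv in ivals}) != 1:
        raise DataError("transcript exons span multiple chromosomes")
    span = GenomicInterval(ivals[0].chrom, ivals[0].start, ivals[-1].end, strand)
    if locus is None:
        locus = span
    elif not locus.contains(span):
        raise DataError(f"locus override {locus} does not contain transcript span {span}")

    fasta = pyfaidx.Fasta(str(genome_path), sequence_always_upper=True)
    try:
        tx_order = ivals if strand == "+" else ivals[::-1]
        exons = []
        for ordinal, iv in enumerate(tx_order, start=1):
            seq = _fetch_sequence(fasta, iv)
            if strand == "-":
                seq = reverse_complement(seq)
            exons.append(ExonModel(ordinal, iv, seq))
        locus_seq = _fetch_sequence(fasta, locus) if keep_locus_sequence else None
    finally:
        fasta.close()
    return GeneModel(gene_id, transcript_id, locus, exons, locus_seq)


def write_gene_model(model: GeneModel, gff3_path: str | Path, fasta_path: str | Path) -> None:
    """Write a gene model as a GFF3 excerpt plus a locus-slice FASTA.

    The FASTA record holds only the locus sequence but declares its absolute
    genomic start with an ``offset=`` header tag, so the GFF3 keeps absolute
    coordinates and :func:`load_gene_model` round-trips exactly.
    """
    if model.locus_sequence is None:
        raise DataError("cannot write a gene model without its locus sequence")
    chrom, strand = model.locus.chrom, model.strand
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"{chrom}\tmetskip\tgene\t{model.locus.start + 1}\t{model.locus.end}\t.\t{strand}\t.\t"
            f"ID=gene:{model.gene_id}\n"
        )
        fh.write(
            f"{chrom}\tmetskip\tmRNA\t{model.exons[0].interval.start + 1 if strand == '+' else model.exons[-1].interval.start + 1}"
            f"\t{model.exons[-1].interval.end if strand == '+' else model.exons[0].interval.end}\t.\t{strand}\t.\t"
            f"ID=transcript:{model.transcript_id};Parent=gene:{model.gene_id}\n"
        )
        for e in model.exons:
            fh.write(
                f"{chrom}\tmetskip\texon\t{e.interval.start + 1}\t{e.interval.end}\t.\t{strand}\t.\t"
                f"ID=exon:{model.transcript_id}.{e.ordinal};Parent=transcript:{model.transcript_id}\n"
            )
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom} offset={model.locus.start}\n")
        seq = model.locus_sequence
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
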