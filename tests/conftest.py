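"""Shared fixtures: toy gene bundles on disk, the synthetic MET model, and
session-scoped simulated read sets (expensive to regenerate per test)."""

from __future__ import annotations

from pathlib import Path

import pytest

from metskip import datasets, simulate, subsampling
from metskip.gene_model import ExonModel, GeneModel, GenomicInterval


def write_gene_bundle(
    tmpdir: Path,
    genome_seq: str,
    exon_coords: list[tuple[int, int]],
    strand: str = "+",
    chrom: str = "chrT",
    gene_id: str = "TOY",
    transcript_id: str = "TOY-1",
) -> tuple[Path, Path]:
    """Write a minimal GFF3 + FASTA pair for a single-transcript toy gene."""
    gff = tmpdir / "toy.gff3"
    fasta = tmpdir / "toy.fa"
    lines = ["##gff-version 3"]
    lo = min(s for s, _ in exon_coords)
    hi = max(e for _, e in exon_coords)
    lines.append(
        f"{chrom}\ttest\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\tID=gene:{gene_id}"
    )
    lines.append(
        f"{chrom}\ttest\tmRNA\t{lo + 1}\t{hi}\t.\t{strand}\t.\t"
        f"ID=transcript:{transcript_id};Parent=gene:{gene_id}"
    )
    for i, (s, e) in enumerate(exon_coords, 1):
        lines.append(
            f"{chrom}\ttest\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
            f"ID=exon:{transcript_id}.{i};Parent=transcript:{transcript_id}"
        )
    gff.write_text("\n".join(lines) + "\n")
    fasta.write_text(f">{chrom}\n{genome_seq}\n")
    return gff, fasta


def toy_gene_model(
    genome_seq: str,
    exon_coords: list[tuple[int, int]],
    chrom: str = "chrT",
    locus: tuple[int, int] | None = None,
) -> GeneModel:
    """Build a plus-strand in-memory toy gene model directly."""
    lo = locus[0] if locus else 0
    hi = locus[1] if locus else len(genome_seq)
    exons = [
        ExonModel(i, GenomicInterval(chrom, s, e), genome_seq[s:e])
        for i, (s, e) in enumerate(exon_coords, 1)
    ]
    return GeneModel(
        "TOY", "TOY-1", GenomicInterval(chrom, lo, hi), exons, genome_seq[lo:hi]
    )


@pytest.fixture(scope="session")
def met_model():
    return datasets.synthetic_met_gene_model()


@pytest.fixture(scope="session")
def line1_seq():
    return datasets.synthetic_line1_sequence()


@pytest.fixture(scope="session")
def wt_readset(met_model):
    specs = simulate.build_transcript_specs(met_model, "WT")
    cfg = simulate.SimConfig(n_read_pairs=5000, error_rate=0.0, seed=101)
    return simulate.simulate_reads(specs, cfg, sample_id="wt")


@pytest.fixture(scope="session")
def d14_readset(met_model):
    specs = simulate.build_transcript_specs(met_model, "delta14")
    cfg = simulate.SimConfig(n_read_pairs=5000, error_rate=0.0, seed=102)
    return simulate.simulate_reads(specs, cfg, sample_id="d14")


@pytest.fixture(scope="session")
def chimera_readset(met_model, line1_seq):
    specs = simulate.build_transcript_specs(met_model, "chimera", line1_sequence=line1_seq)
    cfg = simulate.SimConfig(n_read_pairs=3000, error_rate=0.0, seed=103)
    return simulate.simulate_reads(specs, cfg, sample_id="chim")


@pytest.fixture(scope="session")
def wt_groups(wt_readset):
    return subsampling.partition_reads(wt_readset, 1000, seed=7)


@pytest.fixture(scope="session")
def d14_groups(d14_readset):
    return subsampling.partition_reads(d14_readset, 1000, seed=7)
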