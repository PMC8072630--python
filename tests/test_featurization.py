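"""Vocabulary construction, k-mer counting (vs a brute-force oracle),
coverage vectors, frequency normalization, and schema-checked I/O."""

import numpy as np
import pytest

from metskip import featurization as fz
from metskip.errors import DataError, SchemaMismatchError
from metskip.gene_model import reverse_complement
from metskip.read_io import AlignedRead
from metskip.subsampling import ReadGroup

from conftest import toy_gene_model


def group_of(seqs, blocks=None, group_id="g0", label="unknown"):
    reads = [
        AlignedRead(f"r{i}", s, blocks=tuple(b) if blocks else ())
        for i, (s, b) in enumerate(zip(seqs, blocks or [()] * len(seqs)))
    ]
    return ReadGroup(group_id, reads, size=len(reads), parent_sample="s", label=label)


def brute_force_kmer_counts(seqs, vocab_kmers, k):
    """Independent dictionary oracle for the both-orientation counting rule."""
    counts = {km: 0 for km in vocab_kmers}
    for s in seqs:
        for probe in (s, reverse_complement(s)):
            for i in range(len(probe) - k + 1):
                w = probe[i : i + k]
                if w in counts:
                    counts[w] += 1
    return np.array([counts[km] for km in vocab_kmers], dtype=float)


class TestVocabulary:
    def test_sliding_window_first_occurrence_order(self):
        m = toy_gene_model("ACGTAC", [(0, 6)])
        v = fz.build_vocabulary(m, k=3, scope=(1,), include_skip_junction=False)
        assert v.kmers == ["ACG", "CGT", "GTA", "TAC"]

    def test_repeated_kmers_deduplicated(self):
        m = toy_gene_model("AAAAA", [(0, 5)])
        v = fz.build_vocabulary(m, k=3, scope=(1,), include_skip_junction=False)
        assert v.kmers == ["AAA"]

    def test_skip_junction_adds_exactly_the_novel_junction_kmers(self, met_model):
        k = 16
        base = fz.build_vocabulary(met_model, k, (13, 14, 15), include_skip_junction=False)
        aug = fz.build_vocabulary(met_model, k, (13, 14, 15), include_skip_junction=True)
        # brute-force enumeration of the skipped-junction windows
        e13, e15 = met_model.exon(13).sequence, met_model.exon(15).sequence
        junction = e13[-(k - 1):] + e15[: k - 1]
        junction_kmers = {junction[i : i + k] for i in range(len(junction) - k + 1)}
        expected_novel = junction_kmers - set(base.kmers)
        assert set(aug.kmers) - set(base.kmers) == expected_novel
        assert aug.kmers[: len(base.kmers)] == base.kmers

    def test_scope_shorter_than_k_rejected(self):
        m = toy_gene_model("ACGTAC", [(0, 4)])
        with pytest.raises(DataError, match="shorter than k"):
            fz.build_vocabulary(m, k=10, scope=(1,))

    def test_vocabulary_hash_tracks_content(self, met_model):
        a = fz.build_vocabulary(met_model, 16, (13, 14, 15))
        b = fz.build_vocabulary(met_model, 16, (13, 14, 15))
        c = fz.build_vocabulary(met_model, 16, (13, 15))
        assert a.hash == b.hash != c.hash


class TestKmerFeatures:
    def test_single_read_identical_to_vocabulary_source(self):
        m = toy_gene_model("ACGTAC", [(0, 6)])
        v = fz.build_vocabulary(m, k=3, scope=(1,), include_skip_junction=False)
        fv = fz.kmer_features(group_of(["ACGTAC"]), v)
        # forward windows hit every slot once; GTA's revcomp TAC adds one more
        # to TAC and vice versa: counting follows the both-orientation rule
        oracle = brute_force_kmer_counts(["ACGTAC"], v.kmers, 3)
        assert np.array_equal(fv.values, oracle)

    def test_reverse_complement_read_gives_identical_vector(self):
        m = toy_gene_model("ACGTACGGTT", [(0, 10)])
        v = fz.build_vocabulary(m, k=4, scope=(1,), include_skip_junction=False)
        fwd = fz.kmer_features(group_of(["ACGTACGGTT"]), v)
        rev = fz.kmer_features(group_of([reverse_complement("ACGTACGGTT")]), v)
        assert np.array_equal(fwd.values, rev.values)

    def test_matches_brute_force_oracle_on_simulated_reads(self, met_model, wt_groups):
        v = fz.build_vocabulary(met_model, 16, (13, 14, 15))
        reads = [r.sequence for r in wt_groups[0].reads[:100]]
        g = group_of(reads)
        fv = fz.kmer_features(g, v)
        assert np.array_equal(fv.values, brute_force_kmer_counts(reads, v.kmers, 16))

    def test_reads_shorter_than_k_contribute_nothing(self):
        m = toy_gene_model("ACGTACGGTT", [(0, 10)])
        v = fz.build_vocabulary(m, k=4, scope=(1,), include_skip_junction=False)
        fv = fz.kmer_features(group_of(["ACG", "ACGTACGGTT"]), v)
        only = fz.kmer_features(group_of(["ACGTACGGTT"]), v)
        assert np.array_equal(fv.values, only.values)

    def test_total_count_bounded_by_window_budget(self, met_model, wt_groups):
        v = fz.build_vocabulary(met_model, 16, (13, 14, 15))
        g = wt_groups[0]
        fv = fz.kmer_features(g, v)
        budget = sum(2 * (len(r.sequence) - 16 + 1) for r in g.reads)
        assert fv.values.sum() <= budget

    def test_read_permutation_invariance(self, met_model, wt_groups):
        v = fz.build_vocabulary(met_model, 16, (13, 14, 15))
        seqs = [r.sequence for r in wt_groups[0].reads[:200]]
        a = fz.kmer_features(group_of(seqs), v)
        b = fz.kmer_features(group_of(seqs[::-1]), v)
        assert np.array_equal(a.values, b.values)


class TestToFrequency:
    def test_normalizes_to_unit_sum(self):
        fv = fz.FeatureVector("kmer_count", (1,), np.array([2.0, 2.0, 4.0]), "g")
        freq = fz.to_frequency(fv)
        assert freq.kind == "kmer_freq"
        assert np.allclose(freq.values, [0.25, 0.25, 0.5])
        assert abs(freq.values.sum() - 1.0) < 1e-12

    def test_all_zero_passes_through_with_warning(self):
        fv = fz.FeatureVector("coverage", (1,), np.zeros(3), "g")
        freq = fz.to_frequency(fv)
        assert freq.warning and np.array_equal(freq.values, np.zeros(3))

    def test_frequency_of_frequency_rejected(self):
        fv = fz.FeatureVector("kmer_freq", (1,), np.array([1.0]), "g")
        with pytest.raises(DataError):
            fz.to_frequency(fv)


class TestCoverageFeatures:
    def test_single_read_block_increments_expected_positions(self):
        from metskip.gene_model import GenomicInterval

        m = toy_gene_model("A" * 30, [(8, 20)])
        g = group_of(["ACGT"], blocks=[[GenomicInterval("chrT", 10, 14)]])
        fv = fz.coverage_features(g, m, scope=(1,))
        expected = np.zeros(12)
        expected[2:6] = 1
        assert np.array_equal(fv.values, expected)

    def test_delta14_groups_have_identically_zero_exon14_block(self, met_model, d14_groups):
        sl = fz.exon_block_slices(met_model, (13, 14, 15))[14]
        for g in d14_groups[:3]:
            fv = fz.coverage_features(g, met_model, (13, 14, 15))
            assert np.all(fv.values[sl] == 0)

    def test_wt_groups_cover_exon14(self, met_model, wt_groups):
        sl = fz.exon_block_slices(met_model, (13, 14, 15))[14]
        fv = fz.coverage_features(wt_groups[0], met_model, (13, 14, 15))
        assert fv.values[sl].mean() > 0

    def test_conservation_total_equals_overlap_bases(self, met_model, wt_groups):
        scope = (13, 14, 15)
        g = wt_groups[0]
        fv = fz.coverage_features(g, met_model, scope)
        overlap = 0
        for r in g.reads:
            for blk in r.blocks:
                for o in scope:
                    iv = met_model.exon(o).interval
                    overlap += max(0, min(blk.end, iv.end) - max(blk.start, iv.start))
        assert fv.values.sum() == overlap

    def test_unaligned_group_warns_and_zeroes(self, met_model):
        g = group_of(["ACGT" * 10, "TTTT" * 10])
        fv = fz.coverage_features(g, met_model, (13, 14, 15))
        assert fv.warning and fv.values.sum() == 0


class TestAttributionAndIO:
    def test_coverage_attribution_matches_block_lengths(self, met_model):
        scope = (13, 14, 15)
        attrib = fz.feature_exon_attribution("coverage", met_model, scope)
        lengths = {o: sum(1 for a in attrib if a == (o,)) for o in scope}
        assert lengths == {o: len(met_model.exon(o)) for o in scope}

    def test_junction_kmers_attributed_to_both_flanks(self, met_model):
        v = fz.build_vocabulary(met_model, 16, (13, 14, 15), include_skip_junction=True)
        attrib = fz.feature_exon_attribution("kmer_count", met_model, (13, 14, 15), v)
        base = fz.build_vocabulary(met_model, 16, (13, 14, 15), include_skip_junction=False)
        novel = attrib[len(base.kmers):]
        assert novel and all(a == (13, 15) for a in novel)

    def test_matrix_round_trip_with_schema(self, tmp_path):
        fvs = [
            fz.FeatureVector("coverage", (1,), np.array([1.0, 2.0, 0.5]), f"g{i}")
            for i in range(4)
        ]
        schema = fz.feature_schema("coverage", (1,), 3)
        path = tmp_path / "X.tsv"
        fz.write_feature_matrix(fvs, path, schema, labels=["WT", "WT", "delta14", "delta14"])
        ids, X, labels, schema2 = fz.load_feature_matrix(path)
        assert ids == [f"g{i}" for i in range(4)]
        assert labels == ["WT", "WT", "delta14", "delta14"]
        assert np.allclose(X, np.array([[1.0, 2.0, 0.5]] * 4))
        assert fz.schema_digest(schema2) == fz.schema_digest(schema)

    def test_dimension_mismatch_with_schema_rejected(self, tmp_path):
        fvs = [fz.FeatureVector("coverage", (1,), np.array([1.0, 2.0]), "g0")]
        schema = fz.feature_schema("coverage", (1,), 3)  # wrong on purpose
        path = tmp_path / "bad.tsv"
        fz.write_feature_matrix(fvs, path, schema)
        with pytest.raises(SchemaMismatchError):
            fz.load_feature_matrix(path)
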