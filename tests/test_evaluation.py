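"""Confusion arithmetic against the published benchmark counts, ROC vs a
Mann-Whitney oracle, normalization, clustering stability, repeat screen."""

import numpy as np
import pytest

from metskip import datasets, evaluation as ev
from metskip.errors import DataError
from metskip.gene_model import GenomicInterval, reverse_complement
from metskip.read_io import AlignedRead


def cs(total, positives, predicted, tp):
    return ev.ConfusionSummary(total, positives, predicted, tp)


class TestConfusionArithmetic:
    """The printed benchmark percentages, recomputed from the printed counts
    with truncation at the printed precision."""

    BENCH = datasets.BRONCHUS_LUNG_COHORT

    def test_prevalence_of_curated_cohort(self):
        c = cs(self.BENCH["total"], self.BENCH["positives"], 0, 0)
        assert ev.prevalence_pct(c, 2) == 2.46

    @pytest.mark.parametrize(
        "model_key,sens_dec,sens,spec_dec,spec",
        [
            ("nn_kmer_freq_full", 2, 5.88, 1, 99.5),
            ("nn_kmer_freq_13_15", 1, 52.9, 1, 81.3),
            ("nn_coverage_freq_13_15", 0, 100.0, 1, 99.8),
            ("cnn_kmer_freq_13_15", 2, 94.11, 0, 100.0),
            ("cnn_coverage_freq_13_15", 2, 47.05, 0, 100.0),
        ],
    )
    def test_benchmark_sensitivity_and_overall_specificity(
        self, model_key, sens_dec, sens, spec_dec, spec
    ):
        calls = datasets.REPORTED_BENCHMARK_CALLS[model_key]
        c = cs(
            self.BENCH["total"],
            self.BENCH["positives"],
            calls["predicted_positive"],
            calls["true_positive"],
        )
        assert ev.sensitivity_pct(c, sens_dec) == sens
        assert ev.specificity_overall_pct(c, spec_dec) == spec

    def test_truncation_not_rounding(self):
        # 16/17 = 94.117...% -> 94.11 (rounding would print 94.12)
        c = cs(690, 17, 16, 16)
        assert ev.sensitivity_pct(c, 2) == 94.11
        # (690-1)/690 = 99.855...% -> 99.8 (rounding would print 99.9)
        assert ev.specificity_overall_pct(cs(690, 17, 18, 17), 1) == 99.8

    def test_sensitivity_edges(self):
        assert ev.sensitivity_pct(cs(690, 17, 17, 17), 0) == 100.0
        assert ev.sensitivity_pct(cs(690, 17, 0, 0), 1) == 0.0
        with pytest.raises(DataError):
            ev.sensitivity_pct(cs(10, 0, 0, 0))

    def test_specificity_variants_agree_when_no_positives_exist(self):
        c = cs(100, 0, 7, 0)
        assert ev.specificity_overall_pct(c) == ev.specificity_classical_pct(c) == 93.0

    def test_zero_false_positives_is_full_specificity(self):
        assert ev.specificity_overall_pct(cs(690, 17, 10, 10)) == 100.0

    def test_invariant_violations_rejected(self):
        with pytest.raises(DataError):
            cs(10, 20, 0, 0)
        with pytest.raises(DataError):
            cs(10, 5, 3, 4)

    def test_from_calls_counts(self):
        labels = ["delta14", "WT", "delta14", "WT"]
        calls = ["delta14", "delta14", "WT", "WT"]
        c = ev.ConfusionSummary.from_calls(labels, calls)
        assert (c.total, c.positives, c.predicted_positive, c.true_positive) == (4, 2, 2, 1)
        assert c.false_positive == 1


def brute_force_auc(scores, labels):
    """Mann-Whitney identity: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        r = ev.roc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(400)
        labels = rng.integers(0, 2, 400)
        assert abs(ev.roc(scores, labels).auc - 0.5) < 0.1

    def test_matches_mann_whitney_oracle_on_random_points(self):
        rng = np.random.default_rng(5)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        r = ev.roc(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(3)
        r = ev.roc(rng.random(100), rng.integers(0, 2, 100))
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            ev.roc([0.1, 0.9], [1, 1])


class TestNormalizeLatentInput:
    def test_zero_variance_feature_becomes_zero(self):
        # constant row sums keep column 0 constant through the frequency step
        X = np.column_stack(
            [np.full(10, 3.0), np.arange(10, dtype=float), 20.0 - np.arange(10)]
        )
        Z = ev.normalize_latent_input(X)
        assert np.all(Z[:, 0] == 0)

    def test_columns_standardized(self):
        X = np.abs(np.random.default_rng(0).normal(size=(50, 8)))
        Z = ev.normalize_latent_input(X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-9)

    def test_sample_order_preserved(self):
        X = np.abs(np.random.default_rng(1).normal(size=(10, 4)))
        Z1 = ev.normalize_latent_input(X)
        Z2 = ev.normalize_latent_input(X.copy())
        assert np.array_equal(Z1, Z2)

    def test_negative_input_rejected(self):
        with pytest.raises(DataError):
            ev.normalize_latent_input(np.array([[-1.0, 2.0]]))


def blobs(n_per=40, k=3, sep=12.0, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(k, dim)) * sep
    return np.vstack([rng.normal(size=(n_per, dim)) + c for c in centers])


class TestClusteringAndStability:
    def test_well_separated_blobs_recover_k3_in_all_runs(self):
        X = blobs()
        results = ev.cluster_latent(X, k_candidates=(2, 3, 4, 5), n_runs=5, seed=1)
        assert all(r.k == 3 for r in results)

    def test_duplicate_rows_share_a_cluster(self):
        X = np.vstack([blobs(), blobs()[:1]])  # row 0 duplicated at the end
        res = ev.cluster_latent(X, k_candidates=(3,), n_runs=2, seed=0)[0]
        assert res.assignments[0] == res.assignments[-1]

    def test_runs_carry_distinct_seeds(self):
        X = blobs()
        results = ev.cluster_latent(X, k_candidates=(3,), n_runs=5, seed=9)
        assert len({r.seed for r in results}) == 5

    def test_identical_partitions_score_exactly_one(self):
        a = np.array([0] * 10 + [1] * 10)
        results = [ev.ClusterResult(a.copy(), 2, i) for i in range(4)]
        s = ev.cluster_stability(results)
        assert s.overall == 1.0
        assert all(v == 1.0 for v in s.per_cluster.values())

    def test_one_random_run_degrades_overall_stability(self):
        a = np.array([0] * 10 + [1] * 10)
        rng = np.random.default_rng(2)
        structured = [ev.ClusterResult(a.copy(), 2, i) for i in range(3)]
        noisy = structured + [ev.ClusterResult(rng.integers(0, 2, 20), 2, 99)]
        assert ev.cluster_stability(noisy).overall < ev.cluster_stability(structured).overall

    def test_blobs_stable_noise_unstable(self):
        Xb = blobs()
        rb = ev.cluster_latent(Xb, k_candidates=(2, 3, 4, 5), n_runs=6, seed=3)
        assert ev.cluster_stability(rb).overall > 0.9
        Xn = np.random.default_rng(4).uniform(size=(120, 10))
        rn = ev.cluster_latent(Xn, k_candidates=(2, 3, 4, 5), n_runs=6, seed=3)
        assert ev.cluster_stability(rn).overall < ev.cluster_stability(rb).overall

    def test_mismatched_sample_sets_rejected(self):
        results = [
            ev.ClusterResult(np.zeros(5, dtype=int), 1, 0),
            ev.ClusterResult(np.zeros(6, dtype=int), 1, 1),
        ]
        with pytest.raises(DataError):
            ev.cluster_stability(results)


class TestRepeatScreen:
    REPEAT = datasets.synthetic_line1_sequence()

    def locus_read(self, name="p1", start=116715700):
        return AlignedRead(
            name, "A" * 50, blocks=(GenomicInterval("chr7", start, start + 50),)
        )

    def test_exact_substring_mate_is_a_hit(self):
        mate = AlignedRead("p1", self.REPEAT[100:200], is_first_in_pair=False)
        hits = ev.repeat_screen([(self.locus_read(), mate)], self.REPEAT, k=31)
        assert len(hits) == 1
        assert hits[0].fusion_point == 116715701  # 1-based locus anchor

    def test_reverse_complement_mate_is_a_hit(self):
        mate = AlignedRead(
            "p1", reverse_complement(self.REPEAT[100:200]), is_first_in_pair=False
        )
        assert len(ev.repeat_screen([(self.locus_read(), mate)], self.REPEAT, k=31)) == 1

    def test_random_mate_shares_no_31mer(self):
        rng = np.random.default_rng(8)
        mate_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        # brute-force cross-check: no common 31-mer between mate and repeat
        mate_kmers = {mate_seq[i : i + 31] for i in range(len(mate_seq) - 30)}
        rc = reverse_complement(mate_seq)
        mate_kmers |= {rc[i : i + 31] for i in range(len(rc) - 30)}
        repeat_kmers = {self.REPEAT[i : i + 31] for i in range(len(self.REPEAT) - 30)}
        assert not (mate_kmers & repeat_kmers)
        mate = AlignedRead("p1", mate_seq, is_first_in_pair=False)
        assert ev.repeat_screen([(self.locus_read(), mate)], self.REPEAT, k=31) == []

    def test_empty_pair_list_is_empty_result(self):
        assert ev.repeat_screen([], self.REPEAT, k=31) == []

    def test_simulated_chimera_yields_hits_inside_intron2_window(
        self, met_model, chimera_readset
    ):
        by_name = {}
        for r in chimera_readset.reads:
            by_name.setdefault(r.name, []).append(r)
        pairs = []
        for mates in by_name.values():
            aligned = [r for r in mates if r.is_aligned]
            unaligned = [r for r in mates if not r.is_aligned]
            if len(aligned) == 1 and len(unaligned) == 1:
                pairs.append((aligned[0], unaligned[0]))
        hits = ev.repeat_screen(pairs, self.REPEAT, k=31)
        assert hits
        window = datasets.intron2_peak_window()
        assert all(window.start < h.fusion_point <= window.end for h in hits)
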