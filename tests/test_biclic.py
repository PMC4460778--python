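"""Bicluster search: average PCC, seeding, expansion, optimization, driver."""

import itertools

import numpy as np
import pytest

from transcoex.biclic import (
    Bicluster,
    BiclicParams,
    PreconditionError,
    avg_pcc,
    exhaustive_biclusters,
    expand_genes,
    expand_samples,
    find_seeds,
    optimize_bicluster,
    run_biclic,
    sample_seed_clusters,
)
from transcoex.synthetic import BatchSpec, PlantedModule, SyntheticConfig, generate_dataset

from conftest import make_matrix


def avg_pcc_oracle(arr):
    """Direct pairwise computation via numpy.corrcoef."""
    vals = []
    for i, j in itertools.combinations(range(arr.shape[0]), 2):
        if arr[i].std() == 0 or arr[j].std() == 0:
            vals.append(0.0)
        else:
            vals.append(np.corrcoef(arr[i], arr[j])[0, 1])
    return float(np.mean(vals))


class TestAvgPcc:
    def test_perfect_linear_relation(self):
        m = make_matrix([[1, 2, 3], [2, 4, 6]])
        assert avg_pcc(m, m.gene_ids, m.sample_ids) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        m = make_matrix([[1, 2, 3], [3, 2, 1]])
        assert avg_pcc(m, m.gene_ids, m.sample_ids) == pytest.approx(-1.0)

    def test_three_gene_hand_case(self):
        m = make_matrix([[1, 2, 3], [1, 3, 2], [2, 1, 3]])
        assert avg_pcc(m, m.gene_ids, m.sample_ids) == pytest.approx(1 / 6)

    def test_matches_direct_pairwise_oracle(self, rng):
        arr = rng.normal(size=(6, 10))
        m = make_matrix(arr)
        assert avg_pcc(m, m.gene_ids, m.sample_ids) == pytest.approx(
            avg_pcc_oracle(arr), abs=1e-12
        )

    def test_zero_variance_gene_contributes_zero(self):
        m = make_matrix([[1, 2, 3], [2, 4, 6], [5, 5, 5]])
        # pairs: (g0,g1)=1, (g0,g2)=0, (g1,g2)=0
        assert avg_pcc(m, m.gene_ids, m.sample_ids) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("genes,samples", [(1, 3), (2, 2)])
    def test_preconditions(self, genes, samples):
        m = make_matrix(np.arange(12.0).reshape(3, 4))
        with pytest.raises(PreconditionError):
            avg_pcc(m, m.gene_ids[:genes], m.sample_ids[:samples])


class TestSeedClusters:
    def test_exact_division(self, rng):
        m = make_matrix(rng.normal(size=(10, 3)))
        groups = sample_seed_clusters(m, m.sample_ids[0], BiclicParams())
        assert [len(g) for g in groups] == [5, 5]

    def test_trailing_singleton_dropped(self, rng):
        m = make_matrix(rng.normal(size=(11, 3)))
        groups = sample_seed_clusters(m, m.sample_ids[0], BiclicParams())
        assert [len(g) for g in groups] == [5, 5]

    def test_grouping_depends_only_on_ranks(self, rng):
        arr = rng.normal(size=(13, 3))
        m1 = make_matrix(arr)
        m2 = make_matrix(np.exp(arr))  # rank-preserving transform
        p = BiclicParams(seed_window=4)
        s = m1.sample_ids[1]
        assert sample_seed_clusters(m1, s, p) == sample_seed_clusters(m2, s, p)


class TestFindSeeds:
    def exact_params(self, **kw):
        return BiclicParams(seed_span=None, **kw)

    def test_recurring_cluster_becomes_seed(self):
        clusters = {
            "s1": [{"a", "b"}],
            "s2": [{"a", "b"}],
            "s3": [{"a", "b"}],
            "s4": [{"c", "d"}],
        }
        seeds = find_seeds(clusters, self.exact_params())
        assert len(seeds) == 1
        assert seeds[0].genes == {"a", "b"}
        assert seeds[0].samples == {"s1", "s2", "s3"}

    def test_two_sample_support_is_not_enough(self):
        clusters = {"s1": [{"a", "b"}], "s2": [{"a", "b"}], "s3": [{"x", "y"}]}
        assert find_seeds(clusters, self.exact_params()) == []

    def test_exact_mode_equals_bruteforce_incidence(self, rng):
        m = make_matrix(rng.normal(size=(20, 10)))
        params = self.exact_params()
        clusters = {s: sample_seed_clusters(m, s, params) for s in m.sample_ids}
        seeds = find_seeds(clusters, params)
        # brute force: every (gene set, sample) incidence counted directly
        incidence = {}
        for s, groups in clusters.items():
            for g in groups:
                incidence.setdefault(frozenset(g), set()).add(s)
        expected = {
            (genes, frozenset(samples))
            for genes, samples in incidence.items()
            if len(samples) >= params.min_samples
        }
        assert {(s.genes, s.samples) for s in seeds} == expected

    def test_span_mode_accepts_shifted_windows(self):
        # same genes cluster tightly in s2/s3 although split across windows
        clusters = {
            "s1": [{"a", "b", "c"}, {"d", "e", "f"}],
            "s2": [{"x", "a", "b"}, {"c", "d", "e"}, {"f", "y", "z"}],
            "s3": [{"a", "c", "b"}, {"q", "r", "t"}],
            "s4": [{"q", "r", "t"}, {"a", "x", "y"}],
        }
        params = BiclicParams(seed_window=3, seed_span=2.0, min_genes=3)
        seeds = find_seeds(clusters, params)
        assert any(
            s.genes == {"a", "b", "c"} and {"s1", "s2", "s3"} <= s.samples
            for s in seeds
        )


class TestExpansion:
    def colinear_matrix(self, n_genes, n_samples, rng, noise=0.0):
        f = rng.normal(size=n_samples)
        arr = np.tile(f, (n_genes, 1))
        if noise:
            arr = arr + rng.normal(0, noise, size=arr.shape)
        return make_matrix(arr)

    def test_colinear_candidate_accepted(self, rng):
        m = self.colinear_matrix(6, 8, rng)
        seed = Bicluster(frozenset(m.gene_ids[:3]), frozenset(m.sample_ids), 1.0)
        out = expand_genes(m, seed, BiclicParams())
        assert out == set(m.gene_ids)
        assert avg_pcc(m, out, m.sample_ids) == pytest.approx(1.0)

    def test_anticorrelated_candidate_rejected(self, rng):
        f = rng.normal(size=8)
        arr = np.vstack([f, f, f, -f])
        m = make_matrix(arr)
        seed = Bicluster(frozenset(m.gene_ids[:3]), frozenset(m.sample_ids), 1.0)
        out = expand_genes(m, seed, BiclicParams())
        assert out == set(m.gene_ids[:3])

    def test_gene_cap_stops_at_max_genes(self, rng):
        m = self.colinear_matrix(51, 6, rng)
        seed = Bicluster(frozenset(m.gene_ids[:2]), frozenset(m.sample_ids), 1.0)
        out = expand_genes(m, seed, BiclicParams())
        assert len(out) == 50

    def test_pattern_consistent_sample_accepted_and_no_cap(self, rng):
        m = self.colinear_matrix(4, 30, rng)
        seed = Bicluster(frozenset(m.gene_ids), frozenset(m.sample_ids[:3]), 1.0)
        out = expand_samples(m, seed, BiclicParams())
        assert out == set(m.sample_ids)  # every consistent sample added

    def test_correlation_breaking_sample_rejected(self, rng):
        f = rng.normal(size=7)
        arr = np.tile(f, (4, 1))
        arr[:, 6] = [5.0, -5.0, 5.0, -5.0]  # breaks all pairwise correlation
        m = make_matrix(arr)
        seed = Bicluster(frozenset(m.gene_ids), frozenset(m.sample_ids[:3]), 1.0)
        out = expand_samples(m, seed, BiclicParams())
        assert m.sample_ids[6] not in out
        assert set(m.sample_ids[:6]) == out


class TestOptimize:
    def test_space_already_above_threshold_returned_unchanged(self, rng):
        f = rng.normal(size=6)
        m = make_matrix(np.tile(f, (4, 1)))
        out = optimize_bicluster(m, m.gene_ids, m.sample_ids, BiclicParams())
        assert out.genes == set(m.gene_ids)
        assert out.samples == set(m.sample_ids)
        assert out.avg_pcc == pytest.approx(1.0)

    def test_poison_gene_removed_matches_exhaustive_oracle(self, rng):
        f = rng.normal(size=6)
        arr = np.tile(f, (5, 1))
        arr[4] = -f  # poison: perfectly anti-correlated with the block
        m = make_matrix(arr)
        params = BiclicParams()
        out = optimize_bicluster(m, m.gene_ids, m.sample_ids, params)
        assert out.genes == set(m.gene_ids[:4])
        assert out.samples == set(m.sample_ids)
        # exhaustive search over all subsets confirms this is sample-optimal
        best = max(
            exhaustive_biclusters(m, params),
            key=lambda b: (len(b.samples), len(b.genes)),
        )
        assert len(out.samples) >= len(best.samples)

    def test_greedy_sample_count_vs_exhaustive_on_random_spaces(self, rng):
        """Greedy keeps at least as many samples as the exhaustive optimum
        in most random <=6x6 spaces; shortfalls are reported, not hidden."""
        params = BiclicParams(pcc_threshold=0.75)
        shortfalls = 0
        comparisons = 0
        for trial in range(12):
            f = rng.normal(size=6)
            arr = np.tile(f, (4, 1)) + rng.normal(0, 0.6, size=(4, 6))
            m = make_matrix(arr)
            greedy = optimize_bicluster(m, m.gene_ids, m.sample_ids, params)
            hits = exhaustive_biclusters(m, params)
            if greedy is None or not hits:
                continue
            comparisons += 1
            best = max(len(b.samples) for b in hits)
            if len(greedy.samples) < best:
                shortfalls += 1
        assert comparisons >= 5
        assert shortfalls <= comparisons // 2  # greedy is near-optimal, logged

    def test_unreachable_threshold_discards_seed(self, rng):
        m = make_matrix(rng.normal(size=(2, 3)) * 0 + [[1, 1, 1], [0, 5, 0]])
        params = BiclicParams()
        assert optimize_bicluster(m, m.gene_ids, m.sample_ids, params) is None


def small_recovery_config(within, seed, n_members=30, n_bg=40):
    return SyntheticConfig(
        n_background_genes=n_bg,
        batches=(BatchSpec("b1", {"MS": n_members, "CTRL": 3}),),
        modules=(PlantedModule("M", 10, frozenset({"MS"}), within),),
        noise_sd=0.25,
        seed=seed,
    )


class TestRunBiclic:
    def jaccard(self, a, b):
        return len(a & b) / len(a | b)

    def test_noiseless_module_recovered_at_high_jaccard(self):
        matrix, truth = generate_dataset(small_recovery_config(1.0, seed=5))
        bics = run_biclic(matrix, BiclicParams())
        tg, ts = set(truth.genes_of("M")), set(truth.samples_of("M"))
        best = max(
            min(self.jaccard(b.genes, tg), self.jaccard(b.samples, ts)) for b in bics
        )
        assert best >= 0.9

    def test_noisy_module_recovered_at_median_jaccard(self):
        scores = []
        for seed in range(20):
            matrix, truth = generate_dataset(small_recovery_config(0.8, seed=seed))
            bics = run_biclic(matrix, BiclicParams())
            tg, ts = set(truth.genes_of("M")), set(truth.samples_of("M"))
            best = max(
                (
                    min(self.jaccard(b.genes, tg), self.jaccard(b.samples, ts))
                    for b in bics
                ),
                default=0.0,
            )
            scores.append(best)
        assert np.median(scores) >= 0.6

    def test_output_contracts_on_pure_noise(self, rng):
        m = make_matrix(rng.normal(size=(80, 40)))
        params = BiclicParams()
        for b in run_biclic(m, params):
            assert b.avg_pcc >= params.pcc_threshold - 1e-9
            assert params.min_genes <= len(b.genes) <= params.max_genes
            assert len(b.samples) >= params.min_samples
            recomputed = avg_pcc(m, b.genes, b.samples)
            assert b.avg_pcc == pytest.approx(recomputed, abs=1e-9)

    def test_sample_order_permutation_invariance(self, rng):
        matrix, _ = generate_dataset(small_recovery_config(1.0, seed=2, n_bg=25))
        perm = rng.permutation(matrix.n_samples)
        shuffled = matrix.subset(samples=[matrix.sample_ids[i] for i in perm])
        a = {(b.genes, b.samples) for b in run_biclic(matrix, BiclicParams())}
        b = {(b.genes, b.samples) for b in run_biclic(shuffled, BiclicParams())}
        assert a == b
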