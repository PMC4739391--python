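import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from barcode_gauge import divergence as div
from barcode_gauge.distances import DistanceMatrix


def matrix_from_pairs(ids, species, pairs):
    n = len(ids)
    d = np.zeros((n, n))
    for (i, j), v in pairs.items():
        d[i, j] = d[j, i] = v
    return DistanceMatrix(ids=ids, species=species, d=d)


class TestDivergenceParameters:
    def test_all_zero(self):
        dm = matrix_from_pairs(list("abcd"), ["s1", "s1", "s2", "s2"], {})
        s = div.divergence_parameters(dm)
        for name in ("theta", "coalescent_depth", "all_intra",
                     "theta_prime", "min_inter", "all_inter"):
            assert getattr(s, name).mean == 0.0

    def test_two_by_two_hand_enumeration(self):
        # 2 species x 2 accessions: both intra pairs 0.01, all 4 inter pairs 0.10
        ids = ["a1", "a2", "b1", "b2"]
        species = ["s1", "s1", "s2", "s2"]
        pairs = {(0, 1): 0.01, (2, 3): 0.01}
        for i in (0, 1):
            for j in (2, 3):
                pairs[(i, j)] = 0.10
        s = div.divergence_parameters(matrix_from_pairs(ids, species, pairs))
        assert s.theta.mean == pytest.approx(0.01)
        assert s.all_intra.mean == pytest.approx(0.01)
        assert s.coalescent_depth.mean == pytest.approx(0.01)
        assert s.theta_prime.mean == pytest.approx(0.10)
        assert s.min_inter.mean == pytest.approx(0.10)
        assert s.all_inter.mean == pytest.approx(0.10)
        for name in ("theta", "coalescent_depth", "all_intra",
                     "theta_prime", "min_inter", "all_inter"):
            assert getattr(s, name).sd == pytest.approx(0.0)

    def test_per_species_definitions(self):
        # species s1 = {0, 1}, s2 = {2}; intra(s1) pairs: 0.02
        # inter pairs: (0,2)=0.06, (1,2)=0.10
        dm = matrix_from_pairs(
            ["a1", "a2", "b1"], ["s1", "s1", "s2"],
            {(0, 1): 0.02, (0, 2): 0.06, (1, 2): 0.10})
        s = div.divergence_parameters(dm)
        assert s.theta.mean == pytest.approx(0.02)
        assert s.theta.n == 1  # only s1 has >= 2 accessions
        # theta_prime per species: s1 -> mean(.06,.10)=.08 ; s2 -> same pairs
        assert s.theta_prime.mean == pytest.approx(0.08)
        assert s.min_inter.mean == pytest.approx(0.06)
        assert s.all_inter.mean == pytest.approx(0.08)

    def test_single_accession_species_skips_intra(self):
        dm = matrix_from_pairs(["a", "b"], ["s1", "s2"], {(0, 1): 0.1})
        s = div.divergence_parameters(dm)
        assert s.all_intra.n == 0 and math.isnan(s.all_intra.mean)
        assert s.all_inter.mean == pytest.approx(0.1)

    def test_intra_never_exceeds_coalescent_depth(self, sim_small_dm):
        s = div.divergence_parameters(sim_small_dm)
        assert s.all_intra.mean <= s.coalescent_depth.mean + 1e-12

    def test_requires_two_species(self):
        dm = matrix_from_pairs(["a", "b"], ["s1", "s1"], {(0, 1): 0.1})
        with pytest.raises(ValueError):
            div.divergence_parameters(dm)


class TestBarcodingGap:
    def test_clean_gap_zero_overlap(self):
        dm = matrix_from_pairs(
            ["a1", "a2", "b1", "b2"], ["s1", "s1", "s2", "s2"],
            {(0, 1): 0.0, (2, 3): 0.0, (0, 2): .1, (0, 3): .1,
             (1, 2): .1, (1, 3): .1})
        gp = div.barcoding_gap(dm)
        assert gp.overlap == 0.0
        assert gp.intra_histogram.sum() == 2
        assert gp.inter_histogram.sum() == 4

    def test_identical_distributions_full_overlap(self, rng):
        # intra and inter distances drawn from one distribution
        n = 40
        ids = [f"x{i}" for i in range(n)]
        species = ["s1", "s1"] + ["s%d" % i for i in range(2, n)]
        d = np.zeros((n, n))
        vals = rng.uniform(0.01, 0.05, size=n * (n - 1) // 2)
        iu = np.triu_indices(n, 1)
        d[iu] = vals
        d += d.T
        dm = DistanceMatrix(ids=ids, species=species, d=d)
        gp = div.barcoding_gap(dm)
        assert gp.overlap > 0.9  # ~0.95 within sampling error

    def test_histogram_counts_sum_to_pairs(self, sim_small_dm):
        gp = div.barcoding_gap(sim_small_dm)
        intra = div.intraspecific_distances(sim_small_dm)
        inter = div.interspecific_distances(sim_small_dm)
        assert gp.intra_histogram.sum() == intra.size
        assert gp.inter_histogram.sum() == inter.size


def oracle_exact_p(diffs):
    """Full 2^n sign enumeration with naive midranks (independent oracle)."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    if n == 0:
        return 1.0, 0.0
    absd = sorted((abs(x), i) for i, x in enumerate(d))
    ranks = [0.0] * n
    i = 0
    pos = 1
    while i < len(absd):
        j = i
        while j < len(absd) and absd[j][0] == absd[i][0]:
            j += 1
        mid = (pos + (pos + (j - i) - 1)) / 2.0
        for k in range(i, j):
            ranks[absd[k][1]] = mid
        pos += j - i
        i = j
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    mu = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2 ** n, w_obs


class TestWilcoxon:
    def test_equal_samples(self):
        r = div.wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert r.p_value == 1.0 and r.direction == "equal" and r.n == 0

    def test_all_positive_differences(self):
        r = div.wilcoxon_signed_rank([2, 4, 6, 8, 10], [1, 2, 3, 4, 5])
        assert r.w_plus == 15 and r.w_minus == 0
        assert r.p_value == pytest.approx(0.0625)
        assert r.direction == "greater"

    def test_rank_sum_identity(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 15))
            x = rng.integers(-5, 6, size=n).astype(float)
            r = div.wilcoxon_signed_rank(x, np.zeros(n))
            m = r.n
            assert r.w_plus + r.w_minus == pytest.approx(m * (m + 1) / 2)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 11))
            x = rng.integers(-4, 5, size=n).astype(float)
            r = div.wilcoxon_signed_rank(x, np.zeros(n))
            p_oracle, w_oracle = oracle_exact_p(x)
            if r.n == 0:
                assert r.p_value == 1.0
            else:
                assert r.w_plus == pytest.approx(w_oracle)
                assert r.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        x = np.array([1.3, -0.8, 2.1, 0.4, -1.9, 3.3, 0.9, -0.2])
        r = div.wilcoxon_signed_rank(x, np.zeros_like(x))
        ref = sps.wilcoxon(x, alternative="two-sided", mode="exact")
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_normal_approximation(self, rng):
        x = rng.normal(0.3, 1.0, size=60)
        r = div.wilcoxon_signed_rank(x, np.zeros_like(x))
        ref = sps.wilcoxon(x, alternative="two-sided", correction=True,
                           mode="approx")
        assert 0 <= r.p_value <= 1
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_direction_from_median_sign(self):
        r = div.wilcoxon_signed_rank([0.5, 0.6, -0.1], [0, 0, 0])
        assert r.direction == "greater"
        r = div.wilcoxon_signed_rank([-0.5, -0.6, 0.1], [0, 0, 0])
        assert r.direction == "less"


class TestCompareLoci:
    def _dm(self, scale, n=12, seed=5):
        rng = np.random.default_rng(seed)
        ids = [f"x{i}" for i in range(n)]
        species = [f"s{i // 2}" for i in range(n)]
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(0.01, 0.1, size=iu[0].size) * scale
        d += d.T
        return DistanceMatrix(ids=ids, species=species, d=d)

    def test_identical_loci_equal(self):
        dm = self._dm(1.0)
        table = div.compare_loci({"A": dm, "B": dm}, mode="inter")
        assert list(table["result"]) == ["A = B"]

    def test_doubled_distances_detected(self):
        a = self._dm(1.0)
        b = self._dm(2.0)  # same pairs, doubled
        table = div.compare_loci({"A": a, "B": b}, mode="inter")
        row = table.iloc[0]
        assert row["result"] == "A < B"
        assert row["p_value"] < 0.05
        assert row["n"] >= 20

    def test_antisymmetry(self):
        a, b = self._dm(1.0), self._dm(2.0)
        t1 = div.compare_loci({"A": a, "B": b}, mode="inter").iloc[0]
        t2 = div.compare_loci({"B": b, "A": a}, mode="inter").iloc[0]
        assert t1["p_value"] == pytest.approx(t2["p_value"])
        assert t1["result"] == "A < B" and t2["result"] == "B > A"
        assert t1["w_plus"] == t2["w_minus"]

    def test_underpowered_flagged(self):
        a = self._dm(1.0, n=4)
        b = self._dm(2.0, n=4)
        table = div.compare_loci({"A": a, "B": b}, mode="intra")
        assert table.iloc[0]["result"] == "underpowered"
        assert math.isnan(table.iloc[0]["p_value"])

    def test_intra_mode_pairs_only_conspecifics(self):
        a, b = self._dm(1.0), self._dm(2.0)
        table = div.compare_loci({"A": a, "B": b}, mode="intra")
        assert table.iloc[0]["n"] == 6  # 6 species x 1 conspecific pair


class TestOrderedLociRecovery:
    def test_simulated_loci_with_ordered_divergence(self):
        """Three loci simulated at increasing divergence on identical
        accession ids must come back in the constructed order."""
        import barcode_gauge.synthetic as syn
        from barcode_gauge.align import progressive_msa
        from barcode_gauge.distances import distance_matrix

        dms = {}
        for locus, inter in (("low", 0.02), ("mid", 0.05), ("high", 0.09)):
            cfg = syn.SimulationConfig(n_species=4, accessions_per_species=3,
                                       root_length=250, target_intra=0.004,
                                       target_inter=inter, seed=3,
                                       indel_rate=0.0, locus="other")
            sim = syn.simulate_dataset(cfg)
            msa = progressive_msa(sim.dataset)
            dms[locus] = distance_matrix(msa, sim.dataset.species)
        table = div.compare_loci(dms, mode="inter")
        verdicts = dict(zip(zip(table["locus_a"], table["locus_b"]),
                            table["result"]))
        assert verdicts[("low", "mid")] == "low < mid"
        assert verdicts[("low", "high")] == "low < high"
        assert verdicts[("mid", "high")] == "mid < high"
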