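"""Meiosis/ascus simulator: exactness of the crossover chain, Haldane
consistency, arrangement models, determinism, and the truth channel."""

import itertools

import numpy as np
import pytest
from scipy.stats import poisson

from octadkit import sim
from octadkit.analysis import TetradCounts, adjacent_discordance, perkins_distance, tally_tetrads
from octadkit.io import CrossDef, MarkerDef, write_octad_table


def cross_at(d_cM, arm="left"):
    """Two markers on one arm: locA at the centromere, locB at d cM."""
    return CrossDef(
        markers=(
            MarkerDef("locA", "chr1", "left", 0.0, "A", "a"),
            MarkerDef("locB", "chr1", arm, d_cM, "B", "b"),
        )
    )


# ---------------------------------------------------------------------------
# crossover-chain exactness


def brute_force_state_distribution(k):
    """Oracle: distribution over chromatid-origin states after exactly k
    crossovers, enumerating all 4^k chromatid choices."""
    counts = {s: 0.0 for s in sim.STATES}
    for choices in itertools.product(range(4), repeat=k):
        v = [0, 0, 1, 1]
        for c in choices:
            i, j = c // 2, 2 + c % 2
            v[i], v[j] = v[j], v[i]
        counts[tuple(v)] += 1.0
    total = 4.0 ** k
    return {s: c / total for s, c in counts.items()}


class TestCrossoverChain:
    @pytest.mark.parametrize("k", [0, 1, 2, 3, 4])
    def test_swap_matrix_power_matches_enumeration(self, k):
        Mk = np.linalg.matrix_power(sim._single_swap_matrix(), k)
        start = sim.STATES.index((0, 0, 1, 1))
        oracle = brute_force_state_distribution(k)
        for si, s in enumerate(sim.STATES):
            assert Mk[start, si] == pytest.approx(oracle[s], abs=1e-12)

    def test_interval_matrix_is_poisson_mixture_of_swaps(self):
        d = 0.2  # Morgans
        P = sim._interval_matrix(d)
        S = sim._single_swap_matrix()
        mix = np.zeros((6, 6))
        for k in range(60):
            mix += poisson.pmf(k, 2 * d) * np.linalg.matrix_power(S, k)
        assert np.allclose(P, mix, atol=1e-10)

    def test_tetrad_class_probs_consistent_with_haldane_r(self):
        # recombinant-spore fraction r = TT/2 + NPD must equal the Haldane
        # map function at every distance
        for d in (0.5, 5, 20, 48.2, 120):
            p = sim.tetrad_class_probs(d)
            assert p["PD"] + p["NPD"] + p["TT"] == pytest.approx(1.0)
            assert p["TT"] / 2 + p["NPD"] == pytest.approx(sim.haldane_r(d), abs=1e-9)


# ---------------------------------------------------------------------------
# meiosis-level properties


class TestMeiosis:
    def test_centromeric_marker_never_shows_second_division_segregation(self):
        origin, sds = sim.simulate_meioses(cross_at(25.0), 5000, 1)
        assert not sds[:, 0].any()  # locA at 0 cM
        assert sds[:, 1].mean() > 0.1  # locB at 25 cM does recombine

    def test_every_meiosis_segregates_2_2(self):
        origin, _ = sim.simulate_meioses(cross_at(30.0), 2000, 2)
        assert (origin.sum(axis=1) == 2).all()

    def test_empirical_recombination_matches_haldane(self):
        # moderate size here; the full-scale check lives in the acceptance suite
        n = 20000
        for d in (10.0, 48.2):
            origin, _ = sim.simulate_meioses(cross_at(d), n, 3)
            rec = (origin[:, :, 0] != origin[:, :, 1]).astype(float)
            per_meiosis = rec.mean(axis=1)
            emp = per_meiosis.mean()
            se = per_meiosis.std(ddof=1) / np.sqrt(n)
            assert abs(emp - sim.haldane_r(d)) < 3 * se

    def test_recombination_is_additive_across_the_centromere(self):
        # markers on opposite arms at 10 + 20 cM separate like one 30 cM interval
        cross = CrossDef(
            markers=(
                MarkerDef("locA", "chr1", "left", 10.0, "A", "a"),
                MarkerDef("locB", "chr1", "right", 20.0, "B", "b"),
            )
        )
        n = 20000
        origin, _ = sim.simulate_meioses(cross, n, 4)
        rec = (origin[:, :, 0] != origin[:, :, 1]).astype(float)
        per_meiosis = rec.mean(axis=1)
        se = per_meiosis.std(ddof=1) / np.sqrt(n)
        assert abs(per_meiosis.mean() - sim.haldane_r(30.0)) < 3 * se

    def test_single_meiosis_wrapper(self, cross):
        products, sds = sim.simulate_meiosis(cross, 5)
        assert len(products) == 4
        assert set(sds) == set(cross.marker_names)
        for j, m in enumerate(cross.markers):
            alleles = sorted(p[j] for p in products)
            assert alleles == sorted([m.allele_p1, m.allele_p2] * 2)


# ---------------------------------------------------------------------------
# ascus packing


def enumeration_mean_discordant_fraction():
    """Oracle: mean discordant fraction of adjacent pairs over ALL
    arrangements of 4 distinct sister pairs into 8 positions."""
    template = (0, 0, 1, 1, 2, 2, 3, 3)
    arrangements = set(itertools.permutations(template))
    total, disc = 0, 0
    for arr in arrangements:
        for i in (0, 2, 4, 6):
            total += 1
            disc += arr[i] != arr[i + 1]
    return disc / total


class TestPacking:
    def test_linear_ordered_sisters_are_adjacent(self):
        products = [("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")]
        spores, sisters = sim.pack_ascus(products, "linear_ordered")
        assert spores == (
            ("A", "B"), ("A", "B"), ("A", "b"), ("A", "b"),
            ("a", "B"), ("a", "B"), ("a", "b"), ("a", "b"),
        )
        assert sisters == (("A", "B"), ("C", "D"), ("E", "F"), ("G", "H"))

    def test_parallel_puts_nonsisters_at_the_ends(self):
        products = [("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")]
        spores, sisters = sim.pack_ascus(products, "parallel")
        # nucleus order (1a, 2a, 2b, 1b): ends come from nuclei 1a and 1b
        assert spores[0] == products[0] and spores[7] == products[1]
        assert set(sisters) == {("A", "B"), ("G", "H"), ("C", "D"), ("E", "F")}

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown arrangement"):
            sim.pack_ascus([("A",)] * 4, "zigzag")

    @pytest.mark.parametrize("model", ["linear_ordered", "random_nuclei"])
    def test_daughters_adjacent_models_give_zero_discordance(self, cross, model):
        config = sim.SimConfig(cross=cross, n_asci=1000, arrangement=model, seed=5)
        counts = sim.simulate_null_discordance(config, 1)
        assert counts[0] == 0

    def test_random_spores_concordance_approaches_one_seventh(self, cross):
        oracle = enumeration_mean_discordant_fraction()
        assert oracle == pytest.approx(6 / 7)
        config = sim.SimConfig(
            cross=cross, n_asci=4000, arrangement="random_spores", seed=6
        )
        arrays = sim.simulate_octad_arrays(config)
        po = arrays["product_origin"]
        distinct = np.array(
            [len({tuple(po[i, p]) for p in range(4)}) == 4 for i in range(po.shape[0])]
        )
        so = arrays["spore_origin"][distinct]
        disc = (so[:, 0::2, :] != so[:, 1::2, :]).any(axis=2)
        per_ascus = disc.mean(axis=1)
        emp = per_ascus.mean()
        se = per_ascus.std(ddof=1) / np.sqrt(len(per_ascus))
        assert abs(emp - oracle) < 3 * se

    def test_arrangement_separation(self, cross):
        means = {}
        for model in ("linear_ordered", "random_nuclei", "random_spores"):
            config = sim.SimConfig(cross=cross, n_asci=500, arrangement=model, seed=7)
            means[model] = sim.simulate_null_discordance(config, 1)[0]
        assert means["linear_ordered"] == 0
        assert means["random_nuclei"] == 0
        assert means["random_spores"] > 0


# ---------------------------------------------------------------------------
# full-cross simulation contracts


class TestSimulateCross:
    def test_identical_seed_gives_byte_identical_tsv(self, cross, tmp_path):
        config = sim.SimConfig(cross=cross, n_asci=50, arrangement="random_spores",
                               viability=0.9, seed=42)
        paths = []
        for name in ("a.tsv", "b.tsv"):
            out = tmp_path / name
            write_octad_table(sim.simulate_cross(config).table, out)
            paths.append(out)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_growing_n_asci_preserves_earlier_asci(self, cross):
        small = sim.simulate_cross(
            sim.SimConfig(cross=cross, n_asci=20, arrangement="random_spores", seed=9)
        ).table
        big = sim.simulate_cross(
            sim.SimConfig(cross=cross, n_asci=60, arrangement="random_spores", seed=9)
        ).table
        assert big.octads[:20] == small.octads

    def test_full_viability_conserves_alleles_4_4(self, cross):
        config = sim.SimConfig(cross=cross, n_asci=1000, arrangement="random_spores",
                               seed=10)
        arrays = sim.simulate_octad_arrays(config)
        assert (arrays["spore_origin"].sum(axis=1) == 4).all()

    def test_dead_spores_unknown_in_observed_channel(self, cross):
        config = sim.SimConfig(cross=cross, n_asci=200, arrangement="linear_ordered",
                               viability=0.8, seed=11, emit_truth=True)
        result = sim.simulate_cross(config)
        n_dead = 0
        for octad in result.table.octads:
            for s in octad.spores:
                if not s.viable:
                    n_dead += 1
                    assert set(s.genotype) == {"?"}
        assert 0 < n_dead < 8 * 200
        # truth channel always carries full genotypes
        for rec in result.truth:
            for g in rec.products:
                assert "?" not in g

    def test_simulated_tetrad_counts_match_haldane_expectation(self):
        # 84 asci as in the published mat1-mrc1 tally, many replicates:
        # mean PD:NPD:TT should sit near the closed-form class probabilities
        d = perkins_distance(TetradCounts(38, 7, 39))
        cross = cross_at(d)
        n_reps, n_asci = 300, 84
        rng = np.random.default_rng(12)
        totals = np.zeros(3)
        for _ in range(n_reps):
            origin, _ = sim.simulate_meioses(cross, n_asci, rng)
            totals += sim.classify_product_origins(origin, 0, 1)
        probs = sim.tetrad_class_probs(d)
        n = n_reps * n_asci
        for cls, idx in (("PD", 0), ("NPD", 1), ("TT", 2)):
            emp = totals[idx] / n
            se = np.sqrt(probs[cls] * (1 - probs[cls]) / n)
            assert abs(emp - probs[cls]) < 4 * se

    def test_array_classification_agrees_with_object_pipeline(self, cross):
        config = sim.SimConfig(cross=cross, n_asci=200, arrangement="random_spores",
                               seed=13)
        arrays = sim.simulate_octad_arrays(config)
        table = sim.simulate_cross(config).table
        ia, ib = cross.index("mat1"), cross.index("mrc1")
        fast = sim.classify_product_origins(arrays["product_origin"], ia, ib)
        slow = tally_tetrads(table, "mat1", "mrc1")
        assert fast == (slow.pd, slow.npd, slow.tt)

    def test_null_discordance_scaling(self, cross):
        config = sim.SimConfig(cross=cross, n_asci=9, arrangement="random_spores",
                               seed=14)
        counts = sim.simulate_null_discordance(config, 500)
        assert counts.shape == (500,)
        assert 0 < counts.mean() < 36

    def test_invalid_config_rejected(self, cross):
        with pytest.raises(ValueError):
            sim.SimConfig(cross=cross, n_asci=0)
        with pytest.raises(ValueError):
            sim.SimConfig(cross=cross, n_asci=1, viability=1.5)
        with pytest.raises(ValueError):
            sim.SimConfig(cross=cross, n_asci=1, arrangement="zigzag")
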