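"""Sister-spore matching, dead-spore imputation, and tetrad reduction."""

import itertools

import pytest

from octadkit import sim
from octadkit.analysis import match_sisters, reduce_to_tetrad
from octadkit.io import MendelianError, SisterMatchError

from conftest import make_octad


def brute_force_products(genotypes):
    """Oracle: all product multisets from perfect matchings of 8 spores
    into 4 genotype-identical pairs (None = dead/wildcard)."""
    idx = list(range(8))
    results = set()

    def pairings(rest):
        if not rest:
            yield []
            return
        a = rest[0]
        for k in range(1, len(rest)):
            b = rest[k]
            for tail in pairings(rest[1:k] + rest[k + 1:]):
                yield [(a, b)] + tail

    for pairing in pairings(idx):
        products = []
        ok = True
        for a, b in pairing:
            ga, gb = genotypes[a], genotypes[b]
            if ga is None and gb is None:
                ok = False  # would need an undeducible genotype
                break
            if ga is not None and gb is not None and ga != gb:
                ok = False
                break
            products.append(ga if ga is not None else gb)
        if ok:
            results.add(tuple(sorted(products)))
    return results


class TestImputationOnFixture:
    def test_ascus5_dead_C_imputed_as_M_plus_plus_plus(self, table):
        pairing = match_sisters(table.octad("5"))
        assert pairing.imputed == (("C", ("M", "+", "+", "+")),)
        assert not pairing.ambiguous

    def test_each_dead_spore_gets_the_printed_genotype(self, table):
        # dead rows in the fixture carry the published deduced genotypes;
        # re-imputation from the live spores must reproduce them
        for ascus_id in ("2", "3", "5", "8"):
            octad = table.octad(ascus_id)
            pairing = match_sisters(octad)
            assert len(pairing.imputed) == 1
            (pos, genotype), = pairing.imputed
            assert octad.spore(pos).genotype == genotype
            assert not pairing.ambiguous

    def test_pairs_partition_positions_with_identical_genotypes(self, table):
        for octad in table.octads:
            pairing = match_sisters(octad)
            flat = [p for pair in pairing.pairs for p in pair]
            assert sorted(flat) == list("ABCDEFGH")
            for a, b in pairing.pairs:
                assert pairing.genotypes[a] == pairing.genotypes[b]


class TestMatchSistersEdgeCases:
    def test_all_identical_live_octad(self):
        pairing = match_sisters(make_octad([("A", "B")] * 8))
        assert pairing.imputed == ()
        assert not pairing.ambiguous

    def test_odd_class_without_dead_spore_fails(self):
        genotypes = [("A", "B")] * 3 + [("a", "b")] * 5
        with pytest.raises(SisterMatchError, match="odd"):
            match_sisters(make_octad(genotypes))

    def test_two_dead_distinct_deductions_flagged_ambiguous(self):
        # the genotype multiset is forced, but which dead position carries
        # which genotype is not
        genotypes = [("A", "B")] * 3 + [("a", "b")] * 3 + [None, None]
        pairing = match_sisters(make_octad(genotypes))
        imputed = sorted(g for _, g in pairing.imputed)
        assert imputed == [("A", "B"), ("a", "b")]
        assert pairing.ambiguous

    def test_two_dead_identical_deductions_not_ambiguous(self):
        # three live copies of one class and one dead spore of another class:
        # dead positions E (completes the A-class) -> unique assignment
        genotypes = [("A", "B")] * 4 + [("a", "b")] * 3 + [None]
        pairing = match_sisters(make_octad(genotypes))
        assert pairing.imputed == (("H", ("a", "b")),)
        assert not pairing.ambiguous

    def test_whole_dead_sister_pair_is_ambiguous_not_fatal(self):
        genotypes = [("A", "B")] * 4 + [("a", "b")] * 2 + [None, None]
        pairing = match_sisters(make_octad(genotypes))
        assert pairing.ambiguous
        assert pairing.imputed == ()  # nothing deducible

    def test_four_spare_dead_spores_unresolvable(self):
        genotypes = [("A", "B")] * 4 + [None] * 4
        with pytest.raises(SisterMatchError, match="unresolvable"):
            match_sisters(make_octad(genotypes))


class TestReduceToTetrad:
    def test_ascus7_reduces_to_two_product_classes(self, table):
        tetrad = reduce_to_tetrad(table.octad("7"))
        assert sorted(tetrad.products) == sorted(
            [
                ("M", "+", "-", "+"),
                ("M", "+", "-", "+"),
                ("P", "-", "+", "-"),
                ("P", "-", "+", "-"),
            ]
        )

    def test_ascus1_products_match_brute_force_matching(self, table):
        octad = table.octad("1")
        tetrad = reduce_to_tetrad(octad)
        oracle = brute_force_products([s.genotype for s in octad.spores])
        assert oracle == {tetrad.products}
        assert tetrad.products == (
            ("M", "-", "+", "+"),
            ("M", "-", "-", "-"),
            ("P", "+", "+", "-"),
            ("P", "+", "-", "+"),
        )

    def test_fixture_products_always_match_brute_force(self, table):
        for octad in table.octads:
            genotypes = [s.genotype if s.viable else None for s in octad.spores]
            oracle = brute_force_products(genotypes)
            assert oracle == {reduce_to_tetrad(octad).products}

    def test_non_2_2_marker_is_mendelian_error(self):
        genotypes = [("A", "B")] * 6 + [("a", "B")] * 2  # locB 8:0
        with pytest.raises(MendelianError, match="2:2"):
            reduce_to_tetrad(make_octad(genotypes))


class TestRecoveryFromSimulation:
    @pytest.mark.parametrize("arrangement", sim.ARRANGEMENT_MODELS)
    def test_fully_viable_octads_recover_truth_products(self, cross, arrangement):
        config = sim.SimConfig(
            cross=cross, n_asci=250, arrangement=arrangement, seed=11,
            emit_truth=True,
        )
        result = sim.simulate_cross(config)
        for octad, truth in zip(result.table.octads, result.truth):
            tetrad = reduce_to_tetrad(octad)
            assert tetrad.products == tuple(sorted(truth.products))

    def test_truth_sister_pairs_are_identical_and_valid(self, cross):
        config = sim.SimConfig(
            cross=cross, n_asci=100, arrangement="random_spores", seed=3,
            emit_truth=True,
        )
        result = sim.simulate_cross(config)
        for octad, truth in zip(result.table.octads, result.truth):
            flat = sorted(p for pair in truth.sister_pairs for p in pair)
            assert flat == list("ABCDEFGH")
            for product, (a, b) in zip(truth.products, truth.sister_pairs):
                assert octad.spore(a).genotype == product
                assert octad.spore(b).genotype == product

    def test_imputation_recovers_single_dead_spore_truth(self, cross):
        config = sim.SimConfig(
            cross=cross, n_asci=400, arrangement="random_spores",
            viability=0.95, seed=7, emit_truth=True,
        )
        result = sim.simulate_cross(config)
        checked = 0
        for octad, truth in zip(result.table.octads, result.truth):
            dead = octad.dead_positions
            if len(dead) != 1:
                continue
            pairing = match_sisters(octad)
            if pairing.ambiguous:
                continue
            pos_to_product = {
                p: prod
                for prod, pair in zip(truth.products, truth.sister_pairs)
                for p in pair
            }
            assert pairing.genotypes[dead[0]] == pos_to_product[dead[0]]
            checked += 1
        assert checked > 50
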