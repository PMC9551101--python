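"""Target/disease-gene crossover enrichment screen."""

import numpy as np
import pandas as pd
import pytest

from mircross.crossover import (
    TargetTable,
    build_universe,
    crossover_probability,
    crossover_screen,
    mirna_urn,
    omega_from_scores,
    read_target_table,
    significant_set,
)
from mircross.genesets import GeneSet
from mircross.nchg import HypergeomParams, hypergeom_sf
from mircross.simulate import SimConfig, simulate_targets


def _table(rows):
    return TargetTable(records=pd.DataFrame(rows, columns=["mirna_id", "gene_id", "score"]))


class TestBuildUniverse:
    def test_counts_and_discards(self):
        background = GeneSet.from_iterable("bg", [f"g{i}" for i in range(10)])
        disease = GeneSet.from_iterable("d", ["g0", "g1", "gX", "gY", "gZ", "g2", "g3",
                                              "g4", "g5", "g6"])
        targets = GeneSet.from_iterable("t", ["g0", "g9"])
        universe, disease_in, report = build_universe(targets, disease, background)
        assert len(universe) == 10
        assert len(disease_in) == 7
        assert report["disease"] == ["gX", "gY", "gZ"]

    def test_urn_counting(self):
        background = GeneSet.from_iterable("bg", [f"g{i}" for i in range(100)])
        disease = GeneSet.from_iterable("d", [f"g{i}" for i in range(20)])
        rows = [("mir-1", f"g{i}", 70.0) for i in list(range(14, 20)) + list(range(30, 39))]
        universe, disease_in, _ = build_universe(_table(rows).genes(), disease, background)
        urn = mirna_urn(_table(rows).records, disease_in, universe)
        assert (urn.params.N, urn.params.K, urn.params.n, urn.params.k) == (100, 20, 15, 6)

    def test_disjoint_disease_raises(self):
        background = GeneSet.from_iterable("bg", ["a", "b"])
        disease = GeneSet.from_iterable("d", ["x"])
        with pytest.raises(ValueError, match="background universe"):
            build_universe(GeneSet.from_iterable("t", ["a"]), disease, background)


class TestOmega:
    def test_equal_scores_give_unity(self):
        t = _table([("m", "a", 80.0), ("m", "b", 80.0), ("m", "c", 80.0)]).records
        assert omega_from_scores(t, frozenset({"a"})) == 1.0

    def test_score_ratio(self):
        t = _table(
            [("m", "a", 90.0), ("m", "b", 90.0),
             ("m", "c", 60.0), ("m", "d", 60.0), ("m", "e", 60.0)]
        ).records
        assert omega_from_scores(t, frozenset({"a", "b"})) == pytest.approx(1.5)

    def test_empty_group_falls_back_to_unity(self):
        t = _table([("m", "a", 95.0), ("m", "b", 55.0)]).records
        assert omega_from_scores(t, frozenset({"zzz"})) == 1.0
        assert omega_from_scores(t, frozenset({"a", "b"})) == 1.0


class TestCrossoverProbability:
    def test_enumeration_example(self):
        bg = GeneSet.from_iterable("bg", ["a", "b", "c", "d"])
        disease = GeneSet.from_iterable("d", ["a", "b"])
        rows = [("m", "a", 70.0), ("m", "b", 70.0)]
        universe, disease_in, _ = build_universe(_table(rows).genes(), disease, bg)
        urn = mirna_urn(_table(rows).records, disease_in, universe)
        res = crossover_probability(urn, omega=2.0, mirna_id="m")
        assert res.p_value == pytest.approx(4 / 13, rel=1e-12)
        assert not res.significant


class TestScreen:
    def test_uniform_scores_reduce_to_central(self):
        """With all scores equal the screen equals a plain hypergeometric screen."""
        cfg = SimConfig(n_mirnas=30, score_bounds=(80.0, 80.0), seed=8,
                        enrichment_multiplier=3.0)
        targets, disease, bg = simulate_targets(cfg)
        up = GeneSet.from_iterable("up", cfg.mirna_ids())
        results = crossover_screen(up, targets, disease["DISEASE"], background=bg)
        for r in results:
            central = hypergeom_sf(
                HypergeomParams(r.n_universe, r.n_disease_in_universe, r.n_targets, r.overlap)
            )
            assert r.omega == 1.0
            assert r.p_value == pytest.approx(central, rel=1e-10)

    def test_gene_relabelling_invariance(self):
        cfg = SimConfig(n_mirnas=12, seed=4)
        targets, disease, bg = simulate_targets(cfg)
        up = GeneSet.from_iterable("up", cfg.mirna_ids())
        base = crossover_screen(up, targets, disease["DISEASE"], background=bg)

        mapping = {g: f"X_{g}" for g in bg}
        renamed = TargetTable(
            records=targets.records.assign(gene_id=targets.records["gene_id"].map(mapping))
        )
        disease2 = GeneSet.from_iterable("DISEASE", [mapping[g] for g in disease["DISEASE"]])
        bg2 = GeneSet.from_iterable("bg", [mapping[g] for g in bg])
        permuted = crossover_screen(up, renamed, disease2, background=bg2)
        for a, b in zip(base, permuted):
            assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_mirna_without_targets_flagged_untestable(self):
        targets = _table([("m1", "a", 60.0), ("m1", "b", 60.0)])
        bg = GeneSet.from_iterable("bg", ["a", "b", "c", "d"])
        disease = GeneSet.from_iterable("d", ["a"])
        res = crossover_screen(
            GeneSet.from_iterable("up", ["m1", "m2"]), targets, disease, background=bg
        )
        m2 = res[1]
        assert not m2.testable and m2.p_value == 1.0 and not m2.significant

    def test_disjoint_disease_list_gives_zero_significant(self):
        cfg = SimConfig(n_mirnas=20, planted_crossover=(), seed=6)
        targets, _, bg = simulate_targets(cfg)
        # a disease list inside the background but outside every target set
        target_genes = targets.genes().as_set()
        free = [g for g in bg if g not in target_genes][:50]
        disease = GeneSet.from_iterable("d", free)
        res = crossover_screen(
            GeneSet.from_iterable("up", cfg.mirna_ids()), targets, disease, background=bg
        )
        assert sum(r.significant for r in res) == 0

    def test_planted_enrichment_recovered(self):
        """Generator plants 20 of 56 miRNAs with 5x preference for disease genes."""
        cfg = SimConfig(n_mirnas=56, seed=3)
        targets, disease, bg = simulate_targets(cfg)
        up = GeneSet.from_iterable("up", cfg.mirna_ids())
        res = crossover_screen(up, targets, disease["DISEASE"], background=bg)
        sig = set(significant_set(res, "sig"))
        planted = set(cfg.mirna_ids()[:20])
        sensitivity = len(sig & planted) / len(planted)
        false_rate = len(sig - planted) / (len(res) - len(planted))
        assert sensitivity >= 0.8
        assert false_rate <= 0.01 + 2.576 * np.sqrt(0.01 * 0.99 / 36)

    def test_mc_route_agrees_with_fnch_on_scale(self, rng):
        """The Monte-Carlo sensitivity check ranks an enriched miRNA as such."""
        cfg = SimConfig(n_mirnas=6, planted_crossover=(("DISEASE", (0,)),),
                        enrichment_multiplier=8.0, n_genes=300,
                        disease_sizes=(("DISEASE", 60),), targets_per_mirna_mean=25.0,
                        seed=13)
        targets, disease, bg = simulate_targets(cfg)
        up = GeneSet.from_iterable("up", cfg.mirna_ids())
        mc = crossover_screen(up, targets, disease["DISEASE"], background=bg,
                              method="mc", rng=rng, mc_iterations=2000)
        fn = crossover_screen(up, targets, disease["DISEASE"], background=bg)
        assert mc[0].p_value < 0.05 and fn[0].p_value < 0.05

    def test_screen_order_independence(self):
        cfg = SimConfig(n_mirnas=10, seed=2)
        targets, disease, bg = simulate_targets(cfg)
        ids = cfg.mirna_ids()
        a = crossover_screen(GeneSet.from_iterable("u", ids), targets,
                             disease["DISEASE"], background=bg)
        b = crossover_screen(GeneSet.from_iterable("u", ids[::-1]), targets,
                             disease["DISEASE"], background=bg)
        pa = {r.mirna_id: r.p_value for r in a}
        pb = {r.mirna_id: r.p_value for r in b}
        assert pa == pb


class TestTableIO:
    def test_score_bounds_enforced(self):
        with pytest.raises(ValueError, match="scores outside"):
            _table([("m", "g", 30.0)])

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _table([("m", "g", 60.0), ("m", "g", 70.0)])

    def test_round_trip(self, tmp_path):
        t = _table([("m1", "g1", 61.5), ("m2", "g2", 99.0)])
        t.records.to_csv(tmp_path / "t.tsv", sep="\t", index=False)
        back = read_target_table(tmp_path / "t.tsv")
        pd.testing.assert_frame_equal(back.records, t.records)
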