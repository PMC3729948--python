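import numpy as np
import pandas as pd
import pytest

import commphylo as cp
from commphylo.alpha import UndefinedMetricError
from commphylo.simulate import FIXTURE_EXPECTED

from .conftest import random_tree
from . import oracles


@pytest.fixture(scope="module")
def fx():
    ds = cp.make_fixture()
    return ds, cp.cophenetic_distances(ds.tree), cp.phylo_correlation(ds.tree)


class TestFaithPD:
    def test_hand_values(self, fx):
        ds, _, _ = fx
        assert cp.faith_pd(ds.tree, ["A", "B", "C"]) == FIXTURE_EXPECTED["PD_P1"]
        assert cp.faith_pd(ds.tree, ["C", "D", "E"]) == FIXTURE_EXPECTED["PD_P2"]
        assert cp.faith_pd(ds.tree, list("ABCDE")) == FIXTURE_EXPECTED["PD_all"]

    def test_single_species_rooted_pd_is_tip_depth(self, small_tree):
        assert cp.faith_pd(small_tree, ["C"]) == 2.0

    def test_unrooted_excludes_path_above_mrca(self, small_tree):
        assert cp.faith_pd(small_tree, ["A", "B"], rooted=False) == 2.0
        assert cp.faith_pd(small_tree, ["A", "B"]) == 3.0

    def test_monotone_in_species(self):
        rng = np.random.default_rng(1)
        tree = random_tree(rng, 15)
        tips = tree.tip_labels
        rng.shuffle(tips)
        values = [cp.faith_pd(tree, tips[: k + 1]) for k in range(len(tips))]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_errors(self, small_tree):
        with pytest.raises(UndefinedMetricError):
            cp.faith_pd(small_tree, [])
        with pytest.raises(cp.PhyloError):
            cp.faith_pd(small_tree, ["nope"])


class TestHelmusIndices:
    def test_star_tree_limits(self):
        star = cp.parse_newick("(A:1,B:1,C:1,D:1)root;")
        corr = cp.phylo_correlation(star)
        assert cp.psv(corr, list("ABCD")) == 1.0
        # Helmus PSE also penalizes abundance unevenness, so it reaches 1
        # on a star only with equal abundances; the pair-averaged variant
        # reaches 1 for any abundances
        assert cp.pse(corr, {s: 3 for s in "ABCD"}) == pytest.approx(1.0)
        assert cp.pse(corr, {"A": 5, "B": 1, "C": 2, "D": 9},
                      method="pairs") == pytest.approx(1.0)
        assert cp.pse(corr, {"A": 5, "B": 1, "C": 2, "D": 9}) < 1.0
        assert cp.psr(cp.psv(corr, list("ABCD")), 4) == 4.0

    def test_hand_values(self, fx):
        ds, _, corr = fx
        assert cp.psv(corr, ["A", "B", "C"]) == pytest.approx(FIXTURE_EXPECTED["PSV_P1"])
        assert cp.psv(corr, ["C", "D", "E"]) == pytest.approx(FIXTURE_EXPECTED["PSV_P2"])
        assert cp.pse(corr, {"A": 2, "B": 1, "C": 1}) == pytest.approx(
            FIXTURE_EXPECTED["PSE_P1"]
        )
        assert cp.pse(corr, {"A": 2, "B": 1, "C": 1}, method="pairs") == \
            pytest.approx(FIXTURE_EXPECTED["PSE_P1_pairs"])

    def test_pse_equals_psv_for_equal_abundances(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            tree = random_tree(rng, int(rng.integers(3, 12)))
            corr = cp.phylo_correlation(tree)
            sp = list(rng.choice(tree.tip_labels,
                                 size=int(rng.integers(2, tree.n_tips + 1)),
                                 replace=False))
            equal = {s: 3 for s in sp}
            for method in ("helmus", "pairs"):
                assert cp.pse(corr, equal, method=method) == pytest.approx(
                    cp.psv(corr, sp), abs=1e-12)

    def test_pse_matches_independent_oracles(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            tree = random_tree(rng, 6)
            corr = cp.phylo_correlation(tree)
            ab = {s: int(rng.integers(1, 5)) for s in tree.tip_labels}
            # pair-averaged variant == individual-expansion enumeration
            assert cp.pse(corr, ab, method="pairs") == pytest.approx(
                oracles.individual_expansion_pse(tree, ab), abs=1e-10
            )
            # Helmus variant == direct transcription of the published form
            m = np.array([ab[s] for s in tree.tip_labels], dtype=float)
            C = corr.loc[tree.tip_labels, tree.tip_labels].to_numpy()
            S, N = len(m), m.sum()
            expected = float((N**2 - m @ C @ m) / (N**2 * (S - 1) / S))
            assert cp.pse(corr, ab) == pytest.approx(expected, abs=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        tree = random_tree(rng, 10)
        scaled = cp.parse_newick(tree.to_newick())
        for node in scaled.dendropy_tree.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length *= 7.3
        ab = {s: int(rng.integers(1, 6)) for s in tree.tip_labels}
        c1, c2 = cp.phylo_correlation(tree), cp.phylo_correlation(scaled)
        assert cp.psv(c1, tree.tip_labels) == pytest.approx(
            cp.psv(c2, tree.tip_labels), abs=1e-10)
        assert cp.pse(c1, ab) == pytest.approx(cp.pse(c2, ab), abs=1e-10)

    def test_undefined_for_single_species(self, fx):
        _, coph, corr = fx
        for call in (
            lambda: cp.psv(corr, ["A"]),
            lambda: cp.pse(corr, {"A": 5}),
            lambda: cp.psr(1.0, 1),
            lambda: cp.mpd_abund(coph, {"A": 5}),
            lambda: cp.mntd_abund(coph, {"A": 5}),
        ):
            with pytest.raises(UndefinedMetricError):
                call()


class TestDistanceMetrics:
    def test_two_species_equal_distance(self, fx):
        _, coph, _ = fx
        for ab in ({"A": 1, "B": 1}, {"A": 9, "B": 2}):
            assert cp.mpd_abund(coph, ab) == pytest.approx(2.0)
            assert cp.mntd_abund(coph, ab) == pytest.approx(2.0)

    def test_hand_values(self, fx):
        _, coph, _ = fx
        ab = {"A": 2, "B": 1, "C": 1}
        assert cp.mpd_abund(coph, ab) == pytest.approx(FIXTURE_EXPECTED["MPD_P1"])
        assert cp.mntd_abund(coph, ab) == pytest.approx(FIXTURE_EXPECTED["MNTD_P1"])

    def test_star_tree_all_pairs_equal(self):
        star = cp.parse_newick("(A:3,B:3,C:3)root;")
        coph = cp.cophenetic_distances(star)
        ab = {"A": 4, "B": 1, "C": 2}
        assert cp.mpd_abund(coph, ab) == pytest.approx(6.0)
        assert cp.mntd_abund(coph, ab) == pytest.approx(6.0)

    def test_matches_brute_force_and_mntd_le_mpd(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            tree = random_tree(rng, 8, ultrametric=bool(rng.random() < 0.5))
            coph = cp.cophenetic_distances(tree)
            sp = list(rng.choice(tree.tip_labels,
                                 size=int(rng.integers(2, 9)), replace=False))
            ab = {s: int(rng.integers(1, 4)) for s in sp}
            mpd = cp.mpd_abund(coph, ab)
            mntd = cp.mntd_abund(coph, ab)
            assert mpd == pytest.approx(oracles.brute_mpd(tree, ab), abs=1e-10)
            assert mntd == pytest.approx(oracles.brute_mntd(tree, ab), abs=1e-10)
            assert mntd <= mpd + 1e-10

    def test_linear_scaling_with_branch_lengths(self, fx):
        ds, coph, _ = fx
        scaled = coph * 3.0
        ab = {"A": 2, "B": 1, "C": 1}
        assert cp.mpd_abund(scaled, ab) == pytest.approx(3 * FIXTURE_EXPECTED["MPD_P1"])
        assert cp.mntd_abund(scaled, ab) == pytest.approx(3 * FIXTURE_EXPECTED["MNTD_P1"])


class TestWoodDensity:
    def test_dbh_squared_weighting(self):
        stems = cp.StemTable(pd.DataFrame({
            "plot": ["P", "P"], "species": ["x_a", "x_b"], "dbh": [10.0, 20.0],
        }))
        traits = cp.TraitTable.from_measurements(
            {"x_a": 0.5, "x_b": 0.7}, ["x_a", "x_b"])
        assert cp.plot_wood_density(stems, traits, "P") == pytest.approx(0.66)

    def test_constant_density_invariance_and_dbh_scaling(self):
        rng = np.random.default_rng(6)
        dbh = rng.uniform(5, 40, size=12)
        stems = cp.StemTable(pd.DataFrame({
            "plot": "P", "species": [f"g_s{i % 3}" for i in range(12)], "dbh": dbh,
        }))
        traits = cp.TraitTable.from_measurements(
            {f"g_s{i}": 0.55 for i in range(3)}, [f"g_s{i}" for i in range(3)])
        assert cp.plot_wood_density(stems, traits, "P") == pytest.approx(0.55)
        doubled = cp.StemTable(stems.table.assign(dbh=dbh * 2))
        traits2 = cp.TraitTable.from_measurements(
            {"g_s0": 0.4, "g_s1": 0.6, "g_s2": 0.9},
            [f"g_s{i}" for i in range(3)])
        assert cp.plot_wood_density(doubled, traits2, "P") == pytest.approx(
            cp.plot_wood_density(cp.StemTable(stems.table.assign(dbh=dbh * 4)),
                                 traits2, "P"))

    def test_unresolvable_species_listed(self):
        stems = cp.StemTable(pd.DataFrame(
            {"plot": ["P"], "species": ["mystery_sp"], "dbh": [12.0]}))
        traits = cp.TraitTable.from_measurements({"x_a": 0.5}, ["x_a"])
        with pytest.raises(cp.PhyloError, match="mystery_sp"):
            cp.plot_wood_density(stems, traits, "P")


class TestPlotMetricsTable:
    def test_fixture_table_values_and_psr_identity(self, fx):
        ds, _, _ = fx
        long, summary = cp.plot_metrics_table(
            ds.tree, ds.community, r_draws=5, target=4, seed=0,
            stems=ds.stems, traits=ds.traits,
        )
        # P1 and P2 both hold exactly 4 stems: rarefaction returns them
        # unchanged, so every draw equals the hand-derived values
        assert summary.loc["P1", "PD"] == pytest.approx(FIXTURE_EXPECTED["PD_P1"])
        assert summary.loc["P2", "PSV"] == pytest.approx(FIXTURE_EXPECTED["PSV_P2"])
        assert summary.loc["P1", "PSE"] == pytest.approx(FIXTURE_EXPECTED["PSE_P1"])
        assert summary["PSR"].equals(summary["PSV"] * summary["S"]) or np.allclose(
            summary["PSR"], summary["PSV"] * summary["S"])
        assert summary.loc["P1", "WD"] > 0

    def test_monospecific_plot_flagged_not_zero(self, small_tree):
        counts = pd.DataFrame({"A": [5, 2], "B": [0, 3]}, index=["mono", "duo"])
        meta = pd.DataFrame({
            "plot": ["mono", "duo"], "forest_type": "YS",
            "stratum": "overstorey", "area_m2": 500.0}).set_index("plot")
        comm = cp.CommunityMatrix(counts, meta)
        long, summary = cp.plot_metrics_table(small_tree, comm, r_draws=2,
                                              target=5, seed=0)
        flagged = long[(long["plot"] == "mono") & (long["metric"] == "PSV")]
        assert flagged["value"].isna().all()
        assert flagged["reason"].notna().all()
        assert np.isnan(summary.loc["mono", "PSV"])
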