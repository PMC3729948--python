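import numpy as np
import pytest

import commphylo as cp
from commphylo.simulate import (
    FIXTURE_EXPECTED,
    ScenarioConfig,
    brownian_trait,
    niche_traits,
)


class TestSimulateTree:
    def test_two_tips_is_a_cherry(self):
        tree = cp.simulate_tree(2, seed=0)
        assert tree.n_tips == 2
        d = tree.tip_depths()
        assert d.iloc[0] == pytest.approx(d.iloc[1])

    def test_ultrametric_and_scaled_to_root_age(self):
        for seed in range(10):
            tree = cp.simulate_tree(30, seed=seed, root_age=100.0)
            assert tree.is_ultrametric(tol=1e-9)
            assert tree.tip_depths().iloc[0] == pytest.approx(100.0)

    def test_tip_labels_unique_and_formatted(self):
        tree = cp.simulate_tree(25, seed=1)
        assert len(set(tree.tip_labels)) == 25
        assert all(l.startswith("sp") for l in tree.tip_labels)

    def test_root_age_distribution_matches_yule_expectation(self):
        # From 2 lineages, time to n plus the final holding interval is a
        # sum of Exp(k*lambda): E[T] = sum_{k=2}^{n} 1/(k*lambda)
        n, lam, reps = 12, 1.0, 500
        rng = np.random.default_rng(2)
        ages = np.array([
            cp.simulate_tree(n, lam, seed=rng, root_age=None)
            .tip_depths().iloc[0]
            for _ in range(reps)
        ])
        expect = sum(1.0 / (k * lam) for k in range(2, n + 1))
        var = sum(1.0 / (k * lam) ** 2 for k in range(2, n + 1))
        se = np.sqrt(var / reps)
        assert abs(ages.mean() - expect) < 3 * se

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            cp.simulate_tree(1)


class TestBrownianTrait:
    def test_variance_grows_with_depth(self):
        tree = cp.simulate_tree(150, seed=3, root_age=100.0)
        rng = np.random.default_rng(4)
        traits = np.array([
            brownian_trait(tree, rate=1.0, seed=rng).to_numpy()
            for _ in range(30)
        ])
        # marginal tip variance should be near rate * root_age
        v = traits.var(axis=0).mean()
        assert 60.0 < v < 140.0

    def test_signal_close_relatives_more_similar(self):
        tree = cp.simulate_tree(100, seed=5, root_age=100.0)
        coph = cp.cophenetic_distances(tree)
        rng = np.random.default_rng(6)
        diffs_close, diffs_far = [], []
        for _ in range(20):
            t = brownian_trait(tree, seed=rng)
            D = coph.to_numpy()
            iu = np.triu_indices_from(D, k=1)
            dd = np.abs(t.to_numpy()[iu[0]] - t.to_numpy()[iu[1]])
            med = np.median(D[iu])
            diffs_close.append(dd[D[iu] < med].mean())
            diffs_far.append(dd[D[iu] >= med].mean())
        assert np.mean(diffs_close) < np.mean(diffs_far)


class TestAssembleCommunity:
    @pytest.fixture(scope="class")
    def pool(self):
        tree = cp.simulate_tree(80, seed=7)
        return tree, cp.cophenetic_distances(tree), niche_traits(tree, seed=8)

    def test_richness_and_stem_totals_exact(self, pool):
        tree, coph, trait = pool
        for regime in ("neutral", "filtering", "repulsion"):
            ab = cp.assemble_community(tree, regime, 2.0, 12, 40, seed=9,
                                       trait=trait, coph=coph)
            assert (ab > 0).sum() == 12
            assert ab.sum() == 40

    def test_strength_zero_identical_to_neutral_draw(self, pool):
        tree, coph, trait = pool
        for regime in ("filtering", "repulsion"):
            a = cp.assemble_community(tree, regime, 0.0, 10, 30, seed=11,
                                      trait=trait, coph=coph)
            b = cp.assemble_community(tree, "neutral", 0.0, 10, 30, seed=11,
                                      trait=trait, coph=coph)
            assert a.equals(b)

    def test_regimes_order_mean_pairwise_distance(self, pool):
        # filtering pulls co-occurring species together on the tree,
        # repulsion pushes them apart: MPD(filtering) < MPD(neutral) <
        # MPD(repulsion) on average
        tree, coph, trait = pool
        rng = np.random.default_rng(12)
        mpds = {}
        for regime, strength in (("filtering", 10.0), ("neutral", 0.0),
                                 ("repulsion", 4.0)):
            vals = []
            for _ in range(30):
                ab = cp.assemble_community(tree, regime, strength, 10, 30,
                                           seed=rng, trait=trait, coph=coph)
                vals.append(cp.mpd_abund(coph, ab))
            mpds[regime] = np.mean(vals)
        assert mpds["filtering"] < mpds["neutral"] < mpds["repulsion"]

    def test_strength_monotone_in_filtering(self, pool):
        tree, coph, trait = pool
        rng = np.random.default_rng(13)
        means = []
        for strength in (0.0, 3.0, 30.0):
            vals = []
            for _ in range(40):
                ab = cp.assemble_community(tree, "filtering", strength, 10, 30,
                                           seed=rng, trait=trait, coph=coph)
                vals.append(cp.mpd_abund(coph, ab))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_infeasible_repulsion_relaxes_with_warning(self, pool):
        tree, coph, trait = pool
        with pytest.warns(UserWarning, match="relaxed"):
            cp.assemble_community(tree, "repulsion", 50.0, 40, 80, seed=14,
                                  coph=coph)


class TestSuccessionDataset:
    @pytest.fixture(scope="class")
    def small_ds(self):
        cfg = ScenarioConfig(pool_size=60, plots_per_type=2,
                             overstorey_stems=25, overstorey_richness=8,
                             understorey_stems=30, understorey_richness=10,
                             seed=1)
        return cp.simulate_succession_dataset(cfg)

    def test_design_shape(self, small_ds):
        ds = small_ds
        assert len(ds.community.plots) == 4 * 2 * 2  # types x plots x strata
        assert set(ds.community.metadata["forest_type"]) == {"YS", "OS",
                                                             "UPOG", "OG"}
        assert set(ds.community.metadata["stratum"]) == {"overstorey",
                                                         "understorey"}

    def test_species_subset_of_tree_and_counts_positive(self, small_ds):
        ds = small_ds
        assert set(ds.community.species) <= set(ds.tree.tip_labels)
        assert (ds.community.plot_totals() > 0).all()

    def test_overstorey_stems_respect_census_threshold(self, small_ds):
        ds = small_ds
        over_plots = ds.community.metadata.index[
            ds.community.metadata["stratum"] == "overstorey"]
        sub = ds.stems.table[ds.stems.table["plot"].isin(over_plots)]
        assert (sub["dbh"] >= 5.0).all()

    def test_trait_table_exercises_genus_fallback(self, small_ds):
        ds = small_ds
        flags = ds.traits.table["resolution"]
        assert (flags == "genus-mean").any()
        assert (flags == "species").any()

    def test_ages_file_reconstructs_tree_via_bladj(self, small_ds):
        ds = small_ds
        dated = cp.bladj_date(ds.topology, ds.ages)
        orig = cp.cophenetic_distances(ds.tree)
        new = cp.cophenetic_distances(dated)
        assert np.allclose(orig.to_numpy(), new.loc[orig.index, orig.columns]
                           .to_numpy(), atol=1e-6)

    def test_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = ScenarioConfig(pool_size=40, plots_per_type=1,
                             overstorey_stems=15, overstorey_richness=6,
                             understorey_stems=15, understorey_richness=6,
                             seed=9)
        d1 = cp.simulate_succession_dataset(cfg)
        d2 = cp.simulate_succession_dataset(cfg)
        p1 = d1.write(tmp_path / "a")
        p2 = d2.write(tmp_path / "b")
        for key in p1:
            assert open(p1[key]).read() == open(p2[key]).read()

    def test_round_trips_through_readers(self, small_ds, tmp_path):
        paths = small_ds.write(tmp_path)
        comm = cp.read_community_table(paths["community"], paths["metadata"])
        assert comm.counts.equals(small_ds.community.counts)
        tree = cp.parse_newick(open(paths["tree"]).read())
        assert sorted(tree.tip_labels) == sorted(small_ds.tree.tip_labels)
        traits = cp.read_trait_table(paths["traits"])
        assert len(traits.table) == len(small_ds.traits.table)
        stems = cp.read_stem_table(paths["stems"])
        assert len(stems.table) == len(small_ds.stems.table)
        ages = cp.AgeConstraints.from_file(paths["ages"])
        assert ages.ages.keys() == small_ds.ages.ages.keys()


class TestFixture:
    def test_fixture_hand_values_documented(self, fixture_dataset):
        ds = fixture_dataset
        corr = cp.phylo_correlation(ds.tree)
        coph = cp.cophenetic_distances(ds.tree)
        assert cp.faith_pd(ds.tree, ds.community.species_set("P1")) == \
            FIXTURE_EXPECTED["PD_P1"]
        assert cp.psv(corr, ds.community.species_set("P2")) == pytest.approx(
            FIXTURE_EXPECTED["PSV_P2"])
        ab1 = ds.community.counts.loc["P1"]
        ab1 = ab1[ab1 > 0]
        assert cp.mpd_abund(coph, ab1) == pytest.approx(FIXTURE_EXPECTED["MPD_P1"])
        assert cp.unifrac(ds.tree, ds.community.species_set("P1"),
                          ds.community.species_set("P2")) == pytest.approx(
            FIXTURE_EXPECTED["UniFrac_P1_P2"])

    def test_fixture_parses_through_every_reader(self, fixture_dataset, tmp_path):
        paths = fixture_dataset.write(tmp_path)
        cp.read_community_table(paths["community"], paths["metadata"])
        cp.read_trait_table(paths["traits"])
        cp.read_stem_table(paths["stems"])
        cp.parse_newick(open(paths["tree"]).read())
        cp.AgeConstraints.from_file(paths["ages"])
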