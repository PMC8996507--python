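"""Synthetic wing generator: trees, Brownian traits, specimens, rendering."""

import numpy as np
import pytest
from scipy import stats

from wingmorph import (HabitatTable, Phylogeny, SimulationConfig,
                       assign_habitats, generate_specimens, phylo_covariance,
                       render_wing_image, simulate_bm_traits, simulate_dataset,
                       simulate_tree)
from wingmorph.images import read_tiff, write_tiff
from wingmorph.simulate import LabelledDataError, RenderError


class TestSimulateTree:
    def test_two_species_is_a_cherry_of_depth_ten(self):
        tree = simulate_tree(2, tree_depth=10.0, seed=0)
        assert sorted(tree.tip_names) == ["sp01", "sp02"]
        lengths = [lf.edge.length for lf in tree.tree.leaf_node_iter()]
        assert lengths == pytest.approx([10.0, 10.0])

    def test_ultrametric_at_paper_scale(self):
        tree = simulate_tree(27, tree_depth=10.0, seed=5)
        depths = np.array(list(tree._tip_depths().values()))
        assert len(depths) == 27
        assert np.ptp(depths) < 1e-9 * 10.0
        assert tree.is_ultrametric()

    def test_same_seed_same_newick(self):
        a = simulate_tree(12, seed=42).as_newick()
        b = simulate_tree(12, seed=42).as_newick()
        assert a == b
        assert a != simulate_tree(12, seed=43).as_newick()

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1)


class TestBrownianTraits:
    def test_tip_variance_matches_sigma2_times_depth(self):
        # Var(tip) = sigma^2 * depth on a 2-tip tree; Monte-Carlo check
        tree = simulate_tree(2, tree_depth=10.0, seed=0)
        x = simulate_bm_traits(tree, sigma2=1.0, p_dims=2000, seed=1)
        assert x.reshape(-1).var() == pytest.approx(10.0, rel=0.1)

    def test_sister_correlation_equals_shared_depth_fraction(self):
        tree = Phylogeny.from_newick("(a:10,(b:1,c:1):9);")
        x = simulate_bm_traits(tree, sigma2=1.0, p_dims=4000, seed=2)
        names = tree.tip_names
        b, c = x[names.index("b")], x[names.index("c")]
        assert np.corrcoef(b, c)[0, 1] == pytest.approx(0.9, abs=0.05)

    def test_small_sigma_limit_is_zero(self):
        tree = simulate_tree(5, seed=3)
        x = simulate_bm_traits(tree, sigma2=1e-18, p_dims=3, seed=0)
        assert np.abs(x).max() < 1e-6

    def test_nonpositive_rate_rejected(self):
        tree = simulate_tree(3, seed=0)
        with pytest.raises(ValueError):
            simulate_bm_traits(tree, sigma2=0.0, p_dims=1)

    def test_non_ultrametric_tree_warns_but_computes(self):
        tree = Phylogeny.from_newick("(a:5,(b:1,c:2):9);")
        with pytest.warns(UserWarning):
            C = phylo_covariance(tree).C
        assert C.shape == (3, 3)


class TestHabitats:
    def test_every_species_labelled_and_grades_balanced(self):
        tree = simulate_tree(27, seed=7)
        hab = assign_habitats(tree, concordance=0.75, seed=1)
        assert set(hab.table.index) == set(tree.tip_names)
        n_open = (hab.table.landscape == "open").sum()
        assert n_open in (13, 14)

    def test_concordance_within_central_99pct_binomial_interval(self):
        tree = simulate_tree(27, seed=7)
        hab = assign_habitats(tree, concordance=0.75, seed=3)
        k = round(hab.concordant_fraction() * 27)
        lo, hi = stats.binom.ppf([0.005, 0.995], 27, 0.75)
        assert lo <= k <= hi

    def test_missing_label_rejected(self):
        import pandas as pd
        with pytest.raises(LabelledDataError):
            HabitatTable(pd.DataFrame({"landscape": ["open", None],
                                       "water_body": ["running", "standing"]},
                                      index=["a", "b"]))


class TestGenerateSpecimens:
    def test_bookkeeping_270_specimens(self):
        cfg = SimulationConfig(n_species=27, n_per_species=10, seed=0)
        tree = simulate_tree(27, seed=0)
        hab = assign_habitats(tree, seed=0)
        configs, labels = generate_specimens(tree, hab, cfg)
        assert len(configs) == 270
        assert len(labels) == 270
        assert (labels.groupby("species").size() == 10).all()
        # label join is consistent with the habitat table
        for sp in tree.tip_names:
            sub = labels[labels.species == sp]
            assert set(sub.landscape) == {hab.landscape(sp)}

    def test_zero_noise_zero_effect_makes_conspecifics_identical(self):
        cfg = SimulationConfig(n_species=4, n_per_species=3, seed=1,
                               habitat_effect_size=0.0, within_species_sd=0.0)
        tree = simulate_tree(4, seed=1)
        hab = assign_habitats(tree, seed=1)
        configs, labels = generate_specimens(tree, hab, cfg)
        by_species = {}
        for c in configs:
            by_species.setdefault(c.metadata["species"], []).append(c.coords)
        for coords in by_species.values():
            for other in coords[1:]:
                assert np.array_equal(coords[0], other)

    def test_missing_habitat_species_rejected(self):
        cfg = SimulationConfig(n_species=4, n_per_species=2, seed=1)
        tree = simulate_tree(4, seed=1)
        hab = assign_habitats(tree, seed=1)
        hab.table = hab.table.drop(tree.tip_names[0])
        with pytest.raises(LabelledDataError):
            generate_specimens(tree, hab, cfg)


class TestRendering:
    def test_frame_dimensions_and_white_background(self, forewing_sample):
        configs, _ = forewing_sample
        img = render_wing_image(configs[0], frame=(200, 56))
        assert img.pixels.shape == (56, 200)
        assert img.pixels.dtype == np.uint8
        for corner in (img.pixels[0, 0], img.pixels[0, -1],
                       img.pixels[-1, 0], img.pixels[-1, -1]):
            assert corner == 255

    def test_mean_brightness_decreases_with_pigment(self, forewing_sample):
        configs, _ = forewing_sample
        means = [render_wing_image(configs[0], pigment_intensity=p).pixels.mean()
                 for p in (0.0, 40.0, 90.0)]
        assert means[0] > means[1] > means[2]

    def test_degenerate_outline_raises(self, forewing_sample):
        configs, _ = forewing_sample
        bad = configs[0].coords.copy()
        bad[[3, 17]] = bad[[17, 3]]    # cross the outline
        from wingmorph import LandmarkConfiguration
        cfg = LandmarkConfiguration(bad, wing_type="forewing")
        with pytest.raises(RenderError):
            render_wing_image(cfg)

    def test_tiff_round_trip_is_bit_exact(self, small_dataset, tmp_path):
        img = small_dataset.images["hindwing"][0]
        write_tiff(tmp_path / "w.tif", img)
        back = read_tiff(tmp_path / "w.tif", wing_type="hindwing")
        assert np.array_equal(back.pixels, img.pixels)
        assert back.frame == img.frame


def test_simulation_is_bitwise_deterministic():
    cfg = SimulationConfig(n_species=5, n_per_species=2, seed=9)
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    assert a.phylogeny.as_newick() == b.phylogeny.as_newick()
    assert a.habitats.table.equals(b.habitats.table)
    for wing in ("forewing", "hindwing"):
        for ca, cb in zip(a.configurations[wing], b.configurations[wing]):
            assert np.array_equal(ca.coords, cb.coords)
        for ia, ib in zip(a.images[wing], b.images[wing]):
            assert np.array_equal(ia.pixels, ib.pixels)
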