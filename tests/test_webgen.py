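"""Community generation: parameter draws, abundances, diets, assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tritroph import (
    ConfigurationError,
    DegenerateCommunityError,
    ParameterRanges,
    assemble_web,
    assign_diet_breadths,
    assign_diets,
    diet_breadth_pmf,
    draw_config,
    generate_abundances,
    generate_community,
)


class TestDrawConfig:
    def test_degenerate_ranges_force_values(self, rng):
        ranges = ParameterRanges(r_min=5, r_max=5, a_min=50, a_max=50,
                                 alpha_min=2.0, alpha_max=2.0)
        cfg = draw_config(ranges, rng)
        assert (cfg.r1, cfg.r2, cfg.r3) == (5, 5, 5)
        assert (cfg.a1, cfg.a2, cfg.a3) == (50, 50, 50)
        assert cfg.alpha2 == cfg.alpha3 == 2.0

    def test_deterministic_under_fixed_seed(self):
        a = draw_config(rng=np.random.default_rng(7))
        b = draw_config(rng=np.random.default_rng(7))
        assert a == b

    def test_richness_mean_matches_discrete_uniform(self, rng):
        # mean of uniform {3..120} is 61.5, sd ~ 34.06
        draws = np.array([draw_config(rng=rng).r1 for _ in range(10_000)])
        se = np.sqrt((118**2 - 1) / 12) / np.sqrt(draws.size)
        assert abs(draws.mean() - 61.5) < 3 * se
        assert draws.min() >= 3 and draws.max() <= 120

    def test_inverted_ranges_rejected(self):
        with pytest.raises(ConfigurationError):
            ParameterRanges(r_min=10, r_max=5)
        with pytest.raises(ConfigurationError):
            ParameterRanges(alpha_min=0.5)


class TestAbundances:
    def test_single_species_takes_all(self, rng):
        assert generate_abundances(1, 42, rng).tolist() == [42]

    def test_rounding_error_bounded(self, rng):
        for _ in range(20):
            counts = generate_abundances(3, 100, rng)
            assert abs(counts.sum() - 100) <= 1.5  # R/2 bound

    def test_pigeonhole_forces_zeros(self, rng):
        counts = generate_abundances(100, 3, rng)
        assert (counts == 0).sum() >= 97
        assert counts.min() >= 0

    def test_invalid_inputs(self, rng):
        with pytest.raises(ConfigurationError):
            generate_abundances(0, 10, rng)


class TestDietBreadths:
    def test_single_resource_forces_one(self, rng):
        assert set(assign_diet_breadths(50, 1, 3.0, rng)) == {1}

    def test_pmf_alpha_one_three_resources(self):
        # normalize k**-2 over {1,2,3}: (1, 1/4, 1/9) / (49/36)
        pmf = diet_breadth_pmf(3, 1.0)
        expected = np.array([1, 1 / 4, 1 / 9]) / (49 / 36)
        np.testing.assert_allclose(pmf, expected, rtol=1e-12)
        np.testing.assert_allclose(pmf, [0.7347, 0.1837, 0.0816], atol=5e-5)

    def test_high_alpha_concentrates_on_specialists(self, rng):
        assert diet_breadth_pmf(100, 10.0)[0] > 0.999
        draws = assign_diet_breadths(10_000, 100, 10.0, rng)
        assert np.mean(draws == 1) > 0.99

    def test_goodness_of_fit_to_truncated_pareto(self, rng):
        # pooled draws across many communities follow the pmf
        alpha, r_res = 1.5, 10
        draws = np.concatenate(
            [assign_diet_breadths(5, r_res, alpha, rng) for _ in range(1000)]
        )
        pmf = diet_breadth_pmf(r_res, alpha)
        observed = np.bincount(draws, minlength=r_res + 1)[1:]
        _, p = stats.chisquare(observed, pmf * draws.size)
        assert p > 0.01

    def test_no_resources_is_degenerate(self, rng):
        with pytest.raises(DegenerateCommunityError):
            assign_diet_breadths(5, 0, 2.0, rng)


class TestDiets:
    def test_single_resource_diet(self, rng):
        diets = assign_diets(np.array([3]), ["P1"], rng)
        assert diets == [["P1", "P1", "P1"]]

    def test_uniform_resource_frequencies(self, rng):
        labels = [f"P{i}" for i in range(1, 6)]
        diets = assign_diets(np.full(2000, 5), labels, rng)
        flat = pd.Series([sp for d in diets for sp in d])
        freqs = flat.value_counts(normalize=True)
        assert np.allclose(freqs, 0.2, atol=0.02)

    def test_deterministic(self):
        labels = ["P1", "P2", "P3"]
        a = assign_diets(np.array([4, 2]), labels, np.random.default_rng(3))
        b = assign_diets(np.array([4, 2]), labels, np.random.default_rng(3))
        assert a == b


def _level_series(mapping):
    return pd.Series(mapping, dtype=np.int64)


class TestAssembly:
    def test_one_to_one_caps_herbivores(self, rng):
        abund = {1: _level_series({"P1": 3}), 2: _level_series({"H1": 5}),
                 3: pd.Series(dtype=np.int64)}
        breadths = {2: _level_series({"H1": 1}), 3: pd.Series(dtype=np.int64)}
        diets = {2: {"H1": ["P1"]}, 3: {}}
        com = assemble_web(abund, breadths, diets, rng)
        assert com.table.n_plants == 3
        assert com.table.n_herbivores == 3  # min(3 plants, 5 herbivores)
        assert com.abundance(2) == 3

    def test_consumer_of_absent_host_is_pruned(self, rng):
        # H2's only potential host has no individuals
        abund = {1: _level_series({"P1": 4}), 2: _level_series({"H1": 2, "H2": 3}),
                 3: pd.Series(dtype=np.int64)}
        breadths = {2: _level_series({"H1": 1, "H2": 1}), 3: pd.Series(dtype=np.int64)}
        diets = {2: {"H1": ["P1"], "H2": ["P9"]}, 3: {}}
        com = assemble_web(abund, breadths, diets, rng)
        assert "H2" not in com.abundances[2].index
        assert com.abundances[2]["H1"] == 2

    def test_enemies_capped_by_surviving_herbivores(self, rng):
        # 2 plants, 2 herbivores, 5 enemies: enemies fill every occupied herb
        abund = {1: _level_series({"P1": 2}), 2: _level_series({"H1": 2}),
                 3: _level_series({"E1": 5})}
        breadths = {2: _level_series({"H1": 1}), 3: _level_series({"E1": 1})}
        diets = {2: {"H1": ["P1"]}, 3: {"E1": ["H1"]}}
        com = assemble_web(abund, breadths, diets, rng)
        assert com.table.n_herbivores == 2
        assert com.table.n_enemies == 2  # one enemy per surviving herbivore

    def test_no_plants_is_degenerate(self, rng):
        abund = {1: pd.Series(dtype=np.int64), 2: _level_series({"H1": 1}),
                 3: pd.Series(dtype=np.int64)}
        with pytest.raises(DegenerateCommunityError):
            assemble_web(abund, {2: _level_series({"H1": 1}), 3: pd.Series(dtype=np.int64)},
                         {2: {"H1": ["P1"]}, 3: {}}, rng)


class TestGeneratedCommunities:
    def test_bit_identical_under_same_config(self, small_config):
        a = generate_community(small_config)
        b = generate_community(small_config)
        pd.testing.assert_frame_equal(a.table.frame, b.table.frame)
        for lvl in (1, 2, 3):
            pd.testing.assert_series_equal(a.abundances[lvl], b.abundances[lvl])

    def test_conservation_invariants(self, community_batch):
        for com in community_batch:
            t = com.table
            assert t.n_plants == com.abundance(1)
            assert t.n_herbivores <= t.n_plants
            assert t.n_enemies <= t.n_herbivores
            assert t.n_herbivores == com.abundance(2)
            assert t.n_enemies == com.abundance(3)

    def test_realized_within_configured(self, community_batch):
        for com in community_batch:
            cfg = com.config
            for lvl in (1, 2, 3):
                assert com.richness(lvl) <= cfg.richness(lvl)
                # realized abundance can exceed configured only by rounding slack
                assert com.abundance(lvl) <= cfg.abundance(lvl) + cfg.richness(lvl) / 2

    def test_realized_breadth_below_assigned(self, community_batch):
        for com in community_batch:
            for lvl in (2, 3):
                realized = com.realized_diet_breadths(lvl)
                assigned = com.assigned_breadths[lvl]
                for sp, k in realized.items():
                    assert k <= assigned[sp]

    def test_enemies_only_via_herbivores(self, community_batch):
        for com in community_batch:
            f = com.table.frame
            assert not (f["enemy_sp"].notna() & f["herb_sp"].isna()).any()
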