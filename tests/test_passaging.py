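"""The culture-split-damage cycle and its Pp distribution bookkeeping."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import hexpassage as hp
from oracles import clipped_normal_mean


class TestDrawInitialPp:
    def test_degenerate_sigma_zero(self, rng):
        values = hp.draw_initial_pp(100, 0.004, 0.0, rng)
        assert np.all(values == 0.004)

    def test_moments_barely_perturbed_by_clipping(self, rng):
        n, mu, sigma = 100_000, 0.004, 1e-3
        values = hp.draw_initial_pp(n, mu, sigma, rng)
        assert values.mean() == pytest.approx(mu, abs=3 * sigma / np.sqrt(n))
        assert values.std() == pytest.approx(sigma, rel=0.02)

    def test_clipped_to_unit_interval(self, rng):
        values = hp.draw_initial_pp(1_000_000, 0.004, 1e-3, rng)
        assert values.min() >= 0.0 and values.max() <= 1.0

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            hp.draw_initial_pp(10, 0.004, -1e-3, rng)


class TestSeedRandom:
    def test_occupied_count_is_rounded_fraction(self, rng):
        cfg = hp.LatticeConfig(37, 23)
        for fraction in (0.15, 0.5, 0.85, 0.999):
            state = hp.seed_random(cfg, fraction, rng)
            assert state.n_cells == round(fraction * 37 * 23)
            state.validate()

    def test_flask_seed_count_arithmetic(self):
        # 15% of the flask-scale lattice, no simulation needed
        assert round(0.15 * 4168 * 3610) == 2_256_972

    def test_full_seeding(self, rng):
        state = hp.seed_random(hp.LatticeConfig(9, 7), 1.0, rng)
        assert state.confluence == 1.0

    def test_seeds_give_different_patterns_same_count(self):
        cfg = hp.LatticeConfig(20, 20)
        a = hp.seed_random(cfg, 0.15, np.random.default_rng(1))
        b = hp.seed_random(cfg, 0.15, np.random.default_rng(2))
        assert a.n_cells == b.n_cells
        assert not np.array_equal(a.occupancy, b.occupancy)

    def test_bad_fraction_and_mismatched_pp(self, rng):
        cfg = hp.LatticeConfig(10, 10)
        with pytest.raises(ValueError):
            hp.seed_random(cfg, 0.0, rng)
        with pytest.raises(ValueError):
            hp.seed_random(cfg, 1.2, rng)
        with pytest.raises(ValueError):
            hp.seed_random(cfg, 0.5, rng, pp_values=np.full(3, 0.004))


class TestGrowToConfluence:
    def test_immediate_return_at_target(self, rng):
        state = hp.seed_random(hp.LatticeConfig(10, 10), 0.5, rng)
        state, duration = hp.grow_to_confluence(state, 0.5)
        assert duration == 0.0

    def test_no_growth_raises_nonconvergence(self, rng):
        state = hp.seed_random(hp.LatticeConfig(10, 10), 0.15, rng, mu_p=0.0, sigma=0.0)
        with pytest.raises(hp.NonConvergenceError, match="density"):
            hp.grow_to_confluence(state, 0.85, max_steps=50)

    def test_reaches_target_density(self, rng):
        state = hp.seed_random(hp.LatticeConfig(40, 35), 0.15, rng, mu_p=0.01, sigma=0.0)
        state, duration = hp.grow_to_confluence(state, 0.85)
        assert state.confluence >= 0.85
        assert duration > 0
        state.validate()


class TestApplyDamage:
    def test_none_preset_is_identity(self, rng):
        pp = rng.uniform(0, 0.01, 1000)
        out = hp.apply_damage(pp, hp.DamageModel.none(), rng)
        assert np.array_equal(out, pp)

    def test_negative_draw_leaves_pp_unchanged(self, rng):
        # sigma_eps=0 makes every draw exactly mu_eps < 0, which must clip to 0
        pp = rng.uniform(0, 0.01, 500)
        out = hp.apply_damage(pp, hp.DamageModel(mu_eps=-1.0, sigma_eps=0.0), rng)
        assert np.array_equal(out, pp)

    def test_mean_decrement_matches_clipped_normal(self, rng):
        pp = np.full(1_000_000, 0.004)
        damage = hp.DamageModel.large()
        out = hp.apply_damage(pp, damage, rng)
        decrement = pp - out
        expected = clipped_normal_mean(1e-4, 1e-4)
        assert expected == pytest.approx(1.083e-4, rel=1e-3)
        se = decrement.std() / np.sqrt(decrement.size)
        assert decrement.mean() == pytest.approx(expected, abs=3 * se)
        # closed form inside the package agrees with the independent oracle
        assert damage.mean_effective_decrement() == pytest.approx(expected)

    def test_floor_at_zero_and_order_preserved(self, rng):
        pp = np.array([0.0, 1e-5, 0.004])
        out = hp.apply_damage(pp, hp.DamageModel(mu_eps=1e-2, sigma_eps=0.0), rng)
        assert np.array_equal(out, [0.0, 0.0, 0.0])

    def test_rejects_pp_outside_unit_interval(self, rng):
        with pytest.raises(ValueError):
            hp.apply_damage(np.array([1.5]), hp.DamageModel.none(), rng)

    def test_unknown_preset_rejected(self):
        with pytest.raises(hp.ConfigError):
            hp.DamageModel.from_preset("huge")


@pytest.fixture(scope="module")
def confluent_state():
    rng = np.random.default_rng(77)
    state = hp.seed_random(hp.LatticeConfig(30, 26), 0.15, rng, mu_p=0.01, sigma=2e-3)
    state, _ = hp.grow_to_confluence(state, 0.85)
    return state


class TestPassageOnce:
    def test_post_split_population_size(self, confluent_state):
        protocol = hp.PassagingProtocol(damage=hp.DamageModel.none())
        new = hp.passage_once(confluent_state, protocol, np.random.default_rng(1))
        assert new.n_cells == round(0.15 * 30 * 26)
        assert new.passage == confluent_state.passage + 1
        new.validate()

    def test_no_damage_survivors_are_submultiset(self, confluent_state):
        protocol = hp.PassagingProtocol(damage=hp.DamageModel.none())
        new = hp.passage_once(confluent_state, protocol, np.random.default_rng(2))
        pool = Counter(confluent_state.pp_values.tolist())
        kept = Counter(new.pp_values.tolist())
        assert all(pool[v] >= c for v, c in kept.items())

    def test_damage_monotone_in_severity_for_fixed_selection(self, confluent_state):
        results = {}
        for name in ("none", "small", "large"):
            protocol = hp.PassagingProtocol(damage=hp.DamageModel.from_preset(name))
            # identical seed => identical selection and identical damage z-scores
            new = hp.passage_once(confluent_state, protocol, np.random.default_rng(99))
            results[name] = new.pp_values
        assert np.all(results["large"] <= results["small"] + 1e-18)
        assert np.all(results["small"] <= results["none"] + 1e-18)

    def test_below_confluence_rejected(self, rng):
        state = hp.seed_random(hp.LatticeConfig(30, 26), 0.2, rng)
        with pytest.raises(ValueError, match="confluence"):
            hp.passage_once(state, hp.PassagingProtocol(), rng)

    def test_homogeneous_no_damage_keeps_exact_mu(self, rng):
        state = hp.seed_random(hp.LatticeConfig(30, 26), 0.15, rng, mu_p=0.02, sigma=0.0)
        state, _ = hp.grow_to_confluence(state, 0.85)
        new = hp.passage_once(state, hp.PassagingProtocol(), rng)
        assert np.all(new.pp_values == 0.02)


class TestSummarisePp:
    def test_constant_list(self):
        s = hp.summarise_pp([0.004] * 10)
        assert s["pp_sd"] == 0.0
        assert s["pp_q1"] == s["pp_median"] == s["pp_q3"] == 0.004

    def test_known_median(self):
        assert hp.summarise_pp([1, 2, 3, 4, 5])["pp_median"] == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hp.summarise_pp([])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_quartile_ordering(self, values):
        s = hp.summarise_pp(values)
        assert s["pp_q1"] <= s["pp_median"] <= s["pp_q3"]
        assert min(values) <= s["pp_mean"] <= max(values)


class TestRunPassagingExperiment:
    def test_record_structure_and_heritability(self):
        protocol = hp.PassagingProtocol(n_passages=3, damage=hp.DamageModel.none())
        model = hp.ModelParameters(mu_p=0.01, sigma=2e-3)
        records, dumps = hp.run_passaging_experiment(
            protocol, model, hp.LatticeConfig(40, 35), seed=5, return_pp=True
        )
        assert [r.passage_number for r in records] == [0, 1, 2, 3]
        assert all(r.duration_h > 0 for r in records)
        assert all(r.pp_q1 <= r.pp_median <= r.pp_q3 for r in records)
        # exact value heritability: every later Pp was drawn at passage 0
        base = np.unique(dumps[0])
        for values in dumps[1:]:
            assert np.isin(values, base).all()

    def test_selection_pressure_raises_mean_pp(self):
        """With heterogeneity and no damage, mean Pp drifts upward (5 replicates)."""
        protocol = hp.PassagingProtocol(n_passages=4, damage=hp.DamageModel.none())
        model = hp.ModelParameters(mu_p=0.01, sigma=2e-3)
        gains = []
        for seed in range(5):
            records = hp.run_passaging_experiment(protocol, model, hp.LatticeConfig(40, 35), seed=seed)
            means = [r.pp_mean for r in records]
            gains.append(means[-1] - means[0])
            rho = stats.spearmanr(range(len(means)), means).statistic
            assert rho > 0
        assert np.mean(gains) > 0

    def test_degenerate_control_exact(self):
        """sigma=0 and no damage: every record has mean mu_p, sd 0, exactly."""
        protocol = hp.PassagingProtocol(n_passages=2, damage=hp.DamageModel.none())
        model = hp.ModelParameters(mu_p=0.01, sigma=0.0)
        records = hp.run_passaging_experiment(protocol, model, hp.LatticeConfig(40, 35), seed=3)
        for r in records:
            assert r.pp_mean == 0.01
            assert r.pp_sd == 0.0

    def test_protocol_validation(self):
        with pytest.raises(hp.ConfigError):
            hp.PassagingProtocol(seed_fraction=0.9, confluence_fraction=0.85)
        with pytest.raises(hp.ConfigError):
            hp.PassagingProtocol(n_passages=-1)
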