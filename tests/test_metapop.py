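"""Season growth, pooling schemes and the adaptive trait-substitution walk."""

import numpy as np
import pandas as pd
import pytest

from coopscape.metapop import (
    ExperimentConfig,
    NonConvergenceError,
    PatchState,
    SeasonParams,
    TransferPlan,
    pool_cooperator_frequency,
    pooled_transfer,
    run_metapopulation_experiment,
    season_growth,
    trait_substitution_run,
)
from coopscape.theory import ResourceDistribution, SelectionRegime, TraitModel, ess_solve
from conftest import random_atom_distribution


@pytest.fixture()
def params():
    return SeasonParams()


class TestSeasonGrowth:
    def test_no_public_good_means_no_growth(self, params):
        """A lone non-producer experiences y = 0, hence gamma = 0."""
        patch = PatchState(R=1.0, x=np.array([0.0]), n=np.array([1e6]))
        grown = season_growth(patch, params)
        assert grown.n[0] == pytest.approx(1e6)

    def test_cheat_overtakes_cooperator_within_patch(self, params):
        patch = PatchState(R=1.0, x=np.array([0.02, 0.0]), n=np.array([5e5, 5e5]))
        grown = season_growth(patch, params)
        cheat_freq = grown.n[1] / grown.total_density
        assert cheat_freq > 0.5

    def test_cooperator_density_increases_with_resources(self, params):
        """Single producer: end-of-season density is strictly increasing in R."""
        densities = []
        for R in (0.25, 0.625, 1.0):
            patch = PatchState(R=R, x=np.array([0.02]), n=np.array([1e6]))
            densities.append(season_growth(patch, params).total_density)
        assert densities[0] < densities[1] < densities[2]

    def test_growth_ceiling_scales_with_resources(self, params):
        patch = PatchState(R=0.5, x=np.array([0.05]), n=np.array([1e7]))
        grown = season_growth(patch, params)
        assert grown.total_density <= params.carrying_coefficient * 0.5 * (1 + 1e-12)

    def test_cheat_frequency_never_decreases(self, params):
        """With shared y, the lower-investment strain's frequency is
        non-decreasing through the season, ceiling or not."""
        patch = PatchState(R=0.8, x=np.array([0.03, 0.01]), n=np.array([8e5, 2e5]))
        prev = 0.2
        for hours in np.linspace(4, 48, 12):
            # constant dt across durations so runs share a trajectory
            p = SeasonParams(n_steps=int(20 * hours))
            grown = season_growth(patch, p, duration=float(hours))
            freq = grown.n[1] / grown.total_density
            assert freq >= prev - 1e-12
            prev = freq

    def test_integration_step_halving_is_converged(self, params):
        """Halving dt moves end-of-season cheat frequency by < 1e-4."""
        patch = PatchState(R=1.0, x=np.array([0.02, 0.0]), n=np.array([5e5, 5e5]))
        freqs = []
        for steps in (960, 1920):
            p = SeasonParams(n_steps=steps)
            grown = season_growth(patch, p)
            freqs.append(grown.n[1] / grown.total_density)
        assert abs(freqs[0] - freqs[1]) < 1e-4

    def test_mutation_diverts_births_to_cheat_slot(self):
        p = SeasonParams(mutation_rate=1e-3)
        patch = PatchState(R=1.0, x=np.array([0.02]), n=np.array([1e6]))
        grown = season_growth(patch, p)
        assert grown.x[-1] == 0.0
        assert 0 < grown.n[-1] < grown.n[0]

    def test_empty_inoculum_rejected(self, params):
        patch = PatchState(R=1.0, x=np.array([0.02]), n=np.array([0.0]))
        with pytest.raises(ValueError, match="inoculum"):
            season_growth(patch, params)


class TestPooledTransfer:
    def make_plan(self, regime):
        return TransferPlan(pairing=((0, 1),), regime=SelectionRegime.coerce(regime))

    def test_identical_patches_are_mode_independent(self):
        x = np.array([0.02, 0.0])
        n = np.array([4e8, 6e8])
        results = {}
        for regime in ("hard", "soft"):
            pa = PatchState(R=1.0, x=x.copy(), n=n.copy())
            pb = PatchState(R=1.0, x=x.copy(), n=n.copy())
            fa, _ = pooled_transfer(pa, pb, self.make_plan(regime))
            results[regime] = fa.n
        np.testing.assert_allclose(results["hard"], results["soft"])
        np.testing.assert_allclose(results["hard"], 0.01 * n)

    def test_hard_pool_is_density_weighted(self):
        pa = PatchState(R=1.0, x=np.array([0.02, 0.0]), n=np.array([9e9, 0.0]))
        pb = PatchState(R=0.25, x=np.array([0.02, 0.0]), n=np.array([0.0, 1e9]))
        fa, fb = pooled_transfer(pa, pb, self.make_plan("hard"))
        freq = fa.n[0] / fa.n.sum()
        assert freq == pytest.approx(0.9)
        assert fb.R == 0.25 and fa.R == 1.0

    def test_soft_pool_equalises_contributions(self):
        pa = PatchState(R=1.0, x=np.array([0.02, 0.0]), n=np.array([9e9, 0.0]))
        pb = PatchState(R=0.25, x=np.array([0.02, 0.0]), n=np.array([0.0, 1e9]))
        fa, _ = pooled_transfer(pa, pb, self.make_plan("soft"))
        assert fa.n[0] / fa.n.sum() == pytest.approx(0.5)

    def test_pool_conserves_composition(self):
        """No strain appears or vanishes in a deterministic transfer."""
        rng = np.random.default_rng(5)
        x = np.array([0.05, 0.02, 0.0])
        na, nb = rng.uniform(1e6, 1e9, 3), rng.uniform(1e6, 1e9, 3)
        pa = PatchState(R=1.0, x=x, n=na)
        pb = PatchState(R=0.25, x=x, n=nb)
        fa, _ = pooled_transfer(pa, pb, self.make_plan("hard"))
        np.testing.assert_allclose(fa.n / fa.n.sum(),
                                   (na + nb) / (na + nb).sum(), rtol=1e-12)

    def test_empty_pool_rejected(self):
        pa = PatchState(R=1.0, x=np.array([0.02]), n=np.array([0.0]))
        pb = PatchState(R=0.25, x=np.array([0.02]), n=np.array([0.0]))
        with pytest.raises(ValueError, match="empty"):
            pooled_transfer(pa, pb, self.make_plan("hard"))

    def test_stochastic_founders_match_expectation(self):
        rng = np.random.default_rng(0)
        pa = PatchState(R=1.0, x=np.array([0.02, 0.0]), n=np.array([6e8, 2e8]))
        pb = PatchState(R=0.25, x=np.array([0.02, 0.0]), n=np.array([2e8, 2e8]))
        fa, _ = pooled_transfer(pa, pb, self.make_plan("hard"), rng=rng)
        expected = 0.01 * 0.5 * (pa.n + pb.n)
        np.testing.assert_allclose(fa.n, expected, rtol=1e-3)


class TestExperiment:
    def two_strain_config(self, pairs, regime, n_transfers=2, **kw):
        return ExperimentConfig(
            pairs=pairs, strains=((0.02, 5e5), (0.0, 5e5)),
            regime=SelectionRegime.coerce(regime), n_transfers=n_transfers, **kw
        )

    def test_deterministic_given_seed(self):
        cfg = self.two_strain_config(((1.0, 0.25),) * 3, "hard", stochastic=True)
        a = run_metapopulation_experiment(cfg, seed=42)
        b = run_metapopulation_experiment(cfg, seed=42)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_single_strain_frequency_constant(self):
        cfg = ExperimentConfig(
            pairs=((0.625, 0.625),), strains=((0.02, 1e6),),
            regime=SelectionRegime.HARD, n_transfers=3,
        )
        _, pools = run_metapopulation_experiment(cfg)
        assert (pools["fraction"] == 1.0).all()

    def test_heterogeneous_beats_homogeneous_under_hard_pooling(self):
        freqs = {}
        for pairs, key in (((1.0, 0.25),), "het"), (((0.625, 0.625),), "hom"):
            cfg = self.two_strain_config(pairs, "hard")
            _, pools = run_metapopulation_experiment(cfg)
            freqs[key] = pool_cooperator_frequency(pools, 2)
        assert freqs["het"] > freqs["hom"]

    def test_soft_pooling_shrinks_arm_difference(self):
        """The soft-pooling arm contrast is an order of magnitude below the
        hard-pooling one (the gradient-level invariance, up to the
        simulator's finite-frequency corrections)."""
        diffs = {}
        for regime in ("hard", "soft"):
            f = {}
            for pairs, key in (((1.0, 0.25),), "het"), (((0.625, 0.625),), "hom"):
                cfg = self.two_strain_config(pairs, regime)
                _, pools = run_metapopulation_experiment(cfg)
                f[key] = pool_cooperator_frequency(pools, 2)
            diffs[regime] = f["het"] - f["hom"]
        assert diffs["hard"] > 0
        assert abs(diffs["soft"]) < 0.15 * diffs["hard"]

    def test_covariance_mechanism_within_a_pair(self):
        """Across a heterogeneous pair the high-R patch ends denser AND
        retains a higher cooperator Malthusian-ratio fitness."""
        cfg = self.two_strain_config(((1.0, 0.25),), "hard", n_transfers=1)
        patches, _ = run_metapopulation_experiment(cfg)
        by_patch = patches.pivot_table(index="R", columns="x", values="density")
        dens = by_patch.sum(axis=1)
        assert dens[1.0] > dens[0.25]
        W = {}
        for R in (0.25, 1.0):
            m_c = np.log(by_patch.loc[R, 0.02] / 5e5)
            m_ch = np.log(by_patch.loc[R, 0.0] / 5e5)
            W[R] = m_c / m_ch
        assert W[1.0] > W[0.25]
        assert all(w < 1 for w in W.values())

    def test_homogeneous_patches_make_regimes_identical(self):
        """With all patches at one R, hard and soft pooling coincide bitwise."""
        out = {}
        for regime in ("hard", "soft"):
            cfg = self.two_strain_config(((0.625, 0.625),) * 2, regime,
                                         n_transfers=3)
            patches, pools = run_metapopulation_experiment(cfg)
            out[regime] = (patches, pools)
        pd.testing.assert_frame_equal(out["hard"][0], out["soft"][0])
        pd.testing.assert_frame_equal(out["hard"][1], out["soft"][1])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ExperimentConfig(pairs=(), strains=((0.02, 1e6),),
                             regime=SelectionRegime.HARD)
        with pytest.raises(ValueError):
            ExperimentConfig(pairs=((1.0, -0.25),), strains=((0.02, 1e6),),
                             regime=SelectionRegime.HARD)
        with pytest.raises(ValueError):
            ExperimentConfig(pairs=((1.0, 0.25),), strains=((0.02, 1e6),),
                             regime=SelectionRegime.HARD, bottleneck=1.5)


class TestTraitSubstitution:
    def test_converges_to_single_patch_ess(self):
        dist = ResourceDistribution.degenerate(1.0)
        traj, z = trait_substitution_run(dist, TraitModel(r=1.0), "hard",
                                         z0=0.0, step=0.01, seed=0)
        assert z == pytest.approx(0.5, abs=0.01)
        assert traj[0] == 0.0 and traj[-1] == z

    def test_zero_relatedness_stays_at_zero(self, two_point):
        _, z = trait_substitution_run(two_point, TraitModel(r=0.0), "hard",
                                      z0=0.0, step=0.01, seed=0)
        assert z == 0.0

    @pytest.mark.parametrize("regime", ["soft", "hard"])
    def test_matches_numeric_ess_within_one_step(self, two_point, regime):
        model = TraitModel(r=1.0)
        step = 0.005
        _, z = trait_substitution_run(two_point, model, regime,
                                      z0=0.1, step=step, seed=1)
        target = ess_solve(two_point, model, regime).z_star
        assert abs(z - target) <= step

    def test_descends_from_above(self, two_point):
        model = TraitModel(r=0.6)
        step = 0.005
        _, z = trait_substitution_run(two_point, model, "soft",
                                      z0=1.0, step=step, seed=2)
        assert abs(z - 0.3) <= step

    def test_random_scenarios_both_regimes(self):
        rng = np.random.default_rng(19)
        step = 0.005
        for _ in range(5):
            dist = random_atom_distribution(rng)
            model = TraitModel(r=float(rng.uniform(0.2, 1.0)))
            for regime in ("soft", "hard"):
                _, z = trait_substitution_run(
                    dist, model, regime, z0=float(rng.uniform(0, 0.2)),
                    step=step, seed=int(rng.integers(2**31)),
                )
                target = ess_solve(dist, model, regime).z_star
                assert abs(z - target) <= step + 1e-12

    def test_nonconvergence_raises_with_trajectory(self, two_point):
        with pytest.raises(NonConvergenceError) as err:
            trait_substitution_run(two_point, TraitModel(r=1.0), "hard",
                                   z0=0.0, step=1e-4, max_iter=10)
        assert len(err.value.trajectory) == 11
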