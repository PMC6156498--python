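"""Stochastic turnover simulator: development, drift, first passage, SSA."""

import math

import numpy as np
import pytest

from mitodel.dynamics import (
    FirstPassageResult,
    SimParams,
    first_passage_time,
    gillespie_cell,
    run_development,
    simulate_lifespan,
    step_counts,
    step_turnover,
    validate_against_ssa,
)


def _small_params(**kw):
    """A 50-cell worm with 50 copies/cell: fast drift for quick tests."""
    defaults = dict(
        n_cells=50,
        copies_per_worm_target=2500,
        egg_copies=500,
        half_life_days=3.0,
        mu=2e-4,
    )
    defaults.update(kw)
    return SimParams(**defaults)


class TestSimParams:
    def test_dt_constraint(self):
        with pytest.raises(ValueError, match="dt_days"):
            SimParams(half_life_days=1.0, dt_days=0.25)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            SimParams(threshold=1.0)

    def test_cell_target(self):
        assert SimParams().cell_target == 313


class TestDevelopment:
    def test_mu_zero_all_wildtype_at_target(self):
        p = SimParams(mu=0.0)
        w = run_development(p, seed=0)
        assert w.n_cells == 959
        assert w.total_mut == 0
        assert w.total_copies == p.copies_per_worm_target
        assert np.isclose(w.wt.mean(), 300_000 / 959, rtol=0.15)

    def test_default_mu_seeds_standing_mutants(self):
        # expected de novo load ~ mu * target * ln(target/egg) ~ 150 molecules
        w = run_development(SimParams(), seed=1)
        assert 50 < w.total_mut < 350
        assert w.max_fraction < 0.5

    def test_founder_fraction_is_martingale(self):
        """Neutral drift through development preserves the expected worm-wide
        mutant fraction (analytic-expectation oracle)."""
        p = _small_params(mu=0.0)
        founder = p.egg_copies // 2
        fracs = np.array(
            [
                run_development(p, seed=s, founder_mut=founder).total_mut
                / p.copies_per_worm_target
                for s in range(200)
            ]
        )
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - 0.5) < 3 * se

    def test_egg_smaller_than_cells_rejected(self):
        with pytest.raises(ValueError):
            SimParams(n_cells=959, egg_copies=500)


class TestTurnover:
    def test_mu_zero_stays_wildtype_at_target(self):
        p = _small_params(mu=0.0)
        w = run_development(p, seed=2)
        for _ in range(200):
            w = step_turnover(w, p, rng=np.random.default_rng(3))
        assert w.total_mut == 0
        # immediate-restore control pins every cell at its target
        assert np.all(w.wt + w.mut == p.cell_target)

    def test_de_novo_rate_matches_linearization(self):
        """New mutants accrue at ~ mu * N * ln2/t_half per cell-day while the
        mutant fraction is small."""
        n_cells, N, hl, mu, dt = 2000, 313, 12.0, 1e-3, 0.25
        rng = np.random.default_rng(4)
        p_death = 1 - math.exp(-math.log(2) / hl * dt)
        wt = np.full(n_cells, N, dtype=np.int64)
        mut = np.zeros(n_cells, dtype=np.int64)
        steps = 4  # one day
        for _ in range(steps):
            wt, mut = step_counts(wt, mut, N, p_death, mu, rng, True)
        expected = mu * N * math.log(2) / hl * n_cells * (steps * dt)
        se = math.sqrt(expected)  # Poisson-scale error
        assert abs(mut.sum() - expected) < 4 * se + 0.1 * expected

    def test_copy_number_homeostasis(self):
        p = _small_params(mu=0.0)
        w = run_development(p, seed=5)
        rng = np.random.default_rng(6)
        # cells born above target decay toward it (no culling), then the
        # immediate-restore control pins every cell at target
        for _ in range(40):
            w = step_turnover(w, p, rng=rng)
            assert np.all(w.wt + w.mut >= p.cell_target)
        for _ in range(360):  # ~100 days total
            w = step_turnover(w, p, rng=rng)
            assert np.all(w.wt + w.mut == p.cell_target)


class TestAgainstSSA:
    def test_symmetric_fixation_probability(self):
        res = validate_against_ssa(
            n=20, half_life_days=3.0, mu=0.0, m0=10, t_end_days=400.0,
            n_runs=600, checkpoints=(400.0,), seed=0,
        )
        se = math.sqrt(0.25 / res["n_runs"])
        assert abs(res["ssa_fixation_prob"] - 0.5) < 4 * se
        assert abs(res["discrete_fixation_prob"] - 0.5) < 4 * se

    def test_neutral_fixation_prob_is_one_over_n(self):
        """Closed form: a single neutral mutant fixes with probability 1/N."""
        res = validate_against_ssa(
            n=20, half_life_days=3.0, mu=0.0, m0=1, t_end_days=600.0,
            n_runs=1500, checkpoints=(600.0,), seed=1,
        )
        se = math.sqrt(0.05 * 0.95 / res["n_runs"])
        assert abs(res["ssa_fixation_prob"] - 1 / 20) < 4 * se
        assert abs(res["discrete_fixation_prob"] - 1 / 20) < 4 * se

    def test_mean_fraction_trajectories_agree(self):
        """Discrete stepper and exact SSA give the same drift (martingale at
        0.5) at five checkpoints within 3 combined SE."""
        res = validate_against_ssa(
            n=50, half_life_days=3.0, mu=0.0, m0=25, t_end_days=60.0,
            n_runs=500, checkpoints=(5.0, 10.0, 20.0, 40.0, 60.0), seed=2,
        )
        for i in range(5):
            diff = abs(res["ssa_mean_fraction"][i] - res["discrete_mean_fraction"][i])
            se = math.hypot(res["ssa_se_fraction"][i], res["discrete_se_fraction"][i])
            assert diff < 3 * se + 1e-9
            assert abs(res["discrete_mean_fraction"][i] - 0.5) < 4 * res["discrete_se_fraction"][i]

    def test_gillespie_absorbs_at_boundaries(self):
        m, absorbed, _ = gillespie_cell(10, 3.0, 0.0, 5, 2000.0, seed=3)
        assert absorbed and m in (0, 10)


class TestLifespanTrajectories:
    def test_mu_zero_burden_stays_zero(self):
        p = _small_params(mu=0.0)
        traj = simulate_lifespan(p, t_end_days=10.0, record_every=2.0, seed=0)
        assert (traj["total_mut"] == 0).all()

    def test_doubling_mu_doubles_burden(self):
        """Linear response of mean burden to the de novo rate at small
        fractions."""
        p1 = SimParams(mu=1e-4, half_life_days=6.0)
        p2 = SimParams(mu=2e-4, half_life_days=6.0)
        b1 = [
            simulate_lifespan(p1, 10.0, record_every=10.0, seed=s)["total_mut"].iloc[-1]
            for s in range(25)
        ]
        b2 = [
            simulate_lifespan(p2, 10.0, record_every=10.0, seed=100 + s)["total_mut"].iloc[-1]
            for s in range(25)
        ]
        ratio = np.mean(b2) / np.mean(b1)
        assert 1.6 < ratio < 2.4

    def test_faster_turnover_accumulates_more(self):
        fast = simulate_lifespan(SimParams(half_life_days=3.0), 10.0, 10.0, seed=7)
        slow = simulate_lifespan(SimParams(half_life_days=12.0), 10.0, 10.0, seed=7)
        assert fast["total_mut"].iloc[-1] > slow["total_mut"].iloc[-1]


class TestFirstPassage:
    def test_mu_zero_never_passes(self):
        p = _small_params(mu=0.0)
        res = first_passage_time(p, n_worms=3, t_cap_days=30.0, seed=0)
        assert res.capped.all()
        assert res.capped_fraction == 1.0
        assert (res.times_days == 30.0).all()

    def test_monotone_in_half_life_and_mu(self):
        """Faster turnover and higher mutation rate both hasten the first
        threshold crossing."""
        base = dict(n_worms=20, t_cap_days=3000.0)
        fast = first_passage_time(_small_params(half_life_days=3.0), seed=1, **base)
        slow = first_passage_time(_small_params(half_life_days=12.0), seed=1, **base)
        hot = first_passage_time(_small_params(mu=2e-3), seed=1, **base)
        assert fast.mean_days < slow.mean_days
        assert hot.mean_days < fast.mean_days

    def test_bit_identical_rerun(self):
        p = _small_params()
        a = first_passage_time(p, n_worms=6, t_cap_days=2000.0, seed=9)
        b = first_passage_time(p, n_worms=6, t_cap_days=2000.0, seed=9)
        assert np.array_equal(a.times_days, b.times_days)

    def test_report_fields(self):
        p = _small_params()
        res = first_passage_time(p, n_worms=6, t_cap_days=2000.0, seed=9)
        d = res.to_dict()
        assert d["n_worms"] == 6
        assert d["mean_years"] == pytest.approx(d["mean_days"] / 365.0)
        assert set(d["quantiles_days"]) == {0.1, 0.5, 0.9}
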