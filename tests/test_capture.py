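"""Hypergeometric capture chain, calibration curve, and inversion."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mitodel.capture import (
    CalibrationCurve,
    CaptureDesign,
    FixedDeletionSpectrum,
    Homogenate,
    UniformDeletionSpectrum,
    _counts_at_fraction,
    _draw_stock,
    _rhyper,
    build_calibration,
    burden_per_worm,
    estimate_fraction,
    simulate_capture,
    simulate_replicates,
    trend_test,
)
from mitodel.genome import Deletion
from mitodel.panel import PanelConfig, Primer, PrimerPanel, build_panel


def _micro_world(n_wells=5, mpw=20, amplifiable_by=3):
    """Tiny world: n_wells pairs of which the first ``amplifiable_by`` can
    amplify the probe deletion; stock exactly fills the wells."""
    probe = Deletion(3000, 5500)  # 2,501 bp
    primers, pair_list = [], []
    for j in range(n_wells):
        if j < amplifiable_by:
            f = Primer(f"F{j}", "F", 2800 - j, 2819 - j)   # mutant amplicon fits
            r = Primer(f"R{j}", "R", 5700 + j, 5719 + j)
        else:
            f = Primer(f"F{j}", "F", 4000 + j, 4019 + j)   # site inside deletion
            r = Primer(f"R{j}", "R", 9000 + j, 9019 + j)
        primers += [f, r]
        pair_list.append((f.name, r.name))
    panel = build_panel(primers, PanelConfig(L_max=1000), explicit_pairs=pair_list)
    stock = n_wells * mpw
    design = CaptureDesign(
        n_wells=n_wells, molecules_per_well=mpw, working_stock_copies=stock,
        n_worms=1, copies_per_worm=stock,
    )
    return panel, design, probe


class TestSamplingChain:
    def test_null_homogenate_never_amplifies(self):
        panel, design, _ = _micro_world()
        h = Homogenate(total_copies=design.working_stock_copies, mutants=[])
        res = simulate_capture(h, panel, design, seed=0)
        assert res.amplified_wells == 0

    def test_saturated_homogenate_amplifies_all_wells(self):
        panel, design, probe = _micro_world(amplifiable_by=5)
        h = Homogenate(
            total_copies=design.working_stock_copies,
            mutants=[(probe, design.working_stock_copies)],
        )
        res = simulate_capture(h, panel, design, seed=0)
        assert res.amplified_wells == design.n_wells
        assert all(w.detected == probe for w in res.per_well)

    def test_panel_well_count_mismatch_rejected(self, small_world):
        panel, design = small_world
        bad = CaptureDesign(
            n_wells=3, molecules_per_well=10, working_stock_copies=30,
            n_worms=1, copies_per_worm=1000,
        )
        h = Homogenate(total_copies=1000, mutants=[])
        with pytest.raises(ValueError, match="one pair per well"):
            simulate_capture(h, panel, bad, seed=0)

    def test_overdrawn_stock_rejected(self):
        with pytest.raises(ValueError, match="stock"):
            CaptureDesign(
                n_wells=10, molecules_per_well=100, working_stock_copies=500,
            )

    def test_occupancy_matches_enumeration_oracle(self):
        """Mean amplified wells for m copies in the stock vs exact enumeration
        over ordered ball-in-urn placements (m <= 3, n <= 10)."""
        n_wells, mpw, a, m = 5, 20, 3, 3
        panel, design, probe = _micro_world(n_wells, mpw, amplifiable_by=a)
        S = design.working_stock_copies

        def oracle():
            total = 0.0

            def rec(i, placed, prob):
                nonlocal total
                if i == m:
                    hit = {j for j in placed if j < a}
                    total += prob * len(hit)
                    return
                s_left = S - i
                for j in range(n_wells):
                    cap = mpw - placed.count(j)
                    if cap > 0:
                        rec(i + 1, placed + [j], prob * cap / s_left)

            rec(0, [], 1.0)
            return total

        expected = oracle()
        h = Homogenate(total_copies=S, mutants=[(probe, m)])
        sims = np.array(
            [simulate_capture(h, panel, design, seed=s).amplified_wells for s in range(4000)]
        )
        se = sims.std(ddof=1) / np.sqrt(sims.size)
        assert abs(sims.mean() - expected) < 4 * se

    def test_single_pair_hypergeometric_closed_form(self):
        """With one well and no error rates the amplification probability has
        the closed form 1 - pmf(0) of the per-well hypergeometric draw."""
        probe = Deletion(3000, 5500)
        f = Primer("F0", "F", 2800, 2819)
        r = Primer("R0", "R", 5700, 5719)
        panel = build_panel([f, r], PanelConfig(L_max=1000), explicit_pairs=[("F0", "R0")])
        S, w, m = 500, 100, 5
        design = CaptureDesign(
            n_wells=1, molecules_per_well=w, working_stock_copies=S,
            n_worms=1, copies_per_worm=S,
        )
        h = Homogenate(total_copies=S, mutants=[(probe, m)])
        p_closed = 1.0 - stats.hypergeom.pmf(0, S, m, w)
        hits = np.array(
            [simulate_capture(h, panel, design, seed=s).amplified_wells for s in range(3000)]
        )
        se = np.sqrt(p_closed * (1 - p_closed) / hits.size)
        assert abs(hits.mean() - p_closed) < 3 * se

    def test_conservation_through_chain(self, rng):
        """Expected mutant count in the working stock equals f x stock size."""
        panel, design, probe = _micro_world()
        S = design.working_stock_copies
        total, m = 10 * S, 40  # f = 40 / 1000
        h = Homogenate(total_copies=total, mutants=[(probe, m)])
        design = CaptureDesign(
            n_wells=design.n_wells, molecules_per_well=design.molecules_per_well,
            working_stock_copies=S, n_worms=1, copies_per_worm=total,
        )
        draws = np.array([_draw_stock(h, design, rng)[1][0] for _ in range(10_000)])
        expected = m * S / total
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se

    def test_well_order_exchangeability(self, small_world):
        """Permuting well order leaves the amplified-well count distribution
        unchanged (two seeds, KS test)."""
        panel, design = small_world
        rev_panel = PrimerPanel(
            primers=panel.primers, pairs=list(reversed(panel.pairs)), config=panel.config
        )
        h = Homogenate.sporadic(design.homogenate_copies, 2e-3)
        a = [simulate_capture(h, panel, design, seed=s).amplified_wells for s in range(250)]
        b = [simulate_capture(h, rev_panel, design, seed=10_000 + s).amplified_wells for s in range(250)]
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_false_rates(self):
        panel, design, _ = _micro_world()
        fp_design = CaptureDesign(
            n_wells=design.n_wells, molecules_per_well=design.molecules_per_well,
            working_stock_copies=design.working_stock_copies, n_worms=1,
            copies_per_worm=design.working_stock_copies, false_positive_rate=1.0,
        )
        h = Homogenate(total_copies=design.working_stock_copies, mutants=[])
        assert simulate_capture(h, panel, fp_design, seed=0).amplified_wells == design.n_wells

    def test_replicates_deplete_single_copy_species(self):
        """A species present as one molecule can be captured in at most one
        replicate when replicates share the extract."""
        panel, design, probe = _micro_world(n_wells=5, mpw=20, amplifiable_by=3)
        # ten replicates together consume the whole 1,000-molecule extract,
        # so the single probe molecule is plated exactly once
        total = 10 * design.working_stock_copies
        h = Homogenate(total_copies=total, mutants=[(probe, 1)])
        total_detections = 0
        for s in range(40):
            reps = simulate_replicates(h, panel, design, n_replicates=10, seed=s)
            seen = sum(any(w.detected == probe for w in r.per_well) for r in reps)
            assert seen <= 1
            total_detections += seen
        assert total_detections > 0  # the molecule is often captured


class TestLargePopulationSampler:
    def test_rhyper_matches_numpy_in_small_regime(self, rng):
        a = _rhyper(rng, 50, 200, 80, size=5000)
        expected = stats.hypergeom.mean(250, 50, 80)
        assert abs(a.mean() - expected) < 4 * a.std(ddof=1) / np.sqrt(a.size)

    def test_rhyper_large_population_moments(self, rng):
        ngood, nbad, n = 3_000_000, 1_497_000_000, 2_360_000
        draws = _rhyper(rng, ngood, nbad, n, size=3000)
        mv = stats.hypergeom.stats(ngood + nbad, ngood, n, moments="mv")
        assert abs(draws.mean() - mv[0]) < 4 * np.sqrt(mv[1] / draws.size)
        assert np.isclose(draws.var(ddof=1), mv[1], rtol=0.15)

    def test_rhyper_degenerate_draw(self, rng):
        assert _rhyper(rng, 2_000_000_000, 0, 1000) == 1000


class TestCalibration:
    def test_fraction_zero_is_point_mass_at_zero(self, small_world):
        panel, design = small_world
        curve = build_calibration(panel, design, [0.0, 1e-4], reps=150, seed=0)
        assert curve.pmf[0, 0] == 1.0

    def test_mean_counts_increase_with_fraction(self, small_world):
        panel, design = small_world
        grid = [1e-4, 5e-4, 2e-3, 8e-3]
        a = build_calibration(panel, design, grid, reps=400, seed=1)
        b = build_calibration(panel, design, grid, reps=400, seed=2)
        for curve in (a, b):
            means = curve.mean_counts()
            assert np.all(np.diff(means) > 0)
        assert np.allclose(a.mean_counts(), b.mean_counts(), rtol=0.25, atol=0.5)

    def test_aggregated_sampler_matches_explicit_chain(self, small_world):
        """The vectorized calibration sampler and the species-resolved
        simulation are the same distribution for a sporadic spectrum."""
        panel, design = small_world
        f = 2e-3
        spectrum = UniformDeletionSpectrum()
        q = spectrum.pair_detectabilities(panel)
        rng = np.random.default_rng(3)
        agg = _counts_at_fraction(f, q, design, 400, rng)
        h = Homogenate.sporadic(design.homogenate_copies, f)
        expl = np.array(
            [
                simulate_capture(h, panel, design, seed=50_000 + s, spectrum=spectrum).amplified_wells
                for s in range(400)
            ]
        )
        assert stats.ks_2samp(agg, expl).pvalue > 0.01

    def test_grid_validation(self, small_world):
        panel, design = small_world
        with pytest.raises(ValueError, match="empty"):
            build_calibration(panel, design, [], reps=200)
        with pytest.raises(ValueError, match="increasing"):
            build_calibration(panel, design, [1e-4, 1e-4], reps=200)
        with pytest.warns(UserWarning, match="reps"):
            build_calibration(panel, design, [1e-4], reps=50, seed=0)

    def test_json_roundtrip(self, small_world, tmp_path):
        panel, design = small_world
        curve = build_calibration(panel, design, [1e-4, 1e-3], reps=120, seed=4)
        curve.to_json(tmp_path / "c.json")
        back = CalibrationCurve.from_json(tmp_path / "c.json")
        assert np.array_equal(back.pmf, curve.pmf)
        assert back.design == curve.design


class TestInversion:
    @pytest.fixture(scope="class")
    def curve(self, small_world):
        panel, design = small_world
        grid = np.geomspace(1e-5, 8e-3, 14)
        return build_calibration(panel, design, grid, reps=500, seed=5)

    def test_all_zero_counts_pin_to_grid_minimum(self, curve):
        est = estimate_fraction([0, 0, 0], curve)
        assert est.point == pytest.approx(curve.fractions[0])
        assert est.ci_lo == curve.fractions[0]

    def test_count_outside_range_rejected(self, curve):
        with pytest.raises(ValueError):
            estimate_fraction([curve.n_wells + 1], curve)

    def test_point_estimate_tracks_generating_fraction(self, small_world):
        panel, _ = small_world
        # deeper wells so expected counts are informative over the grid
        design = CaptureDesign(
            n_wells=len(panel), molecules_per_well=2000,
            working_stock_copies=len(panel) * 2000, n_worms=2, copies_per_worm=100_000,
        )
        grid = np.geomspace(1e-4, 1e-2, 12)
        curve = build_calibration(panel, design, grid, reps=400, seed=5)
        spectrum = UniformDeletionSpectrum()
        q = spectrum.pair_detectabilities(panel)
        rng = np.random.default_rng(6)
        true_fracs = np.geomspace(8e-4, 8e-3, 5)
        recovered = []
        for f in true_fracs:
            counts = _counts_at_fraction(float(f), q, design, 60, rng)
            recovered.append(estimate_fraction(list(counts), curve).point)
        slope = stats.linregress(np.log(true_fracs), np.log(recovered)).slope
        assert 0.8 < slope < 1.2

    def test_estimate_is_deterministic(self, curve):
        a = estimate_fraction([3, 4, 5], curve)
        b = estimate_fraction([3, 4, 5], curve)
        assert a.point == b.point and (a.ci_lo, a.ci_hi) == (b.ci_lo, b.ci_hi)


class TestBurdenAndTrend:
    def test_burden_arithmetic(self):
        from mitodel.capture import MutantFractionEstimate

        e = MutantFractionEstimate(point=2.733e-4, ci_lo=2e-4, ci_hi=4e-4, observed_counts=[11])
        rep = burden_per_worm(e)
        assert rep.per_worm == pytest.approx(81.99, abs=0.01)
        assert rep.per_cell == pytest.approx(81.99 / 959, rel=1e-6)
        assert rep.per_cell < 0.1

    def test_zero_fraction_zero_burden(self):
        from mitodel.capture import MutantFractionEstimate

        e = MutantFractionEstimate(point=0.0, ci_lo=0.0, ci_hi=0.0, observed_counts=[0])
        assert burden_per_worm(e).per_worm == 0.0

    def test_trend_constant_fractions(self):
        slope, p = trend_test([(4, 3e-4), (7, 3e-4), (10, 3e-4)])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_trend_perfect_collinear(self):
        slope, p = trend_test([(4, 1e-4), (7, 2e-4), (10, 3e-4), (13, 4e-4)])
        assert slope > 0 and p < 1e-6

    def test_trend_validation(self):
        with pytest.raises(ValueError):
            trend_test([(4, 1e-4), (7, 2e-4)])
        with pytest.raises(ValueError):
            trend_test([(4, 1e-4), (4, 2e-4), (4, 3e-4)])

    def test_trend_type_i_error_rate(self, rng):
        """Under a no-trend null at realistic noise the 5% test rejects ~5%."""
        ages = np.array([4.0, 7.0, 10.0])
        rejections = 0
        n = 1000
        for _ in range(n):
            fracs = 3e-4 + rng.normal(0, 5e-5, size=3)
            _, p = trend_test(list(zip(ages, fracs)))
            if p < 0.05:
                rejections += 1
        assert 0.025 < rejections / n < 0.080
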