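"""Leakage unmixing, FRET computation, trace classification, and
point-wise histogram / mixture-fit tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snarefret import (AnalysisConfig, IntensityTrace, LeakageMatrix,
                       SimulationConfig, apply_leakage, classify_field,
                       classify_trace, compute_fret, correct_leakage,
                       fit_gaussian_mixture, fraction_without_transitions,
                       pointwise_histogram)
from snarefret.fret import FretTrace
from snarefret.simulate import simulate_field


class TestLeakageCorrection:
    def test_zero_leakage_is_identity(self):
        lm = LeakageMatrix(l_da=0.0, l_ad=0.0)
        d, a = correct_leakage(np.array([200.0]), np.array([800.0]), lm)
        assert d[0] == 200.0 and a[0] == 800.0

    def test_reference_leakage_round_trip(self):
        lm = LeakageMatrix(l_da=0.017, l_ad=0.165)
        true_d, true_a = np.array([200.0]), np.array([800.0])
        obs_d, obs_a = apply_leakage(true_d, true_a, lm)
        d, a = correct_leakage(obs_d, obs_a, lm)
        np.testing.assert_allclose(d, true_d, rtol=1e-12)
        np.testing.assert_allclose(a, true_a, rtol=1e-12)

    def test_matches_hand_solved_system(self):
        # observed = M @ true with M = [[1-l_da, l_ad], [l_da, 1-l_ad]];
        # for l_da=0.1, l_ad=0.3, observed (400, 600):
        #   0.9 d + 0.3 a = 400; 0.1 d + 0.7 a = 600
        # -> d = (0.7*400 - 0.3*600)/(0.63-0.03) = 100/0.6
        #    a = (0.9*600 - 0.1*400)/0.6        = 500/0.6
        lm = LeakageMatrix(l_da=0.1, l_ad=0.3)
        d, a = correct_leakage(np.array([400.0]), np.array([600.0]), lm)
        assert d[0] == pytest.approx(100.0 / 0.6, rel=1e-12)
        assert a[0] == pytest.approx(500.0 / 0.6, rel=1e-12)

    def test_singular_matrix_rejected(self):
        lm = LeakageMatrix.model_construct(l_da=0.4, l_ad=0.6)
        with pytest.raises(ValueError, match="singular"):
            correct_leakage(np.ones(3), np.ones(3), lm)

    @settings(derandomize=True, max_examples=50)
    @given(l_da=st.floats(0.0, 0.45), l_ad=st.floats(0.0, 0.45),
           d=st.floats(0.0, 1e5), a=st.floats(0.0, 1e5))
    def test_mix_unmix_identity_property(self, l_da, l_ad, d, a):
        lm = LeakageMatrix(l_da=l_da, l_ad=l_ad)
        obs_d, obs_a = apply_leakage(np.array([d]), np.array([a]), lm)
        rd, ra = correct_leakage(obs_d, obs_a, lm)
        assert rd[0] == pytest.approx(d, abs=1e-6 * (1 + abs(d)))
        assert ra[0] == pytest.approx(a, abs=1e-6 * (1 + abs(a)))


class TestComputeFret:
    @pytest.mark.parametrize("donor,acceptor,expected",
                             [(500.0, 500.0, 0.5),
                              (800.0, 0.0, 0.0),
                              (0.0, 800.0, 1.0)])
    def test_reference_values(self, donor, acceptor, expected):
        e = compute_fret(np.array([donor]), np.array([acceptor]))
        assert e[0] == pytest.approx(expected)

    def test_low_total_flagged_not_divided(self):
        e = compute_fret(np.array([1.0, 500.0]), np.array([2.0, 500.0]),
                         total_floor=100.0)
        assert np.isnan(e[0]) and e[1] == 0.5

    def test_bounded_for_nonnegative_inputs(self, rng):
        d = rng.uniform(0, 1000, 200)
        a = rng.uniform(0, 1000, 200)
        e = compute_fret(d, a, total_floor=1.0)
        ok = np.isfinite(e)
        assert np.all((e[ok] >= 0) & (e[ok] <= 1))


def _trace_from_e(e, total=1000.0, frame_rate=10.0, mid="m0", fid="f0"):
    e = np.asarray(e, dtype=float)
    return IntensityTrace(mid, fid, frame_rate, total * (1 - e), total * e)


class TestClassification:
    def setup_method(self):
        self.cfg = AnalysisConfig(
            leakage={"l_da": 0.0, "l_ad": 0.0}, min_frames=20)

    def test_constant_high_then_acceptor_bleach(self):
        # high FRET, then an anti-correlated step (donor rises to full
        # total) that never recovers: without transitions, bleach set
        e = np.concatenate([np.full(300, 0.8), np.full(100, 0.0)])
        ft = classify_trace(_trace_from_e(e), self.cfg)
        assert ft.classification == "without_transitions"
        assert ft.bleach_frame is not None
        assert abs(ft.bleach_frame - 300) <= 3

    def test_return_to_high_is_a_transition(self):
        # a down-step that later returns to high FRET is a conformational
        # transition, not bleach
        e = np.concatenate([np.full(200, 0.8), np.full(50, 0.2),
                            np.full(150, 0.8)])
        ft = classify_trace(_trace_from_e(e), self.cfg)
        assert ft.classification == "with_transitions"
        assert ft.bleach_frame is None
        # section II covers the interior dwell
        assert ft.section_bounds == (200, 250)

    def test_never_high_is_excluded(self):
        ft = classify_trace(_trace_from_e(np.full(400, 0.05)), self.cfg)
        assert ft.classification == "excluded"
        assert ft.exclusion_reason == "no_acceptor"

    def test_short_trace_excluded(self):
        ft = classify_trace(_trace_from_e(np.full(10, 0.8)), self.cfg)
        assert ft.classification == "excluded"
        assert ft.exclusion_reason == "too_short"

    def test_multi_complex_excluded(self):
        ft = classify_trace(_trace_from_e(np.full(300, 0.8), total=2000.0),
                            self.cfg, reference_total=1000.0)
        assert ft.classification == "excluded"
        assert ft.exclusion_reason == "multi_complex"

    def test_matches_simulated_ledger(self, analysis_config):
        # at relative noise 0.08, classification should agree with the
        # ground-truth ledger for >= 95% of donor-visible molecules
        cfg = SimulationConfig(n_molecules_per_field=80, n_fields=1, seed=33)
        field = simulate_field(cfg, 0)
        fts = classify_field(field.traces, analysis_config)
        truth = {m.molecule_id: m for m in field.ledger}
        agree = sum(
            truth[ft.molecule_id].expected_classification(
                analysis_config.min_frames, cfg.frame_rate) == ft.classification
            for ft in fts)
        assert agree / len(fts) >= 0.95

    def test_false_without_rate_decreases_with_transition_rate(self,
                                                               analysis_config):
        # with faster true dynamics, fewer transitioning molecules are
        # mistaken for static ones (monotone over 3 settings)
        false_rates = []
        for k, seed in [(0.01, 3), (0.05, 4), (0.5, 5)]:
            cfg = SimulationConfig(
                rate_matrix=[[-2 * k, 2 * k], [k, -k]],
                n_molecules_per_field=60, n_fields=1, seed=seed,
                label_efficiency=1.0, donor_bleach_rate=0.0,
                acceptor_bleach_rate=0.0)
            field = simulate_field(cfg, 0)
            fts = classify_field(field.traces, analysis_config)
            fret_ids = {m.molecule_id for m in field.ledger
                        if m.label_class == "fret"
                        and m.n_completed_excursions > 0}
            n_false = sum(ft.classification == "without_transitions"
                          for ft in fts if ft.molecule_id in fret_ids)
            false_rates.append(n_false / max(len(fret_ids), 1))
        assert false_rates[0] >= false_rates[1] >= false_rates[2]
        assert false_rates[2] == 0.0


class TestFractionWithoutTransitions:
    def _ft(self, cls, fid="f0"):
        t = FretTrace("m", fid, 10.0, np.zeros(1), np.zeros(1), np.zeros(1),
                      classification=cls)
        return t

    def test_single_field_arithmetic(self):
        traces = ([self._ft("without_transitions")] * 50
                  + [self._ft("with_transitions")] * 100
                  + [self._ft("excluded")] * 50)
        mean, sd, per = fraction_without_transitions({"f0": traces})
        assert mean == pytest.approx(0.25)   # 50 / 200 donor spots
        assert sd == 0.0

    def test_mean_sd_across_fields(self):
        fields = {}
        for fid, frac in [("f0", 0.2), ("f1", 0.3), ("f2", 0.4)]:
            n_without = int(frac * 10)
            fields[fid] = ([self._ft("without_transitions", fid)] * n_without
                           + [self._ft("with_transitions", fid)]
                           * (10 - n_without))
        mean, sd, _ = fraction_without_transitions(fields)
        assert mean == pytest.approx(0.3)
        assert sd == pytest.approx(0.1)

    def test_all_transitioning_gives_zero(self):
        mean, _, _ = fraction_without_transitions(
            {"f0": [self._ft("with_transitions")] * 20})
        assert mean == 0.0

    def test_empty_field_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="no molecules"):
            mean, _, _ = fraction_without_transitions(
                {"f0": [], "f1": [self._ft("with_transitions", "f1")] * 4})
        assert mean == 0.0


class TestPointwiseHistogram:
    def _classified(self, e, cls="with_transitions", bounds=None):
        ft = FretTrace("m", "f", 10.0, np.asarray(e, float),
                       np.zeros(len(e)), np.zeros(len(e)),
                       classification=cls)
        ft.section_bounds = bounds if bounds else (0, len(e))
        return ft

    def test_two_level_trace_occupancy(self):
        e = np.concatenate([np.full(300, 0.8), np.full(100, 0.2)])
        centers, density = pointwise_histogram([self._classified(e)], bins=14)
        width = centers[1] - centers[0]
        mass_high = density[np.argmin(np.abs(centers - 0.8))] * width
        mass_low = density[np.argmin(np.abs(centers - 0.2))] * width
        assert mass_high == pytest.approx(0.75, abs=0.01)
        assert mass_low == pytest.approx(0.25, abs=0.01)

    def test_area_is_one(self, rng):
        e = rng.uniform(0, 1, 500)
        centers, density = pointwise_histogram([self._classified(e)], bins=40)
        width = centers[1] - centers[0]
        assert density.sum() * width == pytest.approx(1.0)

    def test_empty_selection_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            _, density = pointwise_histogram([], bins=10)
        assert np.all(density == 0)

    def test_simulated_occupancy_recovered(self):
        # bin masses around each state match ground-truth occupancy
        cfg = SimulationConfig(n_molecules_per_field=30, n_fields=1, seed=9,
                               label_efficiency=1.0, donor_bleach_rate=0.0,
                               acceptor_bleach_rate=0.0)
        field = simulate_field(cfg, 0)
        acfg = AnalysisConfig()
        fts = classify_field(field.traces, acfg)
        centers, density = pointwise_histogram(fts, bins=70)
        width = centers[1] - centers[0]
        high_mass = density[centers > 0.5].sum() * width
        truth = {m.molecule_id: m for m in field.ledger}
        occs = []
        for ft in fts:
            if ft.classification != "with_transitions":
                continue
            m = truth[ft.molecule_id]
            lo, hi = ft.section_bounds
            occs.append(m.path.occupancy(2, until=hi / cfg.frame_rate)[1])
        # pooled-frame comparison is approximate: 3 SE of the per-trace
        # occupancy spread around its mean
        se = np.std(occs) / np.sqrt(len(occs))
        assert abs(high_mass - np.mean(occs)) < 3 * se + 0.05


class TestGaussianMixture:
    def _hist_from(self, samples, bins=60):
        density, edges = np.histogram(samples, bins=bins, range=(-0.2, 1.2),
                                      density=True)
        return 0.5 * (edges[:-1] + edges[1:]), density

    def test_single_component_recovery(self, rng):
        centers, density = self._hist_from(rng.normal(0.5, 0.08, 40_000))
        fit = fit_gaussian_mixture(centers, density, 1, [0.4])
        assert fit.converged
        assert fit.means[0] == pytest.approx(0.5, abs=0.01)
        assert fit.sigmas[0] == pytest.approx(0.08, rel=0.02)

    def test_three_component_recovery(self, rng):
        samples = np.concatenate([rng.normal(0.2, 0.05, 20_000),
                                  rng.normal(0.5, 0.05, 20_000),
                                  rng.normal(0.8, 0.05, 20_000)])
        centers, density = self._hist_from(samples, bins=80)
        fit = fit_gaussian_mixture(centers, density, 3, [0.2, 0.5, 0.8])
        assert fit.converged
        np.testing.assert_allclose(fit.means, [0.2, 0.5, 0.8], atol=0.02)

    def test_components_sorted_by_mean(self, rng):
        samples = np.concatenate([rng.normal(0.2, 0.05, 10_000),
                                  rng.normal(0.8, 0.05, 10_000)])
        centers, density = self._hist_from(samples)
        fit = fit_gaussian_mixture(centers, density, 2, [0.9, 0.1])
        assert fit.means[0] < fit.means[1]

    def test_all_zero_histogram_flagged(self):
        centers = np.linspace(0, 1, 50)
        fit = fit_gaussian_mixture(centers, np.zeros(50), 2, [0.2, 0.8])
        assert not fit.converged
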