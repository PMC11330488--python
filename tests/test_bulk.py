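"""Trace normalization and global multi-curve fitting."""

import numpy as np
import pytest

import fibrilkin as fk
from fibrilkin.bulk import DEFAULT_SEED_MEAN_LENGTH


def sigmoid(t, mid=10.0, rate=1.0):
    return 1.0 / (1.0 + np.exp(-rate * (t - mid)))


T = np.linspace(0, 20, 200)


class TestNormalize:
    def test_increasing_affine_map_preserves_half_time(self):
        raw = fk.KineticTrace(T, 100.0 + 100.0 * sigmoid(T), 100.0)
        norm = fk.normalize_trace(raw)
        assert np.all((norm.fraction_aggregated > -0.05) & (norm.fraction_aggregated < 1.05))
        assert fk.half_time(norm) == pytest.approx(10.0, abs=0.2)

    def test_quench_direction_flip_gives_identical_curve(self):
        up = fk.normalize_trace(fk.KineticTrace(T, 100 + 100 * sigmoid(T), 100.0))
        down = fk.normalize_trace(
            fk.KineticTrace(T, 200 - 100 * sigmoid(T), 100.0, direction="decrease")
        )
        np.testing.assert_allclose(
            up.fraction_aggregated, down.fraction_aggregated, atol=1e-12
        )

    def test_constant_signal_raises_no_transition(self):
        with pytest.raises(ValueError, match="no transition"):
            fk.normalize_trace(fk.KineticTrace(T, np.full(T.size, 150.0), 100.0))

    def test_noise_only_trace_raises(self):
        rng = np.random.default_rng(0)
        sig = 150.0 + rng.normal(0, 1.0, T.size)
        with pytest.raises(ValueError, match="no transition"):
            fk.normalize_trace(fk.KineticTrace(T, sig, 100.0))

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        raw = fk.KineticTrace(T, 100 + 100 * sigmoid(T) + rng.normal(0, 1, T.size), 100.0)
        once = fk.normalize_trace(raw)
        twice = fk.normalize_trace(
            fk.KineticTrace(once.times, once.fraction_aggregated, 100.0)
        )
        np.testing.assert_allclose(
            once.fraction_aggregated, twice.fraction_aggregated, atol=1e-12
        )

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            fk.KineticTrace(np.linspace(0, 10, 10), np.zeros(10), 100.0)


class TestGlobalFit:
    def test_noise_free_kappa_recovery_within_1pct(self):
        cfg = fk.GeneratorConfig(seed=3, noise_bulk=0.0)
        traces, truth = fk.gen_kinetic_traces(cfg)
        norm = [fk.normalize_trace(t) for t in traces]
        fit = fk.global_fit(norm, n_starts=3, seed=0, kappa_reference_m=100.0)
        assert fit.converged
        assert fit.kappa == pytest.approx(0.4, rel=0.01)

    def test_noisy_kappa_recovery_within_10pct(self, normalized_study_traces):
        norm, truth = normalized_study_traces
        fit = fk.global_fit(norm, n_starts=5, seed=0, kappa_reference_m=100.0)
        assert fit.kappa == pytest.approx(0.4, rel=0.10)

    def test_objective_is_sum_of_per_trace_rss(self, normalized_study_traces):
        norm, _ = normalized_study_traces
        fit = fk.global_fit(norm, n_starts=2, seed=0)
        assert fit.objective == pytest.approx(sum(fit.per_trace_rss))

    def test_objective_invariant_to_trace_order(self, normalized_study_traces):
        norm, _ = normalized_study_traces
        a = fk.global_fit(norm, n_starts=2, seed=0)
        b = fk.global_fit(norm[::-1], n_starts=2, seed=0)
        assert a.objective == pytest.approx(b.objective, rel=1e-6)

    def test_objective_invariant_to_affine_signal_rescaling(self, study_traces):
        traces, _ = study_traces
        rescaled = [
            fk.KineticTrace(t.times, 3.0 * t.signal + 50.0, t.m_total,
                            t.seed_mass, t.direction)
            for t in traces
        ]
        a = fk.global_fit([fk.normalize_trace(t) for t in traces], n_starts=2, seed=0)
        b = fk.global_fit([fk.normalize_trace(t) for t in rescaled], n_starts=2, seed=0)
        assert a.objective == pytest.approx(b.objective, rel=1e-9)

    def test_zero_dimensional_fit_equals_direct_residuals(self, normalized_study_traces):
        norm, _ = normalized_study_traces
        full = fk.global_fit(norm, n_starts=3, seed=0)
        fixed = {k: full.params[k] for k in ("kplus_kn", "kplus_k2", "kplus")}
        pinned = fk.global_fit(norm, fixed=fixed)
        assert pinned.objective == pytest.approx(full.objective, rel=1e-9)

    def test_single_unseeded_trace_not_identifiable(self, normalized_study_traces):
        norm, _ = normalized_study_traces
        with pytest.raises(ValueError, match="non-identifiable"):
            fk.global_fit([norm[0]], model="primary_only")

    def test_recovery_median_error_below_10pct(self):
        """Over stochastic replicates at 1% noise, median kappa error < 10%."""
        errs = []
        for s in range(10):
            cfg = fk.GeneratorConfig(seed=500 + s)
            traces, _ = fk.gen_kinetic_traces(cfg)
            norm = [fk.normalize_trace(t) for t in traces]
            fit = fk.global_fit(norm, n_starts=3, seed=s, kappa_reference_m=100.0)
            errs.append(abs(fit.kappa - 0.4) / 0.4)
        assert np.median(errs) < 0.10


class TestModelComparison:
    def test_secondary_data_requires_secondary(self, normalized_study_traces):
        norm, _ = normalized_study_traces
        report = fk.compare_primary_vs_secondary(norm, n_starts=2, seed=0)
        assert report.objective_ratio >= 5.0
        assert report.verdict == "secondary required"

    def test_primary_only_data_is_not_misclassified(self):
        kplus = 20.0
        kn = 0.15**2 / (2 * kplus * 100.0)
        rates = fk.RateConstants(kn=kn, nc=1.0, kplus=kplus)
        cfg = fk.GeneratorConfig(seed=7, rates=rates, seed_pcts=(0.0,),
                                 m_totals=(50.0, 100.0), t_max=40.0)
        traces, _ = fk.gen_kinetic_traces(cfg)
        norm = [fk.normalize_trace(t) for t in traces]
        report = fk.compare_primary_vs_secondary(norm, n_starts=2, seed=0)
        assert report.verdict in ("primary sufficient", "indeterminate")
        assert report.objective_ratio < 5.0

    def test_seed_responsive_half_times_select_secondary(self, normalized_study_traces):
        norm, _ = normalized_study_traces
        hts = [fk.half_time(t) for t in norm]
        assert hts[0] > hts[1] > hts[2]  # seed concentration-dependent speed-up
        report = fk.compare_primary_vs_secondary(norm, n_starts=2, seed=1)
        assert report.verdict == "secondary required"


class TestFragmentationConstrained:
    def test_low_fragmentation_bound_cannot_explain_fast_kinetics(
        self, normalized_study_traces
    ):
        norm, _ = normalized_study_traces
        free = fk.global_fit(norm, n_starts=3, seed=0, kappa_reference_m=100.0)
        pinned = fk.fit_with_fragmentation_fixed(norm, kappa_frag=0.01,
                                                 n_starts=3, seed=0)
        assert pinned.objective >= 10.0 * free.objective

    def test_self_consistent_constraint_fits_fine(self):
        """Fragmentation-generated data constrained to the true rate."""
        rates = fk.default_rates()
        rates = rates.with_(k2=0.0, kminus=rates.k2)  # same kappa, frag-driven
        cfg = fk.GeneratorConfig(seed=9, rates=rates)
        traces, _ = fk.gen_kinetic_traces(cfg)
        norm = [fk.normalize_trace(t) for t in traces]
        kappa_true = rates.kappa_fragmentation(100.0)
        free = fk.global_fit(norm, model="primary_plus_fragmentation",
                             n_starts=3, seed=0, kappa_reference_m=100.0)
        pinned = fk.fit_with_fragmentation_fixed(norm, kappa_frag=kappa_true,
                                                 n_starts=3, seed=0)
        assert pinned.objective <= 2.0 * free.objective

    def test_constraint_at_optimum_changes_nothing(self, normalized_study_traces):
        norm, _ = normalized_study_traces
        free = fk.global_fit(norm, model="primary_plus_fragmentation",
                             n_starts=3, seed=0, kappa_reference_m=100.0)
        pinned = fk.fit_with_fragmentation_fixed(norm, kappa_frag=free.kappa,
                                                 n_starts=3, seed=0)
        assert pinned.objective == pytest.approx(free.objective, rel=1e-3)

    def test_rejects_nonpositive_bound(self, normalized_study_traces):
        norm, _ = normalized_study_traces
        with pytest.raises(ValueError):
            fk.fit_with_fragmentation_fixed(norm, kappa_frag=0.0)
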