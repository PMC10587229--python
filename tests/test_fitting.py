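import warnings

import numpy as np
import pytest

from vazcycle.fitting import (
    FitError,
    bootstrap_fit,
    fit_hplc_reduced,
    fit_npq,
    fit_unit_conversion,
    rmsd,
)
from vazcycle.model import KineticParameters, simulate
from vazcycle.observables import HPLCSeries, total_xanthophylls
from vazcycle.protocols import parse_protocol
from vazcycle.synth import make_hplc_series, make_npq_traces

REF = KineticParameters()


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def test_rmsd_example():
    assert rmsd(np.array([0.0, 1.0]), np.array([1.0, 3.0])) == pytest.approx(
        np.sqrt(2.5))


def test_rmsd_rejects_length_mismatch():
    with pytest.raises(ValueError):
        rmsd(np.array([1.0]), np.array([1.0, 2.0]))


def _series(times, scale):
    v = -scale * times
    return HPLCSeries(times=times, delta={"V": v, "A": 0.3 * -v, "Z": 0.7 * -v})


def test_fit_unit_conversion_exact_scale():
    t = np.arange(5.0)
    model = _series(t, 1.0)
    data = _series(t, 10.2)
    assert fit_unit_conversion(model, data) == pytest.approx(10.2)


def test_fit_unit_conversion_clips_at_zero():
    t = np.arange(5.0)
    assert fit_unit_conversion(_series(t, 1.0), _series(t, -3.0)) == 0.0


def test_fit_unit_conversion_rejects_zero_model():
    t = np.arange(5.0)
    with pytest.raises(FitError):
        fit_unit_conversion(_series(t, 0.0), _series(t, 1.0))


# ---------------------------------------------------------------------------
# Stage 1: HPLC reduced fit
# ---------------------------------------------------------------------------

def test_hplc_reduced_fit_noise_free_self_consistency():
    """On noise-free data the pool-only fit recovers an equivalent model.

    The identifiable truth for the dark-activity parameter is the value the
    pool-only model needs to reproduce the same dark steady state; the
    stage-1 model has no protein buffer, so it differs from the full-model
    value.
    """
    series = [make_hplc_series(REF, p, noise_sd_mmol=0.0)
              for p in ("5HL-10D-5HL", "1HL-4D-7HL-5D-1HL-2D", "10HL-10D", "1HL-1D")]
    out = fit_hplc_reduced(series)
    # The fitted pool-only model must reproduce the data curves to well below
    # the 5 mmol/mol measurement noise (structural mismatch from the small
    # protein-bound pool remains, but at the ~0.03 mmol/mol level).
    n_points = 3 * sum(s.times.size for s in series)
    assert np.sqrt(out["objective"] / n_points) < 0.1
    for key in ("k_VDE_light",):
        assert out[key] == pytest.approx(getattr(REF, key), rel=0.05)


def test_hplc_reduced_fit_requires_protocol():
    s = make_hplc_series(REF, "1HL-1D", noise_sd_mmol=0.0)
    bare = HPLCSeries(times=s.times, delta=s.delta)
    with pytest.raises(FitError):
        fit_hplc_reduced([bare])


def test_hplc_reduced_fit_rejects_underdetermined():
    s = make_hplc_series(REF, "1HL", sample_times=[0.0, 1.0], noise_sd_mmol=0.0)
    with pytest.raises(FitError):
        fit_hplc_reduced([HPLCSeries(times=s.times[:1],
                                     delta={x: s.delta[x][:1] for x in ("V", "A", "Z")},
                                     protocol=s.protocol)])


# ---------------------------------------------------------------------------
# Stage 2: NPQ fit
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def short_traces():
    traces = []
    for prot in ("5HL-9D-5HL", "2HL-2D"):
        traces.extend(make_npq_traces(REF, prot, noise_sd=0.05,
                                      n_replicates=2, seed=11))
    return traces


def test_fit_npq_recovers_quenching_capacities(short_traces):
    fit = fit_npq(short_traces, REF, n_starts=4, seed=3)
    assert fit.estimates["q_V"] == pytest.approx(0.10, abs=0.05)
    assert fit.estimates["q_Z"] == pytest.approx(0.92, abs=0.08)
    assert fit.objective < 2.0 * 0.05**2 * sum(len(t) for t in short_traces)


def test_fit_npq_pins_binding_by_default(short_traces):
    fit = fit_npq(short_traces, REF, n_starts=2, seed=0)
    assert "k_bind_f" not in fit.free_names
    assert fit.params.k_bind_f == REF.k_bind_f


def test_fit_npq_free_binding_flag(short_traces):
    fit = fit_npq(short_traces, REF, n_starts=1, seed=0, max_nfev=5,
                  pattern_evals=0)
    assert "k_bind_f" not in fit.free_names
    fit2 = fit_npq(short_traces, REF, n_starts=1, seed=0, max_nfev=5,
                   pattern_evals=0, free_binding=True)
    assert "k_bind_f" in fit2.free_names


def test_fit_npq_respects_knockout_pinning(short_traces):
    init = REF.replace(k_VA=0.0, k_AZ=0.0)
    fit = fit_npq(short_traces, init, n_starts=1, seed=0, max_nfev=3,
                  pattern_evals=0)
    assert fit.params.k_VA <= 1e-9
    assert fit.params.k_AZ <= 1e-9


def test_fit_npq_requires_traces():
    with pytest.raises(FitError):
        fit_npq([], REF)


def test_fit_npq_flat_objective_guard():
    """With no quenching signal at all, the fit warns that nothing is constrained."""
    silent = REF.replace(P_tot=0.0, r_qZ=0.0)
    traces = make_npq_traces(silent, "2HL-2D", noise_sd=0.0, n_replicates=1, seed=0)
    with pytest.warns(RuntimeWarning, match="identifiability"):
        # With no protein pool, the remaining qZ channel must be pinned too
        # for the data to carry no information at all.
        fit_npq(traces, silent, n_starts=3, seed=0, max_nfev=3, pattern_evals=0,
                constraints={"r_qZ": (0.0, 1e-12)})


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_deterministic_and_contains_estimate(short_traces):
    fit = fit_npq(short_traces, REF, n_starts=2, seed=5, max_nfev=8,
                  pattern_evals=50)
    b1 = bootstrap_fit(fit, short_traces, n_resamples=5, seed=9, max_nfev=4)
    b2 = bootstrap_fit(fit, short_traces, n_resamples=5, seed=9, max_nfev=4)
    assert b1.se == b2.se
    for name in b1.free_names:
        lo, hi = b1.intervals[name]
        assert lo <= b1.estimates[name] <= hi


def test_case_bootstrap_needs_replicates():
    traces = make_npq_traces(REF, "2HL-2D", noise_sd=0.05, n_replicates=1, seed=0)
    fit = fit_npq(traces, REF, n_starts=1, seed=0, max_nfev=3, pattern_evals=0)
    with pytest.raises(FitError):
        bootstrap_fit(fit, traces, n_resamples=3, method="case")


def test_two_stage_bootstrap_requires_replicates(short_traces):
    from vazcycle.fitting import bootstrap_two_stage

    hplc = [make_hplc_series(REF, "1HL-1D", seed=s) for s in (1,)]
    stage1 = fit_hplc_reduced(hplc)
    fit = fit_npq(short_traces, REF, n_starts=1, seed=0, max_nfev=3,
                  pattern_evals=0)
    with pytest.raises(FitError, match="replicate"):
        bootstrap_two_stage(fit, short_traces, hplc, stage1, n_resamples=2)


def test_two_stage_bootstrap_widens_stage1_seeded_intervals(short_traces):
    """Resampling the HPLC data adds the stage-1 error component."""
    from vazcycle.fitting import bootstrap_two_stage

    hplc = [make_hplc_series(REF, "1HL-1D", seed=s) for s in (1, 2)]
    stage1 = fit_hplc_reduced(hplc)
    fit = fit_npq(short_traces, REF, n_starts=1, seed=0, max_nfev=5,
                  pattern_evals=0)
    b = bootstrap_two_stage(fit, short_traces, hplc, stage1,
                            n_resamples=3, seed=4, max_nfev=3)
    assert b.meta["bootstrap_method"] == "two_stage"
    assert all(np.isfinite(list(b.se.values())))
    for name in b.free_names:
        lo, hi = b.intervals[name]
        assert lo <= b.estimates[name] <= hi


def test_residual_bootstrap_works_with_single_replicate():
    traces = make_npq_traces(REF, "2HL-2D", noise_sd=0.05, n_replicates=1, seed=0)
    fit = fit_npq(traces, REF, n_starts=1, seed=0, max_nfev=5, pattern_evals=0)
    b = bootstrap_fit(fit, traces, n_resamples=3, method="residual", max_nfev=3)
    assert all(se >= 0 for se in b.se.values())
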