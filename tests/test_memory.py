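import numpy as np
import pytest

from vazcycle.memory import (
    MemoryScanResult,
    memory_timescale,
    quencher_stoichiometry,
    recovery_scan,
    steady_state_partition,
)
from vazcycle.model import KineticParameters, apply_knockout

REF = KineticParameters()


@pytest.fixture(scope="module")
def ref_scan():
    return recovery_scan(REF)


def test_recovery_decreases_with_dark_duration(ref_scan):
    r = ref_scan.recovery
    assert np.all(np.diff(r) < 0)


def test_recovery_approaches_full_for_short_darkness():
    scan = recovery_scan(REF, T_values=[0.05])
    assert scan.recovery[0] > 0.9


def test_recovery_scan_rejects_nonpositive_T():
    with pytest.raises(ValueError):
        recovery_scan(REF, T_values=[0.0, 5.0])


def test_memory_timescale_matches_slow_epoxidation(ref_scan):
    """tau_mem tracks the slow A -> V epoxidation step (~1/k_AV = 19.6 min)."""
    tau = memory_timescale(ref_scan)
    assert 15.0 < tau < 30.0
    assert ref_scan.tau_mem == tau
    assert ref_scan.fit["rms_residual"] < 0.02


def test_memory_timescale_tracks_inverse_k_AV():
    """Scaling both epoxidation steps scales the memory timescale inversely."""
    taus = []
    for f in (0.5, 1.0, 2.0):
        p = REF.replace(k_AV=f * REF.k_AV, k_ZA=f * REF.k_ZA)
        scan = recovery_scan(p, T_values=np.array([1, 5, 9, 12, 15, 20, 30]) / f)
        taus.append(f * memory_timescale(scan))
    taus = np.array(taus)
    assert np.max(np.abs(taus / taus[1] - 1.0)) < 0.2


def test_memory_timescale_exact_exponential_self_fit():
    scan = MemoryScanResult(
        T_values=np.array([1.0, 5.0, 10.0, 20.0, 40.0]),
        recovery=0.1 + 0.8 * np.exp(-np.array([1.0, 5.0, 10.0, 20.0, 40.0]) / 15.0),
        npq_end_first_hl=1.0)
    assert memory_timescale(scan) == pytest.approx(15.0, rel=1e-6)


def test_memory_timescale_rejects_flat_scan():
    scan = MemoryScanResult(T_values=np.array([1.0, 5.0, 10.0]),
                            recovery=np.array([0.5, 0.5, 0.5]),
                            npq_end_first_hl=1.0)
    with pytest.raises(ValueError):
        memory_timescale(scan)


def test_memory_timescale_rejects_too_few_points():
    scan = MemoryScanResult(T_values=np.array([1.0, 5.0]),
                            recovery=np.array([0.9, 0.5]),
                            npq_end_first_hl=1.0)
    with pytest.raises(ValueError):
        memory_timescale(scan)


def test_vde_knockout_has_no_memory_signal():
    """Without de-epoxidation there is no zeaxanthin build-up to remember.

    The scan is not bit-for-bit flat (the fast quencher equilibration leaves
    a sub-percent transient), so the check is that any fitted "memory"
    amplitude is negligible against the recovery floor.
    """
    p = apply_knockout(REF, "vde")
    scan = recovery_scan(p, T_values=[1.0, 5.0, 10.0, 20.0])
    assert np.max(scan.recovery) - np.min(scan.recovery) < 0.05
    try:
        memory_timescale(scan)
    except ValueError:
        return  # flat-scan rejection is also acceptable
    amp, tau, floor = (scan.fit[k] for k in ("amplitude", "tau", "floor"))
    curve_span = amp * (np.exp(-scan.T_values[0] / tau)
                        - np.exp(-scan.T_values[-1] / tau))
    assert curve_span < 0.05 * floor


# ---------------------------------------------------------------------------
# Steady-state partition
# ---------------------------------------------------------------------------

def test_partition_sums_to_one():
    part = steady_state_partition(REF)
    assert sum(part.values()) == pytest.approx(1.0, abs=1e-9)
    # Zeaxanthin dominates both channels at steady state.
    assert part["qE_Z"] > 0.5
    assert 0.1 < part["qZ"] < 0.4


def test_partition_no_qZ_channel():
    part = steady_state_partition(REF.replace(r_qZ=0.0))
    assert part["qZ"] == 0.0


def test_partition_pure_qZ_without_protein():
    part = steady_state_partition(REF.replace(P_tot=0.0))
    assert part["qZ"] == pytest.approx(1.0)


def test_partition_undefined_without_any_channel():
    with pytest.raises(ValueError):
        steady_state_partition(REF.replace(P_tot=0.0, r_qZ=0.0))


# ---------------------------------------------------------------------------
# Quencher stoichiometry
# ---------------------------------------------------------------------------

def test_stoichiometry_example():
    s = quencher_stoichiometry(0.6, chl_per_protein=10.0, npq_limit=1.106,
                               tau_F0_ns=1.5)
    assert s.protein_fraction == pytest.approx(0.006)
    assert s.one_in == pytest.approx(166.7, rel=1e-3)
    # 0.006 * 1500 ps / 1.106 = 8.14 ps
    assert s.lifetime_bound_ps == pytest.approx(8.14, rel=1e-3)
    assert s.is_estimate


def test_stoichiometry_computes_npq_limit_from_model():
    s = quencher_stoichiometry(0.6, params=REF)
    assert s.npq_limit == pytest.approx(1.106, rel=0.01)
    assert s.lifetime_bound_ps < 10.0


def test_stoichiometry_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        quencher_stoichiometry(0.0)
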