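"""Two-stage constrained parameter estimation with bootstrap uncertainty.

Stage 1 (:func:`fit_hplc_reduced`) fits a pool-only first-order model of
xanthophyll interconversion, with exponential VDE activation, to HPLC
Delta[X] series; it determines the V -> A -> Z and Z -> A -> V rate
constants and the VDE activation kinetics.

Stage 2 (:func:`fit_npq`) fits the full quenching model to NPQ_tau traces
by least squares, with the stage-1 interconversion parameters box-constrained
to within +/-50% of their seeded values and binding/activation rates shared
across the three xanthophylls.  The optimizer is a multi-start bounded
least-squares (Latin-hypercube starts) followed by a derivative-free
compass-search refinement.

Uncertainty comes from :func:`bootstrap_fit`, which resamples replicate
traces (case bootstrap) or residual blocks and reports two-standard-error
intervals per parameter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import KineticParameters, dark_steady_state, simulate
from .observables import HPLCSeries, NPQTrace, npq_trace, total_xanthophylls
from .protocols import LightProtocol

__all__ = [
    "FitResult",
    "FitError",
    "fit_hplc_reduced",
    "fit_npq",
    "bootstrap_fit",
    "bootstrap_two_stage",
    "fit_unit_conversion",
    "rmsd",
]

# Interconversion parameters seeded from the HPLC stage and box-constrained
# to +/-50% during the NPQ fit.
VAZ_PARAMS = ("k_VA", "k_AZ", "alpha_max_dark", "k_ZA", "k_AV",
              "k_VDE_light", "k_VDE_dark")

# Quenching-side parameters, free within broad fixed bounds.
_QUENCH_BOUNDS: Dict[str, Tuple[float, float]] = {
    "q_V": (1e-4, 0.999),
    "q_A": (1e-4, 0.999),
    "q_Z": (1e-4, 0.999),
    "r_qZ": (0.0, 0.5),
    "k_QX_light": (0.2, 30.0),
    "k_QX_dark": (0.2, 30.0),
    "k_bind_f": (0.05, 100.0),
    "k_bind_b": (0.05, 100.0),
}

_FIT_RK4_DT = 0.02  # min; fixed-step size of the fast integration path

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Optimization failed or the data cannot constrain the model."""


@dataclass
class FitResult:
    """Point estimates, uncertainty intervals and diagnostics of a fit."""

    params: KineticParameters
    estimates: Dict[str, float]
    objective: float
    rmsd_per_sequence: Dict[str, float] = field(default_factory=dict)
    se: Optional[Dict[str, float]] = None
    intervals: Optional[Dict[str, Tuple[float, float]]] = None
    free_names: Tuple[str, ...] = ()
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be non-negative")
        if self.intervals is not None:
            for name, (lo, hi) in self.intervals.items():
                est = self.estimates[name]
                if not (lo - 1e-12 <= est <= hi + 1e-12):
                    raise ValueError(f"interval for {name} does not contain the estimate")

    def to_frame(self):
        import pandas as pd

        rows = []
        for name in self.free_names or self.estimates:
            lo, hi = (self.intervals or {}).get(name, (np.nan, np.nan))
            rows.append({"parameter": name, "estimate": self.estimates[name],
                         "lo": lo, "hi": hi})
        return pd.DataFrame(rows)


def rmsd(pred: np.ndarray, obs: np.ndarray) -> float:
    """Root-mean-square deviation between two equal-length series."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if pred.size < 1:
        raise ValueError("series must contain at least one point")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def fit_unit_conversion(model_totals: HPLCSeries, data: HPLCSeries) -> float:
    """Single nonnegative scale from reduced-unit to HPLC concentration changes.

    Closed form: c = sum(m*d) / sum(m^2) over all three pigments and matched
    time points, clipped at zero.
    """
    if model_totals.times.shape != data.times.shape or \
            not np.allclose(model_totals.times, data.times):
        raise ValueError("model and data series must share their time points")
    m = np.concatenate([model_totals.delta[x] for x in ("V", "A", "Z")])
    d = np.concatenate([data.delta[x] for x in ("V", "A", "Z")])
    mm = float(np.dot(m, m))
    if mm == 0.0:
        raise FitError("model totals are identically zero; conversion undefined")
    return max(0.0, float(np.dot(m, d) / mm))


# ---------------------------------------------------------------------------
# Stage 1: pool-only fit to HPLC data
# ---------------------------------------------------------------------------

def _pool_params(theta: np.ndarray) -> KineticParameters:
    """Pool-only model: the full model with the protein channel removed.

    With no protein and no binding the remaining dynamics are exactly the
    first-order V/A/Z chain driven by the VDE activity, expressed in the
    concentration units of the data (labile pool total ``theta[7]``).
    """
    k_VA, k_AZ, amd, k_ZA, k_AV, kvl, kvd, L = theta
    return KineticParameters(
        k_bind_f=0.0, k_bind_b=0.0, P_tot=0.0, X_tot=L, c_hplc=1.0,
        k_VA=k_VA, k_AZ=k_AZ, alpha_max_dark=min(amd, 1.0),
        k_ZA=k_ZA, k_AV=k_AV, k_VDE_light=kvl, k_VDE_dark=kvd,
    )


def _predict_pool_deltas(theta: np.ndarray, protocol: LightProtocol,
                         times: np.ndarray) -> Dict[str, np.ndarray]:
    p = _pool_params(theta)
    traj = simulate(protocol, p, method="rk4", rk4_dt=_FIT_RK4_DT, output_dt=0.25)
    series = total_xanthophylls(traj, p)
    return {x: np.interp(times, series.times, series.delta[x]) for x in ("V", "A", "Z")}


def fit_hplc_reduced(hplc: Sequence[HPLCSeries], x0: Optional[Dict[str, float]] = None,
                     ) -> Dict[str, float]:
    """Least-squares fit of the reduced interconversion model to HPLC data.

    Every series must carry its exposure protocol.  Returns the seven
    interconversion parameters (per minute; ``alpha_max_dark`` dimensionless)
    plus the fitted labile pool size ``pool_size`` in data units.

    Raises
    ------
    FitError
        If no series is given, a series lacks its protocol, or the data are
        too sparse to constrain the kinetics (fewer than two distinct
        post-zero time points in total).
    """
    if not hplc:
        raise FitError("at least one HPLC series is required")
    for s in hplc:
        if s.protocol is None:
            raise FitError(f"series {s.label!r} has no protocol attached")
    n_info = sum(int(np.sum(s.times > 0)) for s in hplc)
    if n_info < 2:
        raise FitError("HPLC data underdetermined: need at least two post-zero samples")

    scale = max(max(np.max(np.abs(s.delta[x])) for x in ("V", "A", "Z")) for s in hplc)
    defaults = {"k_VA": 0.1, "k_AZ": 0.1, "alpha_max_dark": 1e-3, "k_ZA": 0.1,
                "k_AV": 0.05, "k_VDE_light": 1.0, "k_VDE_dark": 1.0,
                "pool_size": max(5.0 * scale, 1.0)}
    if x0:
        defaults.update(x0)
    names = list(VAZ_PARAMS) + ["pool_size"]
    theta0 = np.array([defaults[n] for n in names])
    lb = np.array([1e-8, 1e-8, 0.0, 1e-8, 1e-8, 1e-3, 1e-3, max(scale, 1e-6)])
    ub = np.array([10.0, 10.0, 1.0, 10.0, 10.0, 50.0, 50.0, 1e4 * max(scale, 1.0)])
    theta0 = np.clip(theta0, lb, ub)

    def residuals(theta):
        out = []
        for s in hplc:
            pred = _predict_pool_deltas(theta, s.protocol, s.times)
            for x in ("V", "A", "Z"):
                out.append(pred[x] - s.delta[x])
        return np.concatenate(out)

    sol = least_squares(residuals, theta0, bounds=(lb, ub), x_scale="jac",
                        ftol=1e-12, xtol=1e-12, gtol=1e-12)
    if not sol.success and sol.status <= 0:
        raise FitError(f"HPLC reduced fit failed: {sol.message}")
    result = {n: float(v) for n, v in zip(names, sol.x)}
    result["objective"] = float(np.sum(sol.fun ** 2))
    return result


# ---------------------------------------------------------------------------
# Stage 2: full-model fit to NPQ traces
# ---------------------------------------------------------------------------

def _params_from_vector(x: np.ndarray, names: Sequence[str],
                        base: KineticParameters) -> KineticParameters:
    updates: Dict[str, float] = {}
    for name, val in zip(names, x):
        if name in ("q_V", "q_A", "q_Z"):
            key = {"q_V": "K_QV_light", "q_A": "K_QA_light", "q_Z": "K_QZ_light"}[name]
            updates[key] = val / (1.0 - val)
        else:
            updates[name] = val
    return base.replace(**updates)


def _vector_from_params(params: KineticParameters, names: Sequence[str]) -> np.ndarray:
    out = []
    for name in names:
        if name in ("q_V", "q_A", "q_Z"):
            K = getattr(params, {"q_V": "K_QV_light", "q_A": "K_QA_light",
                                 "q_Z": "K_QZ_light"}[name])
            out.append(K / (1.0 + K))
        else:
            out.append(getattr(params, name))
    return np.array(out, dtype=float)


def _grouped(traces: Sequence[NPQTrace]) -> Dict[str, List[NPQTrace]]:
    groups: Dict[str, List[NPQTrace]] = {}
    for tr in traces:
        if tr.protocol is None:
            raise FitError(f"trace {tr.label!r} has no protocol attached")
        groups.setdefault(tr.protocol.label, []).append(tr)
    return groups


def _stable_dt(params: KineticParameters) -> float:
    """Fixed step small enough for the fastest linearized rate in the model."""
    lam = (params.k_bind_f * params.X_tot + params.k_bind_b
           + max(params.k_QX_light, params.k_QX_dark)
           + max(params.k_VDE_light, params.k_VDE_dark))
    return min(_FIT_RK4_DT, 2.0 / max(lam, 1e-12))


def _npq_residuals(params: KineticParameters, traces: Sequence[NPQTrace]) -> np.ndarray:
    n_total = sum(len(tr) for tr in traces)
    try:
        init = dark_steady_state(params)
    except Exception:
        return np.full(n_total, 1e3)
    dt = _stable_dt(params)
    out = []
    cache: Dict[str, np.ndarray] = {}
    cache_t: Dict[str, np.ndarray] = {}
    for tr in traces:
        key = tr.protocol.label
        if key not in cache:
            traj = simulate(tr.protocol, params, init=init, method="rk4",
                            rk4_dt=dt, output_dt=0.25)
            if not np.all(np.isfinite(traj.states)):
                return np.full(n_total, 1e3)
            mod = npq_trace(traj, params, check_reference=False)
            cache[key] = mod.npq
            cache_t[key] = mod.times
        out.append(np.interp(tr.times, cache_t[key], cache[key]) - tr.npq)
    return np.concatenate(out)


def _compass_search(fun, x0, lb, ub, f0, step0=0.05, min_step=1e-4,
                    max_evals=400) -> Tuple[np.ndarray, float, int]:
    """Derivative-free pattern (compass) refinement on box-normalized axes."""
    span = ub - lb
    span[span == 0] = 1.0
    x, fbest = x0.copy(), f0
    step = step0
    nev = 0
    while step >= min_step and nev < max_evals:
        improved = False
        for i in range(x.size):
            if ub[i] - lb[i] < 1e-12:
                continue
            for sgn in (+1.0, -1.0):
                xi = x.copy()
                xi[i] = np.clip(x[i] + sgn * step * span[i], lb[i], ub[i])
                if xi[i] == x[i]:
                    continue
                f = fun(xi)
                nev += 1
                if f < fbest - 1e-15:
                    x, fbest = xi, f
                    improved = True
                    break
                if nev >= max_evals:
                    break
            if nev >= max_evals:
                break
        if not improved:
            step *= 0.5
    return x, fbest, nev


def fit_npq(
    traces: Sequence[NPQTrace],
    init: KineticParameters,
    constraints: Optional[Dict[str, Tuple[float, float]]] = None,
    n_starts: int = 16,
    seed: int = 0,
    free_totals: bool = False,
    free_binding: bool = False,
    max_nfev: int = 30,
    pattern_evals: int = 300,
) -> FitResult:
    """Constrained global fit of the full model to NPQ_tau traces.

    Parameters
    ----------
    traces
        NPQ traces, each carrying its light protocol; replicate traces of
        the same protocol contribute independent residuals (plain sum of
        squares, uniform weights).
    init
        Starting parameters; the interconversion (VAZ-step) entries should
        come from :func:`fit_hplc_reduced` and are box-constrained to within
        +/-50% of their values here.
    constraints
        Optional overrides of per-parameter ``(lo, hi)`` bounds.
    n_starts
        Latin-hypercube starts for the quenching-side parameters.
    free_totals
        Also fit ``P_tot`` and ``X_tot``.  Off by default: the observables
        are invariant under a joint rescaling of the totals against the
        quenching parameters, so the totals are structurally unidentifiable
        from NPQ data alone and are treated as fixed conventions.
    free_binding
        Also fit ``k_bind_f`` and ``k_bind_b``.  Off by default: snapshot
        NPQ data only constrain the equilibrium occupancy of the bound pool,
        not the binding kinetics themselves, which leaves a sloppy ridge
        along which stronger binding trades off against smaller quenching
        capacities with a noise-equivalent objective.  Pinning the binding
        rates to their seeded values selects a point on that ridge and makes
        the quenching capacities well determined.
    """
    if not traces:
        raise FitError("at least one NPQ trace is required")
    groups = _grouped(traces)

    names = [n for n in _QUENCH_BOUNDS
             if free_binding or n not in ("k_bind_f", "k_bind_b")]
    bounds: Dict[str, Tuple[float, float]] = {n: _QUENCH_BOUNDS[n] for n in names}
    for name in VAZ_PARAMS:
        v = getattr(init, name)
        # A zero seed pins the parameter (a knockout stays a knockout).
        bounds[name] = (0.5 * v, 1.5 * v if v > 0 else 1e-10)
        names.append(name)
    if free_totals:
        bounds["P_tot"] = (0.1 * init.P_tot, 10.0 * init.P_tot)
        bounds["X_tot"] = (0.1 * init.X_tot, 10.0 * init.X_tot)
        names.extend(["P_tot", "X_tot"])
    if constraints:
        bounds.update(constraints)
    # alpha_max_dark can never exceed 1 by definition.
    lo, hi = bounds["alpha_max_dark"]
    bounds["alpha_max_dark"] = (lo, min(hi, 1.0))

    lb = np.array([bounds[n][0] for n in names])
    ub = np.array([bounds[n][1] for n in names])
    x_init = np.clip(_vector_from_params(init, names), lb, ub)

    def residuals(x):
        return _npq_residuals(_params_from_vector(x, names, init), traces)

    def objective(x):
        r = residuals(x)
        return float(np.dot(r, r))

    # Multi-start over the quenching-side box; VAZ entries start at the seed.
    rng = np.random.default_rng(seed)
    n_q = sum(1 for n in names if n in _QUENCH_BOUNDS)
    sampler = qmc.LatinHypercube(d=n_q, seed=rng.integers(2**31 - 1))
    unit = sampler.random(max(n_starts - 1, 0))
    starts = [x_init.copy()]
    for row in unit:
        x = x_init.copy()
        x[:n_q] = lb[:n_q] + row * (ub[:n_q] - lb[:n_q])
        starts.append(x)

    logger.info("fit_npq: %d traces over sequences %s, %d starts",
                len(traces), sorted(groups), len(starts))
    best = None
    start_objectives = []
    for i, x0 in enumerate(starts[: max(n_starts, 1)]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = least_squares(residuals, x0, bounds=(lb, ub), x_scale="jac",
                                max_nfev=max_nfev, ftol=1e-10, xtol=1e-10)
        obj = float(np.dot(sol.fun, sol.fun))
        start_objectives.append(obj)
        logger.info("fit_npq: start %d/%d nfev=%d objective=%.6g",
                    i + 1, len(starts), sol.nfev, obj)
        if best is None or obj < best[1]:
            best = (sol.x.copy(), obj)
    if best is None:
        raise FitError("no optimizer start succeeded")

    # Polish the winner, then pattern-search refinement.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = least_squares(residuals, best[0], bounds=(lb, ub), x_scale="jac",
                            max_nfev=4 * max_nfev, ftol=1e-12, xtol=1e-12)
    x_best, obj_best = sol.x.copy(), float(np.dot(sol.fun, sol.fun))
    if obj_best > best[1]:
        x_best, obj_best = best
    x_best, obj_best, n_pattern = _compass_search(
        objective, x_best, lb, ub, obj_best, max_evals=pattern_evals)
    logger.info("fit_npq: refined objective=%.6g (pattern evals %d)",
                obj_best, n_pattern)

    flat = (np.std(start_objectives) <= 1e-10 * (1.0 + np.mean(start_objectives))
            and len(start_objectives) > 1)
    if flat:
        warnings.warn(
            "objective is flat across all starts: the supplied data do not "
            "constrain the free parameters (identifiability guard)",
            RuntimeWarning,
        )

    params_hat = _params_from_vector(x_best, names, init)
    estimates = {n: float(v) for n, v in zip(names, x_best)}

    rmsds = {}
    init_state = dark_steady_state(params_hat)
    for label, group in groups.items():
        traj = simulate(group[0].protocol, params_hat, init=init_state,
                        method="rk4", rk4_dt=_FIT_RK4_DT, output_dt=0.25)
        mod = npq_trace(traj, params_hat, check_reference=False)
        obs = np.mean([tr.npq for tr in group], axis=0)
        rmsds[label] = rmsd(np.interp(group[0].times, mod.times, mod.npq), obs)

    return FitResult(
        params=params_hat,
        estimates=estimates,
        objective=obj_best,
        rmsd_per_sequence=rmsds,
        free_names=tuple(names),
        bounds=bounds,
        meta={
            "n_starts": len(starts),
            "seed": seed,
            "start_objectives": start_objectives,
            "pattern_evals": n_pattern,
            "flat_objective": bool(flat),
            "training_sequences": sorted(groups),
        },
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _refit_from(fit: FitResult, traces: Sequence[NPQTrace],
                max_nfev: int) -> np.ndarray:
    names = list(fit.free_names)
    lb = np.array([fit.bounds[n][0] for n in names])
    ub = np.array([fit.bounds[n][1] for n in names])
    x0 = np.array([fit.estimates[n] for n in names])
    base = fit.params

    def residuals(x):
        return _npq_residuals(_params_from_vector(x, names, base), traces)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = least_squares(residuals, np.clip(x0, lb, ub), bounds=(lb, ub),
                            x_scale="jac", max_nfev=max_nfev, ftol=1e-9, xtol=1e-9)
    return sol.x


def _case_resample(groups: Dict[str, List[NPQTrace]], rng) -> List[NPQTrace]:
    out: List[NPQTrace] = []
    for label in sorted(groups):
        reps = groups[label]
        idx = rng.integers(0, len(reps), size=len(reps))
        out.extend(reps[i] for i in idx)
    return out


def _block_resample(trace: NPQTrace, model_npq: np.ndarray, rng,
                    block_min: float) -> NPQTrace:
    resid = trace.npq - model_npq
    dt = float(np.median(np.diff(trace.times)))
    block = max(1, int(round(block_min / dt)))
    n = resid.size
    starts = rng.integers(0, n, size=(n // block) + 1)
    pieces = [resid[(s + np.arange(block)) % n] for s in starts]
    new_resid = np.concatenate(pieces)[:n]
    return NPQTrace(times=trace.times.copy(), npq=model_npq + new_resid,
                    label=trace.label, replicate=trace.replicate,
                    protocol=trace.protocol)


def bootstrap_fit(
    fit: FitResult,
    traces: Sequence[NPQTrace],
    n_resamples: int = 1000,
    seed: int = 0,
    method: str = "case",
    block_min: float = 1.0,
    max_nfev: int = 12,
) -> FitResult:
    """Bootstrap the training traces and report 2-SE parameter intervals.

    ``method="case"`` resamples replicate traces with replacement within
    each protocol (requires >= 2 replicates somewhere); ``method="residual"``
    uses a moving-block resampling of the residuals about the fitted curves
    (usable with a single replicate).  Each resample is refitted starting
    from the point estimate.  Deterministic for a given seed.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be at least 2")
    groups = _grouped(traces)
    if method == "case" and all(len(g) < 2 for g in groups.values()):
        raise FitError(
            "case bootstrap needs replicate traces; use method='residual' "
            "for single-replicate data"
        )
    rng = np.random.default_rng(seed)

    model_curves: Dict[str, np.ndarray] = {}
    if method == "residual":
        init_state = dark_steady_state(fit.params)
        for label, group in groups.items():
            traj = simulate(group[0].protocol, fit.params, init=init_state,
                            method="rk4", rk4_dt=_FIT_RK4_DT, output_dt=0.25)
            mod = npq_trace(traj, fit.params, check_reference=False)
            model_curves[label] = np.interp(group[0].times, mod.times, mod.npq)

    samples = []
    for _ in range(n_resamples):
        if method == "case":
            resampled = _case_resample(groups, rng)
        elif method == "residual":
            resampled = [
                _block_resample(tr, model_curves[label], rng, block_min)
                for label in sorted(groups) for tr in groups[label]
            ]
        else:
            raise ValueError(f"unknown bootstrap method {method!r}")
        samples.append(_refit_from(fit, resampled, max_nfev=max_nfev))
    arr = np.asarray(samples)

    names = list(fit.free_names)
    se = {n: float(np.std(arr[:, i], ddof=1)) for i, n in enumerate(names)}
    intervals = {
        n: (fit.estimates[n] - 2.0 * se[n], fit.estimates[n] + 2.0 * se[n])
        for n in names
    }
    meta = dict(fit.meta)
    meta.update({"bootstrap_n": n_resamples, "bootstrap_seed": seed,
                 "bootstrap_method": method})
    return FitResult(
        params=fit.params,
        estimates=dict(fit.estimates),
        objective=fit.objective,
        rmsd_per_sequence=dict(fit.rmsd_per_sequence),
        se=se,
        intervals=intervals,
        free_names=fit.free_names,
        bounds=dict(fit.bounds),
        meta=meta,
    )


def _grouped_hplc(hplc: Sequence[HPLCSeries]) -> Dict[str, List[HPLCSeries]]:
    groups: Dict[str, List[HPLCSeries]] = {}
    for s in hplc:
        if s.protocol is None:
            raise FitError(f"series {s.label!r} has no protocol attached")
        groups.setdefault(s.protocol.label, []).append(s)
    return groups


def bootstrap_two_stage(
    fit: FitResult,
    traces: Sequence[NPQTrace],
    hplc: Sequence[HPLCSeries],
    stage1: Dict[str, float],
    n_resamples: int = 200,
    seed: int = 0,
    max_nfev: int = 12,
) -> FitResult:
    """Bootstrap the full two-stage pipeline and report 2-SE intervals.

    The plain NPQ bootstrap (:func:`bootstrap_fit`) holds the stage-1
    interconversion seeds fixed, so it cannot see the component of the
    stage-2 error that enters through the HPLC fit; its intervals
    undercover for the stage-1-seeded parameters.  Here each resample
    case-resamples the HPLC replicate series *and* the NPQ replicate
    traces, refits stage 1 (warm-started from the full-data solution),
    rebuilds the +/-50% interconversion box around the new seeds, and
    refits stage 2 from the point estimate.  Deterministic for a given
    seed.  Requires >= 2 replicates of both data types.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be at least 2")
    npq_groups = _grouped(traces)
    hplc_groups = _grouped_hplc(hplc)
    if all(len(g) < 2 for g in npq_groups.values()) or \
            all(len(g) < 2 for g in hplc_groups.values()):
        raise FitError("two-stage bootstrap needs replicate NPQ traces and "
                       "replicate HPLC series")
    rng = np.random.default_rng(seed)
    names = list(fit.free_names)
    warm = {k: stage1[k] for k in list(VAZ_PARAMS) + ["pool_size"]}

    samples = []
    for _ in range(n_resamples):
        hplc_b: List[HPLCSeries] = []
        for label in sorted(hplc_groups):
            reps = hplc_groups[label]
            idx = rng.integers(0, len(reps), size=len(reps))
            hplc_b.extend(reps[i] for i in idx)
        traces_b = _case_resample(npq_groups, rng)
        try:
            s1 = fit_hplc_reduced(hplc_b, x0=warm)
        except FitError:
            continue
        base = fit.params.replace(
            **{k: max(s1[k], 0.0) for k in VAZ_PARAMS})
        lb, ub, x0 = [], [], []
        for n in names:
            if n in VAZ_PARAMS:
                v = getattr(base, n)
                lo = 0.5 * v
                hi = 1.5 * v if v > 0 else 1e-10
                if n == "alpha_max_dark":
                    hi = min(hi, 1.0)
                x0.append(v)
            else:
                lo, hi = fit.bounds[n]
                x0.append(fit.estimates[n])
            lb.append(lo)
            ub.append(hi)
        lb, ub = np.array(lb), np.array(ub)
        x0 = np.clip(np.array(x0), lb, ub)

        def residuals(x):
            return _npq_residuals(_params_from_vector(x, names, base), traces_b)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = least_squares(residuals, x0, bounds=(lb, ub), x_scale="jac",
                                max_nfev=max_nfev, ftol=1e-9, xtol=1e-9)
        obj = float(np.dot(sol.fun, sol.fun))
        samples.append((sol.x, obj))
    if len(samples) < 2:
        raise FitError("two-stage bootstrap: too few successful resamples")

    # A refit is only a valid draw from the resampling distribution if the
    # optimizer actually converged on its resample.  Diverged refits (an
    # objective far above the typical resample objective) are optimizer
    # failures, not statistical variation; drop them and report the count.
    objs = np.array([o for _, o in samples])
    cutoff = 2.0 * float(np.median(objs))
    kept = [x for x, o in samples if o <= cutoff]
    n_dropped = len(samples) - len(kept)
    if len(kept) < 2:
        raise FitError("two-stage bootstrap: too few converged resamples")
    arr = np.asarray(kept)

    # Robust normal-reference scale (IQR/1.349) rather than the plain SD:
    # the cheap single-start refits occasionally wander along the sloppy
    # ridge on individual resamples, and those optimizer excursions dominate
    # a plain SD while barely moving the quartiles.
    q25 = np.quantile(arr, 0.25, axis=0)
    q75 = np.quantile(arr, 0.75, axis=0)
    se = {n: float((q75[i] - q25[i]) / 1.349) for i, n in enumerate(names)}
    intervals = {
        n: (fit.estimates[n] - 2.0 * se[n], fit.estimates[n] + 2.0 * se[n])
        for n in names
    }
    meta = dict(fit.meta)
    meta.update({
        "bootstrap_n": len(kept),
        "bootstrap_dropped": n_dropped,
        "bootstrap_seed": seed,
        "bootstrap_method": "two_stage",
        "bootstrap_quantiles": {
            n: [float(q) for q in
                np.quantile(arr[:, i], [0.05, 0.25, 0.5, 0.75, 0.95])]
            for i, n in enumerate(names)
        },
    })
    return FitResult(
        params=fit.params,
        estimates=dict(fit.estimates),
        objective=fit.objective,
        rmsd_per_sequence=dict(fit.rmsd_per_sequence),
        se=se,
        intervals=intervals,
        free_names=fit.free_names,
        bounds=dict(fit.bounds),
        meta=meta,
    )
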