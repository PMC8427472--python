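"""Free energy estimation: thermodynamic integration and MBAR.

Thermodynamic integration treats the quadrature of <dU/dlambda> over lambda
as a stochastic integral: each window mean carries an autocorrelation-
corrected standard error, and quadrature weights propagate those errors
into the integral assuming independent windows.

MBAR (multistate Bennett acceptance ratio) solves the self-consistent
equations

    f_k = -ln sum_n exp(-u_kn) / sum_l N_l exp(f_l - u_ln)

for the dimensionless free energies of all K states jointly, anchored at
f_0 = 0, and reports per-state asymptotic errors from the standard
covariance estimator.  The solver warm-starts with self-consistent
iteration and finishes with damped Newton steps on the MBAR objective;
log-sum-exp is used throughout for overflow safety.

Ensemble (replica-level) combination is kept separate from within-replica
errors: an ensemble estimate reports the replica mean, the between-replica
sample SD, and the SEM, never silently merged with the per-replica
stochastic errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import logsumexp

from .constants import kt_kcal
from .synthdata import DhdlEnsemble, LambdaSchedule, ReducedPotentialSet

__all__ = [
    "WindowStat",
    "FreeEnergyEstimate",
    "MbarConvergenceError",
    "statistical_inefficiency",
    "window_mean_and_sem",
    "ti_integrate",
    "ti_per_replica",
    "ti_ensemble",
    "mbar_solve",
    "mbar_delta_g",
    "mbar_ensemble",
    "ensemble_combine",
    "ddg_from_legs",
    "replica_range_report",
]


# ---------------------------------------------------------------------------
# per-window statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowStat:
    """Mean dU/dlambda of one window with autocorrelation-corrected SEM."""

    lam: float
    mean_dhdl: float
    sem_dhdl: float
    n_eff: float
    n: int


def statistical_inefficiency(series: Sequence[float]) -> float:
    """Statistical inefficiency g = 1 + 2 sum_t rho(t).

    The normalized autocovariance (biased estimator, computed by FFT) is
    summed until its first non-positive value — the initial-positive-
    sequence truncation.  g is clipped to >= 1; for a constant series g = 1.
    For an AR(1) process with lag-1 correlation rho, g -> (1+rho)/(1-rho).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean()
    c0 = float(xc @ xc) / n
    if c0 == 0.0:
        return 1.0
    # full autocovariance via FFT, biased normalization (divide by n)
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n] / n
    rho = acov / acov[0]
    g = 1.0
    for t in range(1, n):
        if rho[t] <= 0.0:
            break
        g += 2.0 * rho[t]
    return max(1.0, g)


def window_mean_and_sem(series: Sequence[float], lam: float = math.nan) -> WindowStat:
    """Mean and autocorrelation-corrected SEM of a dU/dlambda series.

    SEM = sd * sqrt(g / n) with sd the sample SD (n-1 denominator) and g
    the statistical inefficiency; n_eff = n / g.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples per window")
    g = statistical_inefficiency(x)
    sd = float(np.std(x, ddof=1))
    return WindowStat(
        lam=float(lam),
        mean_dhdl=float(x.mean()),
        sem_dhdl=sd * math.sqrt(g / x.size),
        n_eff=x.size / g,
        n=x.size,
    )


# ---------------------------------------------------------------------------
# free energy container
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyEstimate:
    """A free energy (difference) in kcal/mol with its uncertainty.

    ``error`` is the method's own statistical error (stochastic-integral
    propagation for TI, asymptotic covariance for MBAR, SEM for ensemble
    means).  When per-replica values are present, ``value`` is their
    arithmetic mean and ``replica_sd`` their sample SD.
    """

    value: float
    error: float
    method: Literal["TI", "MBAR"]
    per_replica: tuple[float, ...] | None = None
    replica_sd: float | None = None

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("error must be >= 0")
        if self.per_replica is not None:
            self.per_replica = tuple(float(x) for x in self.per_replica)
            if not math.isclose(
                self.value, float(np.mean(self.per_replica)),
                rel_tol=1e-9, abs_tol=1e-9,
            ):
                raise ValueError("value must equal the mean of per_replica")


# ---------------------------------------------------------------------------
# thermodynamic integration
# ---------------------------------------------------------------------------

def _quadrature_weights(
    lambdas: np.ndarray, rule: Literal["trapezoid", "natural_spline"]
) -> np.ndarray:
    if rule == "trapezoid":
        w = np.zeros_like(lambdas)
        d = np.diff(lambdas)
        w[:-1] += d / 2.0
        w[1:] += d / 2.0
        return w
    if rule == "natural_spline":
        # cardinal-basis integration: weight_i = integral of the natural
        # cubic spline through the i-th unit vector
        w = np.empty_like(lambdas)
        for i in range(lambdas.size):
            e = np.zeros_like(lambdas)
            e[i] = 1.0
            w[i] = CubicSpline(lambdas, e, bc_type="natural").integrate(
                lambdas[0], lambdas[-1]
            )
        return w
    raise ValueError(f"unknown quadrature rule {rule!r}")


def ti_integrate(
    stats: Sequence[WindowStat],
    schedule: LambdaSchedule,
    quadrature: Literal["trapezoid", "natural_spline"] = "trapezoid",
) -> FreeEnergyEstimate:
    """Integrate window means over lambda; propagate window SEMs.

    value = sum_i w_i * mean_i, error = sqrt(sum_i w_i^2 * sem_i^2), with
    w_i the quadrature weights (composite trapezoid by default; a natural
    cubic-spline rule is available for sensitivity checks).  The error
    model treats windows as independent, i.e. the quadrature is a
    stochastic integral over independently sampled windows.
    """
    lams = np.asarray(schedule.lambdas)
    if len(stats) != lams.size:
        raise ValueError(
            f"{len(stats)} window stats for a {lams.size}-window schedule"
        )
    stat_lams = np.array([s.lam for s in stats])
    if np.any(np.diff(stat_lams) <= 0):
        raise ValueError("window stats must be sorted by increasing lambda")
    if not np.allclose(stat_lams, lams, atol=1e-12):
        raise ValueError("window stat lambdas do not match the schedule")
    w = _quadrature_weights(lams, quadrature)
    means = np.array([s.mean_dhdl for s in stats])
    sems = np.array([s.sem_dhdl for s in stats])
    return FreeEnergyEstimate(
        value=float(w @ means),
        error=float(np.sqrt(np.sum(w**2 * sems**2))),
        method="TI",
    )


def ti_per_replica(
    ensemble: DhdlEnsemble,
    quadrature: Literal["trapezoid", "natural_spline"] = "trapezoid",
) -> list[FreeEnergyEstimate]:
    """One TI estimate per replica of a dU/dlambda ensemble."""
    out = []
    for r in ensemble.replicas:
        stats = [
            window_mean_and_sem(s, lam=lam)
            for s, lam in zip(ensemble.replica_series(r), ensemble.schedule.lambdas)
        ]
        out.append(ti_integrate(stats, ensemble.schedule, quadrature=quadrature))
    return out


def ti_ensemble(
    ensemble: DhdlEnsemble,
    quadrature: Literal["trapezoid", "natural_spline"] = "trapezoid",
) -> FreeEnergyEstimate:
    """Per-replica TI followed by replica-level combination."""
    return ensemble_combine(ti_per_replica(ensemble, quadrature=quadrature))


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------

class MbarConvergenceError(RuntimeError):
    """MBAR self-consistent equations failed to converge within max_iter."""


def _mbar_log_denominator(f: np.ndarray, u_kn: np.ndarray, log_counts: np.ndarray) -> np.ndarray:
    # log sum_l N_l exp(f_l - u_ln), one value per sample
    return logsumexp(log_counts[:, None] + f[:, None] - u_kn, axis=0)


def _mbar_update(f: np.ndarray, u_kn: np.ndarray, log_counts: np.ndarray) -> np.ndarray:
    log_denom = _mbar_log_denominator(f, u_kn, log_counts)
    f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
    return f_new - f_new[0]


def _mbar_weights(f: np.ndarray, u_kn: np.ndarray, log_counts: np.ndarray) -> np.ndarray:
    """N x K weight matrix W[n, k] = exp(f_k - u_kn - log_denom_n)."""
    log_denom = _mbar_log_denominator(f, u_kn, log_counts)
    return np.exp(f[:, None] - u_kn - log_denom[None, :]).T


def _mbar_objective(f: np.ndarray, u_kn: np.ndarray, counts: np.ndarray) -> float:
    log_counts = np.log(counts)
    n_tot = counts.sum()
    log_denom = _mbar_log_denominator(f, u_kn, log_counts)
    return float(log_denom.sum() / n_tot - (counts / n_tot) @ f)


def _mbar_covariance(w: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the dimensionless free energies.

    Uses the SVD form Theta = V S (I - S V^T N V S)^+ S V^T with W = U S V^T
    the thin SVD of the N x K weight matrix and N = diag(counts), which is
    the standard estimator evaluated without forming any N x N matrix.
    """
    u, s, vt = np.linalg.svd(w, full_matrices=False)
    v = vt.T
    inner = np.eye(s.size) - (s[:, None] * vt) @ (counts[:, None] * v) * s[None, :]
    return v @ (s[:, None] * np.linalg.pinv(inner) * s[None, :]) @ vt


def mbar_solve(
    rp: ReducedPotentialSet,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    n_sci_warmup: int = 100,
) -> list[FreeEnergyEstimate]:
    """Solve the MBAR equations; return per-state free energies vs state 0.

    Each returned estimate is f_k - f_0 in kcal/mol with the asymptotic
    standard error of that difference.  Convergence means
    max |delta f| < tol between iterations; failure to converge raises
    :class:`MbarConvergenceError`.
    """
    counts = rp.counts.astype(float)
    if np.any(counts <= 0):
        raise ValueError("every sampled state must have at least one sample")
    if rp.n_states < 2:
        raise ValueError("MBAR needs at least 2 states")
    u_kn = rp.u_kn
    log_counts = np.log(counts)
    f = np.zeros(rp.n_states)

    converged = False
    iters = 0
    for _ in range(min(n_sci_warmup, max_iter)):
        f_new = _mbar_update(f, u_kn, log_counts)
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        iters += 1
        if delta < tol:
            converged = True
            break

    # damped Newton on f[1:] (f[0] anchored at 0)
    if not converged:
        n_tot = counts.sum()
        obj = _mbar_objective(f, u_kn, counts)
        while iters < max_iter:
            w = _mbar_weights(f, u_kn, log_counts)  # N x K
            col = w.sum(axis=0)
            grad = counts * (col - 1.0) / n_tot
            wn = w * counts[None, :]
            hess = -(wn.T @ wn) / n_tot
            np.fill_diagonal(hess, hess.diagonal() + counts * col / n_tot)
            try:
                step = np.linalg.solve(hess[1:, 1:], -grad[1:])
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess[1:, 1:], -grad[1:], rcond=None)[0]
            scale = 1.0
            for _ in range(30):
                f_try = f.copy()
                f_try[1:] = f[1:] + scale * step
                obj_try = _mbar_objective(f_try, u_kn, counts)
                if obj_try <= obj:
                    break
                scale *= 0.5
            else:  # Newton stalled; fall back to one SCI sweep
                f_try = _mbar_update(f, u_kn, log_counts)
                obj_try = _mbar_objective(f_try, u_kn, counts)
            delta = float(np.max(np.abs(f_try - f)))
            f, obj = f_try, obj_try
            iters += 1
            if delta < tol:
                converged = True
                break

    if not converged:
        raise MbarConvergenceError(
            f"MBAR did not converge within {max_iter} iterations (last |df| = {delta:.3e})"
        )

    w = _mbar_weights(f, u_kn, log_counts)
    theta = _mbar_covariance(w, counts)
    kt = kt_kcal(rp.temperature)
    out = []
    for k in range(rp.n_states):
        var = theta[k, k] + theta[0, 0] - 2.0 * theta[k, 0]
        out.append(
            FreeEnergyEstimate(
                value=kt * float(f[k] - f[0]),
                error=kt * math.sqrt(max(var, 0.0)),
                method="MBAR",
            )
        )
    return out


def mbar_delta_g(
    rp: ReducedPotentialSet, tol: float = 1e-10, max_iter: int = 10_000
) -> FreeEnergyEstimate:
    """End-state free energy difference f_{K-1} - f_0 in kcal/mol."""
    return mbar_solve(rp, tol=tol, max_iter=max_iter)[-1]


def mbar_ensemble(
    replica_sets: Sequence[ReducedPotentialSet],
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> FreeEnergyEstimate:
    """Per-replica MBAR end-state differences, combined at replica level."""
    return ensemble_combine(
        [mbar_delta_g(rp, tol=tol, max_iter=max_iter) for rp in replica_sets]
    )


# ---------------------------------------------------------------------------
# replica-level combination
# ---------------------------------------------------------------------------

def ensemble_combine(per_replica: Sequence[FreeEnergyEstimate]) -> FreeEnergyEstimate:
    """Combine replica estimates: mean, between-replica SD, and SEM.

    The reported ``error`` is the SEM replica_sd / sqrt(n) — precision as
    assessed from independent replicas, not from any single replica's
    internal error estimate.
    """
    if len(per_replica) == 0:
        raise ValueError("need at least 1 replica estimate")
    methods = {e.method for e in per_replica}
    if len(methods) != 1:
        raise ValueError(f"mixed methods in ensemble: {sorted(methods)}")
    vals = np.array([e.value for e in per_replica])
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return FreeEnergyEstimate(
        value=float(vals.mean()),
        error=sd / math.sqrt(vals.size),
        method=per_replica[0].method,
        per_replica=tuple(vals),
        replica_sd=sd,
    )


def ddg_from_legs(
    complex_leg: FreeEnergyEstimate, solvent_leg: FreeEnergyEstimate
) -> FreeEnergyEstimate:
    """Relative binding free energy: complex-leg minus solvent-leg.

    Errors add in quadrature.  Per-replica differences are paired by
    replica index when both legs carry equally many replicas; on a count
    mismatch the difference falls back to unpaired propagation with a
    warning.
    """
    if complex_leg.method != solvent_leg.method:
        raise ValueError(
            f"method mismatch: {complex_leg.method} vs {solvent_leg.method}"
        )
    value = complex_leg.value - solvent_leg.value
    error = math.hypot(complex_leg.error, solvent_leg.error)
    per_replica = None
    replica_sd = None
    if complex_leg.per_replica is not None and solvent_leg.per_replica is not None:
        if len(complex_leg.per_replica) == len(solvent_leg.per_replica):
            diffs = np.array(complex_leg.per_replica) - np.array(solvent_leg.per_replica)
            per_replica = tuple(diffs)
            replica_sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
        else:
            warnings.warn(
                "replica counts differ between legs; using unpaired error propagation",
                stacklevel=2,
            )
    return FreeEnergyEstimate(
        value=value, error=error, method=complex_leg.method,
        per_replica=per_replica, replica_sd=replica_sd,
    )


def replica_range_report(
    per_replica_ddg: Sequence[float],
    mbar_errs: Sequence[float] | None = None,
) -> dict[str, float | None]:
    """Replica spread summary: mean, SD, min, max, range, mean MBAR error.

    Contrasting the between-replica range/SD with the mean per-replica
    MBAR asymptotic error exposes how far single-simulation error bars
    understate the true run-to-run variability.
    """
    vals = np.asarray(per_replica_ddg, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 replicas")
    mean_mbar = float(np.mean(mbar_errs)) if mbar_errs is not None else None
    return {
        "mean": float(vals.mean()),
        "sd": float(np.std(vals, ddof=1)),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "range": float(vals.max() - vals.min()),
        "mean_mbar_err": mean_mbar,
    }
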