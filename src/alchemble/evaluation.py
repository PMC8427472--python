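"""Accuracy/precision/bias statistics for relative binding free energies.

Calculated affinity differences (ddg_cal) are compared with experimental
ones (ddg_exp) per ligand pair.  Because a pair's sign is an arbitrary
ordering choice, every pair is first *rearranged* so that ddg_exp >= 0
(both values, and any per-replica values, negated together).  On the
rearranged set:

    MUE  = sum |ddg_exp - ddg_cal| / n
    MSE  = sum (ddg_cal - ddg_exp) / n          (signed; rearrangement matters)
    RMSE = sqrt( sum (ddg_exp - ddg_cal)^2 / n )

plus ordinary least squares ddg_cal = slope * ddg_exp + intercept with
Pearson r, bootstrap SDs of any metric by pair-level resampling, and a
binned underestimation analysis: pairs are grouped by ddg_exp into
[0, 1.37), [1.37, 2.73), [2.73, inf) kcal/mol (the printed 1- and
2-log-unit activity boundaries) and each bin reports the percentage of
pairs with ddg_cal strictly below ddg_exp and the mean signed deviation.
A shrinkage bias shows up as underestimation percentages that grow with
the bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .constants import DEFAULT_BIN_EDGES, KB_KCAL_MOL_K
from .synthdata import PairRecord

__all__ = [
    "BinStat",
    "EvaluationReport",
    "rearrange_pairs",
    "metrics",
    "regression_stats",
    "bootstrap_metric",
    "binned_underestimation",
    "log_units_to_kcal",
    "evaluate",
]


def log_units_to_kcal(log_units: float, temperature: float = 298.15) -> float:
    """Convert activity log units to kcal/mol: log_units * kB T ln(10)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return log_units * KB_KCAL_MOL_K * temperature * math.log(10.0)


# ---------------------------------------------------------------------------
# sign rearrangement
# ---------------------------------------------------------------------------

def rearrange_pairs(records: list[PairRecord]) -> list[PairRecord]:
    """Flip each pair with ddg_exp < 0 so that ddg_exp >= 0.

    Both ddg_exp and ddg_cal (and per-replica values) are negated together;
    uncertainties and order are untouched.  Pairs with ddg_exp exactly 0
    are left as-is, making the operation an involution.
    """
    out = []
    for rec in records:
        if rec.ddg_exp < 0:
            out.append(
                replace(
                    rec,
                    ddg_exp=-rec.ddg_exp,
                    ddg_cal=-rec.ddg_cal,
                    per_replica=None
                    if rec.per_replica is None
                    else tuple(-x for x in rec.per_replica),
                )
            )
        else:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def _arrays(records: list[PairRecord]) -> tuple[np.ndarray, np.ndarray]:
    exp = np.array([r.ddg_exp for r in records])
    cal = np.array([r.ddg_cal for r in records])
    return exp, cal


def metrics(records: list[PairRecord]) -> tuple[float, float, float]:
    """(MUE, MSE, RMSE) in kcal/mol over the rearranged pairs.

    MUE and RMSE are invariant to rearrangement; the signed MSE is defined
    on the rearranged set, where a negative value means net underestimation
    of the experimental differences.
    """
    if len(records) == 0:
        raise ValueError("need at least 1 pair")
    exp, cal = _arrays(rearrange_pairs(records))
    dev = cal - exp
    return (
        float(np.mean(np.abs(dev))),
        float(np.mean(dev)),
        float(np.sqrt(np.mean(dev**2))),
    )


def regression_stats(records: list[PairRecord]) -> tuple[float, float, float]:
    """(slope, intercept, pearson_r) of unweighted OLS ddg_cal ~ ddg_exp,
    fitted on the rearranged pairs."""
    if len(records) < 3:
        raise ValueError("need at least 3 pairs for regression")
    exp, cal = _arrays(rearrange_pairs(records))
    if np.unique(exp).size < 2:
        raise ValueError("degenerate regression: all ddg_exp identical")
    fit = sps.linregress(exp, cal)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


_METRIC_FNS = {
    "mue": lambda recs: metrics(recs)[0],
    "mse": lambda recs: metrics(recs)[1],
    "rmse": lambda recs: metrics(recs)[2],
    "slope": lambda recs: regression_stats(recs)[0],
    "intercept": lambda recs: regression_stats(recs)[1],
    "pearson_r": lambda recs: regression_stats(recs)[2],
}


def bootstrap_metric(
    records: list[PairRecord],
    metric_name: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Bootstrap SD of a metric by resampling pairs with replacement."""
    if len(records) < 2:
        raise ValueError("need at least 2 pairs to bootstrap")
    try:
        fn = _METRIC_FNS[metric_name]
    except KeyError:
        raise ValueError(
            f"unknown metric {metric_name!r}; choose from {sorted(_METRIC_FNS)}"
        ) from None
    rng = np.random.default_rng(seed)
    n = len(records)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vals[b] = fn([records[i] for i in idx])
    return float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# binned underestimation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinStat:
    """Underestimation statistics for one |ddg_exp| bin.

    ``pct_underestimated`` and ``mean_signed_dev`` are NaN for an empty bin
    — absence of pairs is not zero underestimation.
    """

    lo: float
    hi: float
    n: int
    pct_underestimated: float
    mean_signed_dev: float


def binned_underestimation(
    records: list[PairRecord],
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> tuple[list[BinStat], BinStat]:
    """Per-bin and total underestimation statistics over rearranged pairs.

    Bins are half-open [lo, hi) on ddg_exp after rearrangement (so all
    values are >= 0): [0, edges[0]), ..., [edges[-1], inf).  A pair is
    underestimated when ddg_cal < ddg_exp strictly; ties do not count.
    """
    edges_arr = np.asarray(edges, dtype=float)
    if np.any(edges_arr <= 0) or np.any(np.diff(edges_arr) <= 0):
        raise ValueError("edges must be positive and strictly increasing")
    exp, cal = _arrays(rearrange_pairs(records))
    bounds = np.concatenate([[0.0], edges_arr, [np.inf]])

    def _stat(mask: np.ndarray, lo: float, hi: float) -> BinStat:
        n = int(mask.sum())
        if n == 0:
            return BinStat(lo=lo, hi=hi, n=0,
                           pct_underestimated=math.nan, mean_signed_dev=math.nan)
        under = np.sum(cal[mask] < exp[mask])
        return BinStat(
            lo=lo, hi=hi, n=n,
            pct_underestimated=100.0 * float(under) / n,
            mean_signed_dev=float(np.mean(cal[mask] - exp[mask])),
        )

    bins = [
        _stat((exp >= lo) & (exp < hi), float(lo), float(hi))
        for lo, hi in zip(bounds[:-1], bounds[1:])
    ]
    total = _stat(np.ones_like(exp, dtype=bool), 0.0, math.inf)
    return bins, total


# ---------------------------------------------------------------------------
# aggregated report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Full benchmark summary: metrics with bootstrap SDs, regression, bins."""

    n_pairs: int
    mue: float
    mse: float
    rmse: float
    mue_sd: float
    mse_sd: float
    rmse_sd: float
    pearson_r: float
    slope: float
    intercept: float
    bins: list[BinStat]
    total: BinStat
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    n_boot: int = 1000

    def to_dict(self) -> dict:
        def _bin(b: BinStat) -> dict:
            return {
                "lo": b.lo,
                "hi": None if math.isinf(b.hi) else b.hi,
                "n": b.n,
                "pct_underestimated": None
                if math.isnan(b.pct_underestimated) else b.pct_underestimated,
                "mean_signed_dev": None
                if math.isnan(b.mean_signed_dev) else b.mean_signed_dev,
            }

        return {
            "n_pairs": self.n_pairs,
            "mue": self.mue, "mue_sd": self.mue_sd,
            "mse": self.mse, "mse_sd": self.mse_sd,
            "rmse": self.rmse, "rmse_sd": self.rmse_sd,
            "pearson_r": self.pearson_r,
            "slope": self.slope, "intercept": self.intercept,
            "bin_edges": list(self.bin_edges),
            "bins": [_bin(b) for b in self.bins],
            "total": _bin(self.total),
            "n_boot": self.n_boot,
        }

    def format_metrics_table(self) -> str:
        """Plain-text metric table (bootstrap SDs in parentheses)."""
        lines = [
            f"n pairs     {self.n_pairs}",
            f"MUE         {self.mue:6.2f} ({self.mue_sd:.2f})",
            f"MSE         {self.mse:6.2f} ({self.mse_sd:.2f})",
            f"RMSE        {self.rmse:6.2f} ({self.rmse_sd:.2f})",
            f"Pearson r   {self.pearson_r:6.2f}",
            f"Slope       {self.slope:6.2f}",
            f"Intercept   {self.intercept:6.2f}",
        ]
        return "\n".join(lines)

    def format_bin_table(self) -> str:
        """Plain-text underestimation-by-bin table."""
        def _row(label: str, b: BinStat) -> str:
            if b.n == 0:
                return f"{label:<22s} {b.n:>4d}   {'NA':>6s}   {'NA':>7s}"
            return (
                f"{label:<22s} {b.n:>4d}   {b.pct_underestimated:6.1f}"
                f"   {b.mean_signed_dev:7.2f}"
            )

        lines = [f"{'|ddG_exp| bin':<22s} {'n':>4s}   {'%under':>6s}   {'meandev':>7s}"]
        for b in self.bins:
            hi = "inf" if math.isinf(b.hi) else f"{b.hi:g}"
            lines.append(_row(f"[{b.lo:g}, {hi})", b))
        lines.append(_row("total", self.total))
        return "\n".join(lines)


def evaluate(
    records: list[PairRecord],
    n_boot: int = 1000,
    seed: int = 0,
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> EvaluationReport:
    """Compute the full evaluation report for a ligand-pair set."""
    mue, mse, rmse = metrics(records)
    slope, intercept, r = regression_stats(records)
    bins, total = binned_underestimation(records, edges=edges)
    return EvaluationReport(
        n_pairs=len(records),
        mue=mue, mse=mse, rmse=rmse,
        mue_sd=bootstrap_metric(records, "mue", n_boot=n_boot, seed=seed),
        mse_sd=bootstrap_metric(records, "mse", n_boot=n_boot, seed=seed),
        rmse_sd=bootstrap_metric(records, "rmse", n_boot=n_boot, seed=seed),
        pearson_r=r, slope=slope, intercept=intercept,
        bins=bins, total=total, bin_edges=tuple(edges), n_boot=n_boot,
    )
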