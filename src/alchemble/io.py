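"""Delimited-text readers/writers for the package's data formats.

All tables are UTF-8, comma-delimited, with ``#`` comment lines allowed.
Formats:

* dU/dlambda table — columns ``replica, window, lambda, step,
  dhdl_kcal_mol``; a JSON sidecar ``<path>.meta.json`` records the
  schedule, temperature, seed/spec info and the ground truth when known.
* u_kn table — a ``counts`` header row (per-state sample counts) followed
  by one row per state of reduced energies.
* ligand-pair CSV — ``pair_id, ddg_exp, ddg_exp_err, ddg_cal, ddg_cal_err,
  rep1..repN``.
* free-energy estimates — flat CSV ``pair_id, method, value, error,
  replica_sd, n_replicas`` and a JSON mirror.

JSON reports carry a ``schema_version`` field and are written with sorted
keys and no timestamps, so identical runs produce byte-identical files.
"""

from __future__ import annotations

import io as _io
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, SCHEMA_VERSION
from .estimators import FreeEnergyEstimate
from .synthdata import DhdlEnsemble, LambdaSchedule, PairRecord, ReducedPotentialSet

__all__ = [
    "write_dhdl_table",
    "read_dhdl_table",
    "write_u_kn",
    "read_u_kn",
    "write_pair_csv",
    "read_pair_csv",
    "write_estimates",
    "write_json_report",
]


class TableFormatError(ValueError):
    """A delimited-text table violates the expected format."""


def _read_table(path: Path, required: Sequence[str]) -> tuple[pd.DataFrame, list[int]]:
    """Read a comma table, skipping ``#`` comments; return (frame, line map).

    The line map gives the 1-based file line number of each data row, so
    malformed rows can be reported by their real position in the file.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    kept, linenos = [], []
    for no, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        kept.append(line)
        linenos.append(no)
    if not kept:
        raise TableFormatError(f"{path}: no data rows")
    frame = pd.read_csv(
        _io.StringIO("\n".join(kept)), skipinitialspace=True,
        float_precision="round_trip",
    )
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    return frame, linenos[1:]  # first kept line is the header


def _require_numeric(
    frame: pd.DataFrame, cols: Sequence[str], linenos: list[int], path: Path
) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna() | frame[col].isna()
        if bad.any():
            rows = [linenos[i] for i in np.flatnonzero(bad.to_numpy())[:5]]
            raise TableFormatError(
                f"{path}: non-numeric or missing values in column {col!r} "
                f"at line(s) {rows}"
            )
        frame[col] = coerced
    return frame


# ---------------------------------------------------------------------------
# dU/dlambda tables
# ---------------------------------------------------------------------------

def write_dhdl_table(ensemble: DhdlEnsemble, path: str | Path, meta: dict | None = None) -> None:
    """Write the ensemble as a long-format table plus a JSON sidecar."""
    path = Path(path)
    rows = []
    for (r, w), series in sorted(ensemble.series.items()):
        lam = ensemble.schedule.lambdas[w]
        for step, val in enumerate(series):
            rows.append((r, w, lam, step, val))
    frame = pd.DataFrame(
        rows, columns=["replica", "window", "lambda", "step", "dhdl_kcal_mol"]
    )
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# dU/dlambda time series, kcal/mol\n")
        # %.17g guarantees exact float round-trips
        frame.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "lambdas": list(ensemble.schedule.lambdas),
        "elec_off_end": ensemble.schedule.elec_off_end,
        "elec_on_start": ensemble.schedule.elec_on_start,
        "temperature": ensemble.temperature,
        "truth": ensemble.truth,
    }
    if meta:
        sidecar.update(meta)
    _sidecar_path(path).write_text(
        json.dumps(sidecar, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_dhdl_table(path: str | Path, temperature: float | None = None) -> DhdlEnsemble:
    """Read a dU/dlambda table back into a :class:`DhdlEnsemble`.

    The JSON sidecar, when present, supplies the schedule endpoints,
    temperature and truth; the lambda grid itself is cross-checked against
    the table.  Missing (replica, window) cells and inconsistent lambdas
    are reported explicitly.
    """
    path = Path(path)
    frame, linenos = _read_table(
        path, ["replica", "window", "lambda", "step", "dhdl_kcal_mol"]
    )
    frame = _require_numeric(
        frame, ["replica", "window", "lambda", "step", "dhdl_kcal_mol"], linenos, path
    )

    meta: dict = {}
    if _sidecar_path(path).exists():
        meta = json.loads(_sidecar_path(path).read_text(encoding="utf-8"))
    if temperature is None:
        temperature = float(meta.get("temperature", DEFAULT_TEMPERATURE))

    lam_by_window: dict[int, float] = {}
    for w, grp in frame.groupby("window"):
        lams = grp["lambda"].unique()
        if lams.size != 1:
            raise TableFormatError(
                f"{path}: window {int(w)} has inconsistent lambda values {sorted(lams)}"
            )
        lam_by_window[int(w)] = float(lams[0])
    windows = sorted(lam_by_window)
    if windows != list(range(len(windows))):
        raise TableFormatError(f"{path}: window indices {windows} are not 0..K-1")
    lambdas = [lam_by_window[w] for w in windows]
    if "lambdas" in meta and not np.allclose(meta["lambdas"], lambdas):
        raise TableFormatError(
            f"{path}: table lambdas disagree with sidecar schedule"
        )
    schedule = LambdaSchedule(
        lambdas=tuple(lambdas),
        elec_off_end=float(meta.get("elec_off_end", 0.55)),
        elec_on_start=float(meta.get("elec_on_start", 0.45)),
    )

    replicas = sorted(int(r) for r in frame["replica"].unique())
    series: dict[tuple[int, int], np.ndarray] = {}
    for r in replicas:
        for w in windows:
            grp = frame[(frame["replica"] == r) & (frame["window"] == w)]
            if grp.empty:
                raise TableFormatError(
                    f"{path}: missing series for replica {r}, window {w}"
                )
            series[(r, w)] = grp.sort_values("step")["dhdl_kcal_mol"].to_numpy()
    return DhdlEnsemble(
        schedule=schedule, series=series, temperature=temperature,
        truth=meta.get("truth"),
    )


# ---------------------------------------------------------------------------
# u_kn matrices
# ---------------------------------------------------------------------------

def write_u_kn(rp: ReducedPotentialSet, path: str | Path) -> None:
    """Write a reduced-potential matrix: counts header row, then K rows."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# reduced potential matrix u_kn (dimensionless)\n")
        fh.write(f"# temperature_K: {rp.temperature!r}\n")
        if rp.truth is not None:
            fh.write(f"# truth_kcal_mol: {rp.truth!r}\n")
        fh.write("counts," + ",".join(str(int(c)) for c in rp.counts) + "\n")
        for row in rp.u_kn:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_u_kn(path: str | Path) -> ReducedPotentialSet:
    """Read a reduced-potential matrix written by :func:`write_u_kn`."""
    path = Path(path)
    temperature = DEFAULT_TEMPERATURE
    truth = None
    counts = None
    rows = []
    for no, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.startswith("temperature_K:"):
                temperature = float(body.split(":", 1)[1])
            elif body.startswith("truth_kcal_mol:"):
                truth = float(body.split(":", 1)[1])
            continue
        fields = stripped.split(",")
        if counts is None:
            if fields[0] != "counts":
                raise TableFormatError(
                    f"{path}:{no}: expected the counts header row first"
                )
            counts = np.array([int(v) for v in fields[1:]])
            continue
        try:
            rows.append(np.array([float(v) for v in fields]))
        except ValueError as exc:
            raise TableFormatError(f"{path}:{no}: non-numeric entry ({exc})") from None
    if counts is None or not rows:
        raise TableFormatError(f"{path}: missing counts header or matrix rows")
    u_kn = np.vstack(rows)
    if u_kn.shape[0] != counts.size:
        raise TableFormatError(
            f"{path}: {u_kn.shape[0]} matrix rows for {counts.size} states"
        )
    return ReducedPotentialSet(
        u_kn=u_kn, counts=counts, temperature=temperature, truth=truth
    )


# ---------------------------------------------------------------------------
# ligand-pair tables
# ---------------------------------------------------------------------------

def write_pair_csv(records: Sequence[PairRecord], path: str | Path) -> None:
    """Write ligand pairs: pair_id, ddg_* columns, rep1..repN."""
    n_rep = max(
        (len(r.per_replica) for r in records if r.per_replica is not None), default=0
    )
    rows = []
    for rec in records:
        row = {
            "pair_id": rec.pair_id,
            "ddg_exp": rec.ddg_exp,
            "ddg_exp_err": rec.ddg_exp_err,
            "ddg_cal": rec.ddg_cal,
            "ddg_cal_err": rec.ddg_cal_err,
        }
        reps = rec.per_replica or ()
        for i in range(n_rep):
            row[f"rep{i + 1}"] = reps[i] if i < len(reps) else math.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(
        path, index=False, lineterminator="\n", float_format="%.17g"
    )


def read_pair_csv(path: str | Path) -> list[PairRecord]:
    """Read a ligand-pair CSV written by :func:`write_pair_csv`."""
    path = Path(path)
    frame, linenos = _read_table(
        path, ["pair_id", "ddg_exp", "ddg_exp_err", "ddg_cal", "ddg_cal_err"]
    )
    num_cols = ["ddg_exp", "ddg_exp_err", "ddg_cal", "ddg_cal_err"]
    frame = _require_numeric(frame, num_cols, linenos, path)
    rep_cols = sorted(
        (c for c in frame.columns if c.startswith("rep") and c[3:].isdigit()),
        key=lambda c: int(c[3:]),
    )
    records = []
    for _, row in frame.iterrows():
        reps = [row[c] for c in rep_cols if not pd.isna(row[c])]
        records.append(
            PairRecord(
                pair_id=str(row["pair_id"]),
                ddg_exp=float(row["ddg_exp"]),
                ddg_exp_err=float(row["ddg_exp_err"]),
                ddg_cal=float(row["ddg_cal"]),
                ddg_cal_err=float(row["ddg_cal_err"]),
                per_replica=tuple(float(v) for v in reps) if reps else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# estimates and reports
# ---------------------------------------------------------------------------

def write_estimates(
    estimates: dict[str, FreeEnergyEstimate], csv_path: str | Path, json_path: str | Path
) -> None:
    """Write labelled free-energy estimates as flat CSV + JSON mirror."""
    rows, payload = [], {}
    for label, est in estimates.items():
        n_rep = len(est.per_replica) if est.per_replica is not None else None
        rows.append(
            {
                "pair_id": label,
                "method": est.method,
                "value": est.value,
                "error": est.error,
                "replica_sd": est.replica_sd,
                "n_replicas": n_rep,
            }
        )
        payload[label] = {
            "method": est.method,
            "value": est.value,
            "error": est.error,
            "replica_sd": est.replica_sd,
            "per_replica": list(est.per_replica) if est.per_replica else None,
        }
    pd.DataFrame(rows).to_csv(csv_path, index=False, lineterminator="\n")
    write_json_report(payload, json_path)


def write_json_report(payload: dict, path: str | Path) -> None:
    """Deterministic JSON with a schema-version stamp."""
    doc = {"schema_version": SCHEMA_VERSION, **payload}
    Path(path).write_text(
        json.dumps(doc, sort_keys=True, indent=1, allow_nan=False) + "\n",
        encoding="utf-8",
    )
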