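"""Panel survival data containers and delimited-text I/O.

A *panel* is a p x q grid of survival strata: one stratum per
(location, time-period) cell, each holding right-censored survival
records ``(time, event, covariates)``. Cells may be empty. Within a
cell, rows are kept sorted ascending by observed time with events
preceding censored records at tied times, so risk sets are suffixes
of the sorted arrays.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "StratumData",
    "PanelData",
    "read_panel_csv",
    "read_distance_matrix",
    "validate_distance_matrix",
    "write_estimates",
    "panel_to_dataframe",
]

DEFAULT_SCHEMA = {"location": "location", "period": "period", "time": "time", "event": "event"}


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class ValidationError(ValueError):
    """Input values violate the survival-data contract."""


def _canonical_order(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Sort ascending by time; events before censorings at ties; stable otherwise."""
    return np.lexsort((np.arange(times.size), -events, times))


@dataclass
class StratumData:
    """Survival records for one (location, period) cell.

    Attributes
    ----------
    times : (n,) float array of positive observed times (months), sorted ascending.
    events : (n,) int array of event indicators in {0, 1}.
    covariates : (n, m) float matrix.
    """

    times: np.ndarray
    events: np.ndarray
    covariates: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.events = np.asarray(self.events, dtype=int).ravel()
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.size == 0:
            self.covariates = self.covariates.reshape(0, self.covariates.shape[-1] if self.covariates.ndim > 1 else 0)
        n = self.times.size
        if self.events.size != n or self.covariates.shape[0] != n:
            raise ValidationError(
                f"inconsistent stratum sizes: times {n}, events {self.events.size}, "
                f"covariates {self.covariates.shape[0]}"
            )
        if n:
            if not np.all(np.isfinite(self.times)) or np.any(self.times <= 0):
                raise ValidationError("observed times must be finite and > 0")
            if not np.isin(self.events, (0, 1)).all():
                raise ValidationError("event indicators must be 0 or 1")
            if not np.all(np.isfinite(self.covariates)):
                raise ValidationError("covariate entries must be finite")
            order = _canonical_order(self.times, self.events)
            self.times = self.times[order]
            self.events = self.events[order]
            self.covariates = self.covariates[order]

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def m(self) -> int:
        return self.covariates.shape[1]

    def subset(self, mask: np.ndarray) -> "StratumData":
        return StratumData(self.times[mask], self.events[mask], self.covariates[mask])


def _empty_stratum(m: int) -> StratumData:
    return StratumData(np.empty(0), np.empty(0, dtype=int), np.empty((0, m)))


@dataclass
class PanelData:
    """A p x q grid of survival strata plus labelling metadata.

    ``strata[i][j]`` is the stratum for location ``location_ids[i]`` in
    period ``period_ids[j]``; ``period_ids`` is strictly ordered and
    temporal adjacency means consecutive positions in that list.
    """

    strata: list  # p x q nested list of StratumData
    location_ids: list
    period_ids: list
    covariate_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        p, q = len(self.location_ids), len(self.period_ids)
        if len(self.strata) != p or any(len(row) != q for row in self.strata):
            raise ValidationError("strata grid shape does not match id lists")
        if p < 1 or q < 1 or (p < 2 and q < 2):
            raise ValidationError("need p >= 2 or q >= 2 (at least one smoothing dimension)")
        if list(self.period_ids) != sorted(self.period_ids):
            raise ValidationError("period_ids must be strictly ordered")
        if len(set(self.period_ids)) != q or len(set(self.location_ids)) != p:
            raise ValidationError("duplicate location or period ids")
        ms = {s.m for row in self.strata for s in row}
        if len(ms) > 1:
            raise ValidationError(f"strata disagree on covariate count: {sorted(ms)}")
        if not self.covariate_names:
            self.covariate_names = [f"x{k}" for k in range(self.m)]
        if len(self.covariate_names) != self.m:
            raise ValidationError("covariate_names length does not match covariate count")

    @property
    def p(self) -> int:
        return len(self.location_ids)

    @property
    def q(self) -> int:
        return len(self.period_ids)

    @property
    def m(self) -> int:
        return self.strata[0][0].m

    @property
    def n_total(self) -> int:
        return sum(s.n for row in self.strata for s in row)

    def cell(self, i: int, j: int) -> StratumData:
        return self.strata[i][j]

    def cells(self):
        """Yield ``(i, j, stratum)`` in lexicographic order."""
        for i in range(self.p):
            for j in range(self.q):
                yield i, j, self.strata[i][j]


def read_panel_csv(path, schema: dict | None = None) -> PanelData:
    """Read a long-format panel CSV (one row per subject) into a :class:`PanelData`.

    ``schema`` maps the roles ``location, period, time, event`` to column
    names (defaults: those same names); every remaining column is treated
    as a numeric covariate unless ``schema["covariates"]`` lists them
    explicitly. Rows are grouped into (location, period) cells and sorted
    canonically; (location, period) pairs absent from the file become
    empty cells.
    """
    sch = dict(DEFAULT_SCHEMA)
    sch.update(schema or {})
    df = pd.read_csv(path)
    for role in ("location", "period", "time", "event"):
        if sch[role] not in df.columns:
            raise SchemaError(f"missing required column {sch[role]!r} (role: {role})")
    reserved = {sch[r] for r in ("location", "period", "time", "event")}
    cov_cols = sch.get("covariates") or [c for c in df.columns if c not in reserved]
    missing = [c for c in cov_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing covariate columns {missing}")

    for c in [sch["time"], sch["event"], *cov_cols]:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"non-numeric value in column {c!r} at data row {row}")
        if df[c].isna().any():
            row = int(np.flatnonzero(df[c].isna().to_numpy())[0])
            raise ValidationError(f"missing value in column {c!r} at data row {row}")

    events = df[sch["event"]].to_numpy()
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("event column contains values outside {0, 1}")
    times = df[sch["time"]].to_numpy(dtype=float)
    if np.any(times <= 0) or not np.all(np.isfinite(times)):
        raise ValidationError("time column contains nonpositive or non-finite values")

    location_ids = sorted(df[sch["location"]].unique().tolist())
    period_ids = sorted(df[sch["period"]].unique().tolist())
    m = len(cov_cols)
    X = df[cov_cols].to_numpy(dtype=float)
    loc_codes = df[sch["location"]].map({v: k for k, v in enumerate(location_ids)}).to_numpy()
    per_codes = df[sch["period"]].map({v: k for k, v in enumerate(period_ids)}).to_numpy()

    strata = []
    for i in range(len(location_ids)):
        row = []
        for j in range(len(period_ids)):
            mask = (loc_codes == i) & (per_codes == j)
            if mask.any():
                row.append(StratumData(times[mask], events[mask], X[mask]))
            else:
                row.append(_empty_stratum(m))
        strata.append(row)
    return PanelData(strata, location_ids, period_ids, list(cov_cols))


def panel_to_dataframe(panel: PanelData) -> pd.DataFrame:
    """Flatten a panel back to long format (inverse of :func:`read_panel_csv`)."""
    rows = []
    for i, j, s in panel.cells():
        for k in range(s.n):
            rows.append(
                (panel.location_ids[i], panel.period_ids[j], s.times[k], s.events[k], *s.covariates[k])
            )
    cols = ["location", "period", "time", "event", *panel.covariate_names]
    return pd.DataFrame(rows, columns=cols)


def validate_distance_matrix(d: np.ndarray) -> np.ndarray:
    """Validate a p x p inter-location distance matrix and return it as float."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError(f"distance matrix must be square, got shape {d.shape}")
    if not np.all(np.isfinite(d)):
        raise ValidationError("distance matrix contains non-finite entries")
    if np.abs(d - d.T).max(initial=0.0) > 1e-9:
        raise ValidationError("distance matrix is asymmetric beyond tolerance 1e-9")
    if np.abs(np.diag(d)).max(initial=0.0) > 0:
        raise ValidationError("distance matrix diagonal must be zero")
    off = d[~np.eye(d.shape[0], dtype=bool)]
    if off.size and off.min() <= 0:
        raise ValidationError("off-diagonal distances must be strictly positive (1/d weights)")
    return d


def read_distance_matrix(path, location_ids: list | None = None) -> np.ndarray:
    """Read a square distance CSV (header row + index column of location ids).

    If ``location_ids`` is given, rows/columns are reordered to that order;
    a label mismatch raises listing the offending ids.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError("distance matrix has duplicate row or column labels")
    if sorted(df.index) != sorted(df.columns):
        raise ValidationError("distance matrix row and column labels disagree")
    if location_ids is not None:
        want = [str(v) for v in location_ids]
        extra = sorted(set(df.index) - set(want))
        missing = sorted(set(want) - set(df.index))
        if extra or missing:
            raise ValidationError(
                f"distance matrix labels mismatch: missing {missing}, unexpected {extra}"
            )
        df = df.loc[want, want]
    return validate_distance_matrix(df.to_numpy())


def write_estimates(
    beta: np.ndarray,
    path,
    panel: PanelData | None = None,
    se: np.ndarray | None = None,
    ci_low: np.ndarray | None = None,
    ci_high: np.ndarray | None = None,
    flags: np.ndarray | None = None,
) -> None:
    """Write a (p, q, m) coefficient grid as long-format CSV.

    One row per (location, period, covariate), columns
    ``location, period, covariate, estimate, se, ci_low, ci_high`` (the last
    three empty when unavailable). Values are written to 12 significant
    digits so a write/read round trip is lossless at that precision.
    Non-finite estimates are rejected before any output is produced,
    except in cells marked by ``flags`` (degenerate / empty cells), whose
    rows carry ``flag=1``.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 3:
        raise ValidationError(f"expected a (p, q, m) grid, got shape {beta.shape}")
    p, q, m = beta.shape
    if flags is None:
        flags = np.zeros((p, q), dtype=bool)
    flags = np.asarray(flags, dtype=bool)
    bad = ~np.isfinite(beta) & ~flags[:, :, None]
    if bad.any():
        raise ValidationError("non-finite estimate in an unflagged cell; refusing to write")

    loc_ids = panel.location_ids if panel is not None else list(range(p))
    per_ids = panel.period_ids if panel is not None else list(range(q))
    cov = panel.covariate_names if panel is not None else [f"x{k}" for k in range(m)]

    def col(a, i, j, k):
        if a is None:
            return ""
        v = np.asarray(a, dtype=float)[i, j, k]
        return f"{v:.12g}" if np.isfinite(v) else ""

    lines = ["location,period,covariate,estimate,se,ci_low,ci_high,flag"]
    for i in range(p):
        for j in range(q):
            for k in range(m):
                est = beta[i, j, k]
                lines.append(
                    f"{loc_ids[i]},{per_ids[j]},{cov[k]},"
                    f"{f'{est:.12g}' if np.isfinite(est) else ''},"
                    f"{col(se, i, j, k)},{col(ci_low, i, j, k)},{col(ci_high, i, j, k)},"
                    f"{int(flags[i, j])}"
                )
    # write atomically: no partial file on failure
    text = "\n".join(lines) + "\n"
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_estimates(path) -> pd.DataFrame:
    """Read an estimates CSV written by :func:`write_estimates`."""
    return pd.read_csv(path)
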