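"""Single-cell response tables: I/O, log transform, selection, Gaussian fits.

The universal input is a table with one row per cell: genotype label
(e.g. WT / KO), stimulus dose (TNF, ng/mL), measurement time (minutes) and a
positive fluorescence response (nuclear NF-kB, arbitrary units).  Long layout
stores one (cell, time) measurement per row; wide layout pairs several time
points per cell (one column per time), which is required for joint
multi-time-point analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCovarianceError,
    EmptySelectionError,
    InsufficientDataError,
    PairingError,
    ResponseDomainError,
    SchemaError,
    TableParseError,
)
from .models import GaussianCondition

logger = logging.getLogger(__name__)

#: file column -> canonical column
DEFAULT_SCHEMA: dict[str, str] = {
    "cell_id": "cell_id",
    "cell_type": "cell_type",
    "tnf_ng_ml": "dose",
    "time_min": "time",
    "nfkb_au": "response",
}

_RESPONSE_PREFIX = "nfkb_au_"
_DOSE_RTOL = 1e-9


@dataclass(frozen=True)
class ConditionKey:
    """Identifies one hypothesis condition: genotype, dose, time points."""

    cell_type: str
    dose: float
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        if len(times) < 1:
            raise ValueError("at least one time point required")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "dose", float(self.dose))


@dataclass(frozen=True)
class ResponseTable:
    """A validated per-cell response table.

    ``data`` uses canonical column names: cell_id, cell_type, dose, and either
    (time, response) in long layout or response_<time> columns in wide layout.
    """

    data: pd.DataFrame
    layout: str = "long"
    log_scale: bool = False
    times: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.layout not in ("long", "wide"):
            raise ValueError(f"layout must be 'long' or 'wide', got {self.layout!r}")
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))

    def __len__(self) -> int:
        return len(self.data)

    def response_columns(self) -> list[str]:
        if self.layout == "long":
            return ["response"]
        return [_canonical_wide_col(t) for t in self.times]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResponseTable):
            return NotImplemented
        return (
            self.layout == other.layout
            and self.log_scale == other.log_scale
            and self.times == other.times
            and self.data.reset_index(drop=True).equals(
                other.data.reset_index(drop=True)
            )
        )


def _wide_col(time: float) -> str:
    return f"{_RESPONSE_PREFIX}{time:g}"


def _canonical_wide_col(time: float) -> str:
    return f"response_{time:g}"


def read_response_table(
    path,
    schema: Mapping[str, str] | None = None,
    strict: bool = False,
) -> ResponseTable:
    """Read a CSV of single-cell responses.

    Wide layout is detected from ``nfkb_au_<time>`` response columns (the
    stem is the mapped response column name).  With ``strict=True``, rows with
    missing, non-finite or negative responses raise :class:`TableParseError`
    naming the offending data rows; otherwise they are kept and reported via
    a warning log.
    """
    schema = dict(schema or DEFAULT_SCHEMA)
    try:
        raw = pd.read_csv(path, float_precision="round_trip")
    except ValueError as exc:
        raise TableParseError(f"could not parse {path}: {exc}") from exc

    inverse = {}
    for file_col, canon in schema.items():
        if canon not in DEFAULT_SCHEMA.values():
            raise SchemaError(f"unknown canonical column {canon!r}")
        inverse[canon] = file_col

    resp_stem = inverse.get("response", "nfkb_au")
    wide_cols = {
        c: float(m.group(1))
        for c in raw.columns
        if (m := re.fullmatch(re.escape(resp_stem) + r"_([0-9.]+)", c))
    }
    layout = "wide" if wide_cols else "long"

    required = ["cell_id", "cell_type", "dose"]
    required += ["time", "response"] if layout == "long" else []
    missing = [
        inverse.get(c, c) for c in required if inverse.get(c, c) not in raw.columns
    ]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")

    rename = {inverse.get(c, c): c for c in ("cell_id", "cell_type", "dose", "time", "response")}
    df = raw.rename(columns=rename)

    if layout == "wide":
        times = tuple(sorted(wide_cols.values()))
        col_map = {c: _canonical_wide_col(t) for c, t in wide_cols.items()}
        df = df.rename(columns=col_map)
        resp_cols = [_canonical_wide_col(t) for t in times]
        keep = ["cell_id", "cell_type", "dose"] + resp_cols
    else:
        times = ()
        resp_cols = ["response"]
        keep = ["cell_id", "cell_type", "dose", "time", "response"]
    extra = [c for c in df.columns if c not in keep]
    df = df[keep + extra]

    bad_rows = []
    for col in resp_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            bad_rows.extend((df.index[bad] + 2).tolist())  # +2: header + 1-basing
        df[col] = vals
    if bad_rows:
        msg = (
            f"{len(set(bad_rows))} malformed response value(s) in {path} "
            f"at file line(s) {sorted(set(bad_rows))[:20]}"
        )
        if strict:
            raise TableParseError(msg)
        logger.warning(msg)

    df["dose"] = pd.to_numeric(df["dose"], errors="raise").astype(float)
    for col in resp_cols:
        df[col] = df[col].astype(float)
    if layout == "long":
        df["time"] = pd.to_numeric(df["time"], errors="raise").astype(float)

    # canonical wide columns stored as response_<t>; times recorded on the table
    return ResponseTable(data=df, layout=layout, log_scale=False, times=times)


def write_response_table(table: ResponseTable, path) -> None:
    """Write the table as CSV with the default column names, full precision."""
    df = table.data.copy()
    if table.layout == "wide":
        df = df.rename(
            columns={_canonical_wide_col(t): _wide_col(t) for t in table.times}
        )
    else:
        df = df.rename(columns={"time": "time_min", "response": "nfkb_au"})
    df = df.rename(columns={"dose": "tnf_ng_ml"})
    df.to_csv(path, index=False, float_format="%.17g")


def log_transform(table: ResponseTable, policy: str = "drop") -> ResponseTable:
    """Replace every response by its natural logarithm.

    Nonpositive responses (possible with immunocytochemistry backgrounds) are
    handled per ``policy``: ``"drop"`` removes those cells and logs the count;
    ``"error"`` raises :class:`ResponseDomainError` listing the cell ids.
    """
    if table.log_scale:
        raise ValueError("table is already log-scale")
    if policy not in ("drop", "error"):
        raise ValueError(f"policy must be 'drop' or 'error', got {policy!r}")
    df = table.data.copy()
    resp_cols = (
        ["response"]
        if table.layout == "long"
        else [_canonical_wide_col(t) for t in table.times]
    )
    nonpos = np.zeros(len(df), dtype=bool)
    for col in resp_cols:
        nonpos |= ~(df[col].to_numpy() > 0)
    if nonpos.any():
        ids = df.loc[nonpos, "cell_id"].tolist()
        if policy == "error":
            raise ResponseDomainError(
                f"{len(ids)} nonpositive response(s); cell_ids {ids[:20]}"
            )
        logger.warning("dropping %d cell(s) with nonpositive responses", len(ids))
        df = df.loc[~nonpos].reset_index(drop=True)
    for col in resp_cols:
        df[col] = np.log(df[col].to_numpy(dtype=float))
    return replace(table, data=df, log_scale=True)


def _dose_match(doses: np.ndarray, dose: float) -> np.ndarray:
    return np.isclose(doses, dose, rtol=_DOSE_RTOL, atol=0.0)


def select_condition(table: ResponseTable, key: ConditionKey) -> np.ndarray:
    """Observation matrix (cells x time points) for one condition.

    The table must be log-scale.  Multi-time-point selection (N > 1) requires
    wide layout, i.e. per-cell paired measurements.
    """
    if not table.log_scale:
        raise ValueError("select_condition requires a log-scale table")
    df = table.data
    mask = (df["cell_type"] == key.cell_type) & _dose_match(
        df["dose"].to_numpy(dtype=float), key.dose
    )
    if table.layout == "long":
        if len(key.times) > 1:
            raise PairingError(
                "joint multi-time selection needs wide-layout (paired) data"
            )
        t = key.times[0]
        mask &= np.isclose(df["time"].to_numpy(dtype=float), t, rtol=_DOSE_RTOL)
        sub = df.loc[mask]
        if sub.empty:
            raise EmptySelectionError(f"no cells match {key}")
        return sub["response"].to_numpy(dtype=float)[:, None]
    missing = [t for t in key.times if t not in table.times]
    if missing:
        raise EmptySelectionError(f"time point(s) {missing} absent from wide table")
    sub = df.loc[mask]
    if sub.empty:
        raise EmptySelectionError(f"no cells match {key}")
    cols = [_canonical_wide_col(t) for t in key.times]
    return sub[cols].to_numpy(dtype=float)


def fit_gaussian(
    observations: np.ndarray,
    condition_cap: float = 1e10,
) -> GaussianCondition:
    """Fit a Gaussian by sample mean and unbiased (n-1) sample covariance.

    Raises :class:`InsufficientDataError` when n <= N (an invertible unbiased
    sample covariance needs at least N+1 rows) and
    :class:`DegenerateCovarianceError` when the sample covariance is singular
    or its condition number exceeds ``condition_cap``.
    """
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    if obs.ndim != 2:
        raise ValueError("observations must be a 2-D matrix (cells x times)")
    n, dim = obs.shape
    if not np.all(np.isfinite(obs)):
        raise ValueError("observations contain non-finite values")
    if n <= dim:
        raise InsufficientDataError(
            f"need at least N+1 = {dim + 1} observations, got {n}"
        )
    mean = obs.mean(axis=0)
    cov = np.cov(obs, rowvar=False, ddof=1).reshape(dim, dim)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 0 or eigvals.max() / eigvals.min() > condition_cap:
        raise DegenerateCovarianceError(
            f"sample covariance is singular or ill-conditioned "
            f"(eigenvalues {eigvals.tolist()})"
        )
    return GaussianCondition(mean=mean, cov=cov, n=n, estimator="unbiased")


def fit_gaussian_independent(
    table: ResponseTable, key: ConditionKey
) -> GaussianCondition:
    """Joint Gaussian assembled from per-time long-layout selections under an
    explicit independence assumption (diagonal covariance).

    Opt-in alternative when no per-cell pairing across time points exists.
    """
    means, variances, ns = [], [], []
    for t in key.times:
        obs = select_condition(
            table, ConditionKey(cell_type=key.cell_type, dose=key.dose, times=(t,))
        )
        fit = fit_gaussian(obs)
        means.append(fit.mean[0])
        variances.append(fit.cov[0, 0])
        ns.append(fit.n)
    return GaussianCondition(
        mean=np.array(means),
        cov=np.diag(variances),
        n=min(ns),
        estimator="unbiased-independent",
    )


def dynamic_range_summary(table: ResponseTable) -> pd.DataFrame:
    """Mean and SD of ln-responses per (cell_type, dose, time).

    Mirrors the dose-response "dynamic range" view: log-means rising with
    dose, log-SDs roughly flat.  Rows agree with :func:`fit_gaussian` on the
    matching selections.
    """
    if not table.log_scale:
        raise ValueError("dynamic_range_summary requires a log-scale table")
    df = table.data
    rows = []
    if table.layout == "long":
        grouped = df.groupby(["cell_type", "dose", "time"], sort=True)
        for (ct, dose, t), sub in grouped:
            vals = sub["response"].to_numpy(dtype=float)
            rows.append(_summary_row(ct, dose, t, vals))
    else:
        for (ct, dose), sub in df.groupby(["cell_type", "dose"], sort=True):
            for t in table.times:
                vals = sub[_canonical_wide_col(t)].to_numpy(dtype=float)
                rows.append(_summary_row(ct, dose, t, vals))
    return pd.DataFrame(
        rows, columns=["cell_type", "dose", "time", "n", "mean", "sd"]
    )


def _summary_row(cell_type, dose, time, vals) -> dict:
    return {
        "cell_type": cell_type,
        "dose": float(dose),
        "time": float(time),
        "n": int(len(vals)),
        "mean": float(vals.mean()) if len(vals) else np.nan,
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
    }
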