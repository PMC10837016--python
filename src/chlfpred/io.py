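"""Reading, normalizing and quality-filtering fluorescence measurement tables.

Two instrument dialects are mapped onto one canonical record layout: a
hand-held leaf-level meter ("multispeq") and an automated canopy scanner
("lift", which additionally reports a signal-to-noise ratio and red-edge
reflectance bands).  The canonical dialect is the package's own CSV layout;
`write_chlf_table` and `read_chlf_table` round-trip it exactly.

The quality-filter cascade applies, in order: a low-light threshold on PPFR,
an SNR floor for scanner records, a per-trial 2.5 x interquartile-range
outlier rule on each listed variable, and finally removal of lines left with
fewer than 30 measurements.  Every removal is attributed to exactly one rule
and accounted for in a `FilterReport`, whose counts always sum back to the
input size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ChlfFormatError",
    "ChlfFilterError",
    "FilterRules",
    "FilterReport",
    "CANONICAL_COLUMNS",
    "DIALECTS",
    "read_chlf_table",
    "write_chlf_table",
    "read_ppfr_log",
    "associate_ppfr",
    "filter_records",
]


class ChlfFormatError(ValueError):
    """Raised for unreadable or malformed measurement tables."""


class ChlfFilterError(ValueError):
    """Raised when filtering cannot proceed (empty input or empty output)."""


CANONICAL_COLUMNS = [
    "trial", "line", "plot", "device", "timestamp",
    "ppfr", "temperature", "fqfm", "snr", "chlorophyll",
    "r531", "r570", "r680", "r710", "r754", "r800",
    "mtci", "pri", "ndvi", "reflectance",
]

_NUMERIC = [
    "ppfr", "temperature", "fqfm", "snr", "chlorophyll",
    "r531", "r570", "r680", "r710", "r754", "r800",
    "mtci", "pri", "ndvi", "reflectance",
]

# canonical field -> source column per dialect
DIALECTS = {
    "canonical": {
        "map": {c: c for c in CANONICAL_COLUMNS},
        "required": ["trial", "line", "timestamp", "fqfm"],
    },
    "multispeq": {
        "map": {
            "trial": "Trial",
            "line": "Line",
            "plot": "Plot",
            "device": "Device ID",
            "timestamp": "time",
            "ppfr": "Light Intensity (PAR)",
            "temperature": "Ambient Temperature",
            "fqfm": "Phi2",
            "chlorophyll": "Relative Chlorophyll",
        },
        "required": ["trial", "line", "timestamp", "fqfm"],
    },
    "lift": {
        "map": {
            "trial": "Trial",
            "line": "Line",
            "plot": "Pot",
            "timestamp": "Timestamp",
            "ppfr": "PAR",
            "temperature": "Temp",
            "fqfm": "FqFm",
            "snr": "SNR",
            "r680": "R680",
            "r710": "R710",
            "r754": "R754",
        },
        "required": ["trial", "line", "timestamp", "fqfm", "snr"],
    },
}


def read_chlf_table(
    path,
    dialect: str = "canonical",
    column_map: Optional[dict] = None,
    trial: Optional[str] = None,
) -> pd.DataFrame:
    """Read one measurement table into the canonical record layout.

    ``column_map`` overrides/extends the dialect's canonical-field -> source
    column mapping, which is how project-specific export headers are
    accommodated.  ``trial`` supplies a trial label when the file has no
    trial column.  Malformed numeric cells are rejected with row-addressed
    messages rather than silently dropped.
    """
    if dialect not in DIALECTS:
        raise ChlfFormatError(f"unknown dialect '{dialect}'; expected one of {sorted(DIALECTS)}")
    spec = DIALECTS[dialect]
    mapping = dict(spec["map"])
    if column_map:
        mapping.update(column_map)
    try:
        raw = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ChlfFormatError(f"{path}: empty file") from exc
    if len(raw) == 0:
        raise ChlfFormatError(f"{path}: no measurement rows")

    out = pd.DataFrame(index=raw.index)
    for canon in CANONICAL_COLUMNS:
        src = mapping.get(canon)
        if src is not None and src in raw.columns:
            out[canon] = raw[src]
    if trial is not None:
        out["trial"] = trial
    for canon in spec["required"]:
        if canon not in out.columns:
            src = mapping.get(canon, canon)
            raise ChlfFormatError(
                f"{path}: missing mandatory column '{src}' (canonical field '{canon}')"
            )

    for col in _NUMERIC:
        if col in out.columns:
            coerced = pd.to_numeric(out[col], errors="coerce")
            bad = out[col].notna() & coerced.isna()
            if bad.any():
                rows = list(out.index[bad][:5])
                raise ChlfFormatError(
                    f"{path}: malformed numeric value(s) in column '{col}' at rows {rows}"
                )
            out[col] = coerced
    ts = pd.to_datetime(out["timestamp"], errors="coerce", format="mixed")
    bad = out["timestamp"].notna() & ts.isna()
    if bad.any():
        rows = list(out.index[bad][:5])
        raise ChlfFormatError(f"{path}: unparseable timestamp(s) at rows {rows}")
    out["timestamp"] = ts

    fq = out["fqfm"]
    bad = fq.notna() & ((fq < 0) | (fq > 1))
    if bad.any():
        rows = list(out.index[bad][:5])
        raise ChlfFormatError(f"{path}: Fq'/Fm' outside [0, 1] at rows {rows}")
    if "ppfr" in out.columns:
        neg = out["ppfr"].notna() & (out["ppfr"] < 0)
        if neg.any():
            rows = list(out.index[neg][:5])
            raise ChlfFormatError(f"{path}: negative PPFR at rows {rows}")
    for col in ("trial", "line"):
        if (out[col].isna() | (out[col].astype(str).str.len() == 0)).any():
            raise ChlfFormatError(f"{path}: empty values in mandatory column '{col}'")
        out[col] = out[col].astype(str)
    return out.reset_index(drop=True)


def write_chlf_table(records: pd.DataFrame, path) -> None:
    """Write records in the canonical CSV dialect (ISO timestamps, full precision)."""
    cols = [c for c in CANONICAL_COLUMNS if c in records.columns]
    out = records[cols].copy()
    if "timestamp" in out.columns:
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    # shortest digit string that round-trips the float exactly
    out.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_ppfr_log(path) -> pd.DataFrame:
    """Read a two-column (timestamp, ppfr) light log."""
    log = pd.read_csv(path, float_precision="round_trip")
    if log.shape[1] < 2:
        raise ChlfFormatError(f"{path}: PPFR log needs (timestamp, value) columns")
    log = log.iloc[:, :2].set_axis(["timestamp", "ppfr"], axis=1)
    log["timestamp"] = pd.to_datetime(log["timestamp"])
    log["ppfr"] = pd.to_numeric(log["ppfr"])
    return log


def associate_ppfr(records: pd.DataFrame, ppfr_log: pd.DataFrame) -> pd.DataFrame:
    """Replace each record's PPFR with the log value recorded in the same minute.

    Timestamps are truncated (not rounded) to the minute on both sides.  When
    several log rows share a minute their mean is used, which makes the
    assignment independent of the log's row order.  Records without a
    matching minute are flagged (``ppfr_matched`` False) and their PPFR left
    unset rather than failing.
    """
    out = records.copy()
    log = ppfr_log.copy()
    log["minute"] = pd.to_datetime(log["timestamp"]).dt.floor("min")
    lookup = log.groupby("minute")["ppfr"].mean()
    minutes = pd.to_datetime(out["timestamp"]).dt.floor("min")
    matched = minutes.map(lookup)
    out["ppfr"] = matched
    out["ppfr_matched"] = matched.notna()
    return out


@dataclass
class FilterRules:
    """Parameters of the quality cascade; thresholds mirror the screening design."""

    min_ppfr: float = 100.0
    min_snr: float = 30.0
    iqr_factor: float = 2.5
    min_obs_per_line: int = 30
    iqr_variables: tuple = ("fqfm", "ppfr", "temperature", "mtci", "pri", "ndvi", "chlorophyll")


@dataclass
class FilterReport:
    """Auditable account of every record removed by the cascade."""

    n_input: int
    removed_low_light: int
    removed_snr: int
    removed_iqr_outlier: int
    removed_sparse_lines: int
    n_retained: int
    removed_cooks: int = 0
    params: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)  # {(trial, var): (lo, hi)}

    def validate(self) -> None:
        removed = (
            self.removed_low_light
            + self.removed_snr
            + self.removed_iqr_outlier
            + self.removed_sparse_lines
            + self.removed_cooks
        )
        counts = [self.n_input, self.n_retained, self.removed_low_light, self.removed_snr,
                  self.removed_iqr_outlier, self.removed_sparse_lines, self.removed_cooks]
        if any(c < 0 for c in counts):
            raise ChlfFilterError("negative count in filter report")
        if self.n_input != self.n_retained + removed:
            raise ChlfFilterError("filter report counts do not sum to the input size")

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["thresholds"] = {
            f"{t}|{v}": list(bounds) for (t, v), bounds in self.thresholds.items()
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "FilterReport":
        payload = json.loads(text)
        thresholds = {
            tuple(k.split("|", 1)): tuple(v) for k, v in payload.pop("thresholds", {}).items()
        }
        return cls(thresholds=thresholds, **payload)


def _iqr_bounds(values: np.ndarray, factor: float):
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    if iqr <= 0:
        return None  # degenerate spread: the rule cannot separate outliers
    return med - factor * iqr, med + factor * iqr


def filter_records(
    records: pd.DataFrame,
    rules: Optional[FilterRules] = None,
    thresholds: Optional[dict] = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the quality cascade and account for every removal.

    Rules run in a fixed order -- cheap range rules first, the
    distribution-based interquartile rule next, the sparse-line rule last
    because the earlier rules change per-line counts.  Each removed record is
    attributed to the first rule that rejects it.

    * Low light: PPFR below ``min_ppfr`` (the boundary value is kept) or
      missing after log association.
    * SNR: records that carry an SNR below ``min_snr`` (scanner streams).
    * IQR: per trial and per listed variable, values farther from the median
      than ``iqr_factor`` times the interquartile range; a degenerate
      (zero) IQR retains all records for that variable.  Passing
      ``thresholds`` from a previous report reuses the stored cut-offs
      instead of recomputing them, which makes the cascade idempotent.
    * Sparse lines: lines left with fewer than ``min_obs_per_line`` records.

    Returns the retained records in their original order plus the report.
    """
    rules = rules or FilterRules()
    if len(records) == 0:
        raise ChlfFilterError("no records to filter")
    n_input = len(records)
    df = records

    ppfr = df["ppfr"] if "ppfr" in df.columns else pd.Series(np.nan, index=df.index)
    low = ppfr.isna() | (ppfr < rules.min_ppfr)
    n_low = int(low.sum())
    df = df.loc[~low]

    if "snr" in df.columns:
        snr_bad = df["snr"].notna() & (df["snr"] < rules.min_snr)
    else:
        snr_bad = pd.Series(False, index=df.index)
    n_snr = int(snr_bad.sum())
    df = df.loc[~snr_bad]

    used_thresholds: dict = {}
    out_mask = pd.Series(False, index=df.index)
    for trial, sub in df.groupby("trial", sort=False):
        for var in rules.iqr_variables:
            if var not in sub.columns:
                continue
            vals = sub[var].dropna()
            if len(vals) == 0:
                continue
            if thresholds is not None:
                bounds = thresholds.get((str(trial), var))
            else:
                bounds = _iqr_bounds(vals.to_numpy(float), rules.iqr_factor)
            if bounds is None:
                continue
            lo_b, hi_b = bounds
            used_thresholds[(str(trial), var)] = (float(lo_b), float(hi_b))
            bad = sub[var].notna() & ((sub[var] < lo_b) | (sub[var] > hi_b))
            out_mask.loc[bad.index[bad]] = True
    n_iqr = int(out_mask.sum())
    df = df.loc[~out_mask]

    if len(df):
        counts = df.groupby("line")["fqfm"].size()
        sparse_lines = counts.index[counts < rules.min_obs_per_line]
        sparse = df["line"].isin(sparse_lines)
    else:
        sparse = pd.Series(False, index=df.index, dtype=bool)
    n_sparse = int(sparse.sum())
    df = df.loc[~sparse]

    if len(df) == 0:
        raise ChlfFilterError("empty after filtering: every record was removed")

    report = FilterReport(
        n_input=n_input,
        removed_low_light=n_low,
        removed_snr=n_snr,
        removed_iqr_outlier=n_iqr,
        removed_sparse_lines=n_sparse,
        n_retained=len(df),
        params={
            "min_ppfr": rules.min_ppfr,
            "min_snr": rules.min_snr,
            "iqr_factor": rules.iqr_factor,
            "min_obs_per_line": rules.min_obs_per_line,
            "iqr_variables": list(rules.iqr_variables),
            "reused_thresholds": thresholds is not None,
        },
        thresholds=used_thresholds,
    )
    report.validate()
    return df, report
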