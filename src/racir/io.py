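"""Reading instrument logs, writing results, and batch processing.

Two on-disk dialects are read: plain CSV with a single header row (the
canonical format this package also writes) and the tab-delimited instrument
log dialect with two header rows (a group row over a variable row, as
portable IRGA systems produce). Column labels are mapped to canonical names
through a :class:`ColumnMap`; common instrument labels (``CO2_r``,
``Tleaf``, ``Qin``, ...) are recognised out of the box.

Batch processing runs the full correction-and-fit pipeline over many files,
isolating failures per entry and writing a one-row-per-input summary; every
discarded record class (down-ramp, lag, outlier, domain trim, Ci window) is
counted in that summary. The batch configuration is a YAML document with a
``schema_version`` key.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .curve import Curve, CurveRole, RampDirection, RAW_FIELDS, DERIVED_FIELDS
from .errors import CurveError, EmptyCurveError, RacirError
from .filtering import FilterSettings

logger = logging.getLogger(__name__)

#: Instrument column labels recognised without a user-supplied map.
DEFAULT_ALIASES: Dict[str, Tuple[str, ...]] = {
    "elapsed_s": ("elapsed_s", "elapsed", "TIME", "time"),
    "co2_ref": ("co2_ref", "CO2_r", "CO2R", "CO2_ref"),
    "co2_sam": ("co2_sam", "CO2_s", "CO2S", "CO2_sample"),
    "h2o_ref": ("h2o_ref", "H2O_r", "H2OR"),
    "h2o_sam": ("h2o_sam", "H2O_s", "H2OS"),
    "flow": ("flow", "Flow"),
    "leaf_area": ("leaf_area", "S", "Area", "area"),
    "t_leaf": ("t_leaf", "Tleaf", "TleafCnd"),
    "t_air": ("t_air", "Tair"),
    "ppfd": ("ppfd", "Qin", "PARi"),
    "pressure": ("pressure", "Pa", "Press"),
    "A": ("A", "An", "Photo"),
    "Ci": ("Ci",),
    "E": ("E", "Trans"),
    "gtw": ("gtw", "gtc_w"),
    "gtc": ("gtc",),
}

#: Raw columns a file must provide (directly or via aliases).
REQUIRED_RAW = RAW_FIELDS


@dataclass
class ColumnMap:
    """Mapping from canonical field names to source column labels."""

    mapping: Dict[str, str] = field(default_factory=dict)

    def resolve(self, columns: Sequence[str]) -> Dict[str, str]:
        """source-label -> canonical-name rename dict for the given columns."""
        rename = {}
        for canonical, aliases in DEFAULT_ALIASES.items():
            source = self.mapping.get(canonical)
            candidates = (source,) if source else aliases
            for label in candidates:
                if label in columns:
                    rename[label] = canonical
                    break
        return rename


def _read_table(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise EmptyCurveError(f"{path}: file is empty")
    if "\t" in first:
        # instrument dialect: group row over variable row, then data
        df = pd.read_csv(path, sep="\t", header=[0, 1],
                         float_precision="round_trip")
        df.columns = [str(c[1]) for c in df.columns]
        logger.info("%s: detected tab-delimited instrument dialect", path)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        logger.info("%s: detected plain CSV dialect", path)
    return df


def _coerce_numeric(df: pd.DataFrame, columns: Sequence[str], path: Path) -> pd.DataFrame:
    for col in columns:
        raw = df[col]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CurveError(
                f"{path}: unparseable numeric value {raw.iloc[row]!r} "
                f"in column {col!r}, data row {row}"
            )
        df[col] = converted
    return df


def read_gasex_file(
    path: Union[str, Path],
    column_map: Optional[ColumnMap] = None,
    role: CurveRole = CurveRole.RACIR,
) -> Curve:
    """Read an instrument log or CSV into a curve, sorted by elapsed time.

    Unknown columns are preserved as opaque extras. Missing required raw
    columns raise a :class:`CurveError` naming them; unparseable numeric
    cells raise with row/column coordinates.
    """
    path = Path(path)
    df = _read_table(path)
    if len(df) == 0:
        raise EmptyCurveError(f"{path}: no data rows")

    rename = (column_map or ColumnMap()).resolve(list(df.columns))
    df = df.rename(columns=rename)

    missing = [c for c in REQUIRED_RAW if c not in df.columns]
    if missing:
        raise CurveError(f"{path}: missing required raw columns: {missing}")

    known = [c for c in list(RAW_FIELDS) + list(DERIVED_FIELDS) if c in df.columns]
    df = _coerce_numeric(df, known, path)
    df = df.sort_values("elapsed_s", kind="stable").reset_index(drop=True)
    return Curve(df, role=role, meta={"source": str(path)})


def write_curve(curve: Curve, path: Union[str, Path]) -> Path:
    """Write a curve as canonical CSV (full float precision, round-trippable)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    curve.data.to_csv(path, index=False)
    return path


def split_ramps(curve: Curve, smooth_window: int = 7) -> Tuple[Curve, Curve]:
    """Split a down-then-up program at the minimum of smoothed reference CO2.

    Returns ``(down, up)``. A monotone non-decreasing trace is returned
    whole as the up portion (empty down); a monotone non-increasing trace
    yields an empty up portion with a warning.
    """
    if len(curve) == 0:
        raise EmptyCurveError("cannot split an empty curve")
    ref = pd.Series(curve["co2_ref"])
    smoothed = ref.rolling(smooth_window, center=True, min_periods=1).median().to_numpy()
    imin = int(np.argmin(smoothed))

    df = curve.data
    if imin >= len(df) - 1 and smoothed[0] > smoothed[-1]:
        logger.warning("no up ramp found; returning the whole curve as down")
        down = curve.with_data(df)
        down.direction = RampDirection.DOWN
        up = curve.with_data(df.iloc[0:0])
        up.direction = RampDirection.UP
        return down, up
    if imin == 0 and not np.any(np.diff(smoothed) < 0):
        logger.warning("no direction change found; returning the whole curve as up")
    down = curve.with_data(df.iloc[:imin])
    down.direction = RampDirection.DOWN
    up = curve.with_data(df.iloc[imin:])
    up.direction = RampDirection.UP
    return down, up


# ---------------------------------------------------------------------------
# batch processing
# ---------------------------------------------------------------------------

BATCH_SCHEMA_VERSION = 1


@dataclass
class BatchEntry:
    racir_file: str
    ecrc_file: str
    rd_value: Optional[float] = None
    leaf_area_correction: Optional[float] = None
    ci_exclusion_windows: Sequence[Tuple[float, float]] = ()
    ci_range: Optional[Tuple[float, float]] = None


@dataclass
class BatchConfig:
    entries: List[BatchEntry]
    output_dir: str = "racir_out"
    delta_threshold: float = 0.05
    leaf_delta_threshold: float = 0.5
    min_run_length: int = 10
    lag_pad: int = 30
    nominal_area: float = 36.0


def load_batch_config(path: Union[str, Path]) -> BatchConfig:
    """Parse the YAML batch configuration (schema_version 1)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    version = doc.get("schema_version")
    if version != BATCH_SCHEMA_VERSION:
        raise RacirError(
            f"unsupported batch config schema_version {version!r}; "
            f"expected {BATCH_SCHEMA_VERSION}"
        )
    entries = [
        BatchEntry(
            racir_file=e["racir_file"],
            ecrc_file=e["ecrc_file"],
            rd_value=e.get("rd_value"),
            leaf_area_correction=e.get("leaf_area_correction"),
            ci_exclusion_windows=[tuple(w) for w in e.get("ci_exclusion_windows", [])],
            ci_range=tuple(e["ci_range"]) if e.get("ci_range") else None,
        )
        for e in doc.get("entries", [])
    ]
    kwargs = {
        k: doc[k]
        for k in (
            "output_dir",
            "delta_threshold",
            "leaf_delta_threshold",
            "min_run_length",
            "lag_pad",
            "nominal_area",
        )
        if k in doc
    }
    return BatchConfig(entries=entries, **kwargs)


def _settings_for(config: BatchConfig, entry: BatchEntry):
    from .pipeline import PipelineSettings

    return PipelineSettings(
        ecrc_filter=FilterSettings(
            delta_threshold=config.delta_threshold,
            min_run_length=config.min_run_length,
            lag_pad=config.lag_pad,
        ),
        leaf_filter=FilterSettings(
            delta_threshold=config.leaf_delta_threshold,
            min_run_length=config.min_run_length,
            lag_pad=config.lag_pad,
        ),
        nominal_area=config.nominal_area,
        leaf_area=entry.leaf_area_correction,
        rd_measured=entry.rd_value,
        ci_exclusion_windows=entry.ci_exclusion_windows,
        partial_ci_range=entry.ci_range,
    )


def run_batch(config: BatchConfig) -> Tuple[pd.DataFrame, int]:
    """Correct and fit every entry of a batch configuration.

    Failures are isolated per entry: each failed input contributes an
    ``error`` column in the summary instead of aborting the run. Returns
    the summary frame (also written to ``summary.csv`` in the output
    directory) and the number of failed entries.
    """
    from .pipeline import correct_and_fit

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    n_failed = 0
    for entry in config.entries:
        stem = Path(entry.racir_file).stem
        row = {"racir_file": entry.racir_file, "ecrc_file": entry.ecrc_file}
        try:
            racir = read_gasex_file(entry.racir_file, role=CurveRole.RACIR)
            ecrc = read_gasex_file(entry.ecrc_file, role=CurveRole.ECRC)
            result = correct_and_fit(racir, ecrc, _settings_for(config, entry))
            write_curve(result.corrected, out_dir / f"{stem}_corrected.csv")
            sidecar = {
                "ecrc_selected": result.ecrc_selected.to_dict(),
                "ecrc_candidates": [m.to_dict() for m in result.ecrc_models],
                "fit": result.fit.to_dict(),
                "fit_partial": (
                    result.fit_partial.to_dict() if result.fit_partial else None
                ),
                "counts": result.counts,
            }
            with open(out_dir / f"{stem}_fit.json", "w") as fh:
                json.dump(sidecar, fh, indent=2, sort_keys=True)
            row.update(result.summary_row())
            row.update(result.counts)
            row["error"] = ""
        except Exception as exc:
            logger.error("entry %s failed: %s", entry.racir_file, exc)
            row["error"] = f"{type(exc).__name__}: {exc}"
            n_failed += 1
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "summary.csv", index=False)
    return summary, n_failed
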