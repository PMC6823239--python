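"""Containers for gas-exchange time series.

A :class:`Curve` is an ordered sequence of logged time points backed by a
:class:`pandas.DataFrame`, plus provenance metadata (what kind of curve it
is, which ramp direction it covers, which empty-chamber model corrected it).
Raw instrument fields and derived quantities live in the same frame; derived
columns are absent until :mod:`racir.gasx` computes them.

:class:`GasExchangeRecord` is the scalar, single-time-point view used by the
record-level equations and by tests that cross-check the vectorised paths.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import CurveError, EmptyCurveError

#: Columns a curve must carry to be computable from scratch.
RAW_FIELDS = (
    "elapsed_s",
    "co2_ref",
    "co2_sam",
    "h2o_ref",
    "h2o_sam",
    "flow",
    "leaf_area",
    "t_leaf",
    "t_air",
    "ppfd",
    "pressure",
)

#: Columns produced by the gas-exchange equations.
DERIVED_FIELDS = ("A", "E", "gtw", "gtc", "Ci")


class CurveRole(str, enum.Enum):
    """What a curve measures: an empty chamber, a rapid ramp, or a stepped curve."""

    ECRC = "ecrc"
    RACIR = "racir"
    TRAD = "trad"


class RampDirection(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    MIXED = "mixed"


@dataclass
class GasExchangeRecord:
    """One logged time point.

    Raw IRGA quantities are required; derived fluxes and conductances start
    as ``None`` and are filled in by :mod:`racir.gasx`. ``flags`` collects
    the names of quality problems (e.g. ``"no_vapor_gradient"``) so that no
    record is ever silently dropped.
    """

    elapsed_s: float
    co2_ref: float  # umol mol-1, reference cell
    co2_sam: float  # umol mol-1, sample cell
    h2o_ref: float  # mmol mol-1
    h2o_sam: float  # mmol mol-1
    flow: float  # umol air s-1
    leaf_area: float  # cm^2; 0 allowed only for empty-chamber records
    t_leaf: float = 25.0  # degC
    t_air: float = 25.0  # degC
    ppfd: float = 1200.0  # umol m-2 s-1
    pressure: float = 101.325  # kPa
    A: Optional[float] = None  # umol m-2 s-1
    E: Optional[float] = None  # mol m-2 s-1
    gtw: Optional[float] = None  # mol m-2 s-1
    gtc: Optional[float] = None  # mol m-2 s-1
    Ci: Optional[float] = None  # umol mol-1
    flags: list = field(default_factory=list)

    def flag(self, name: str) -> None:
        if name not in self.flags:
            self.flags.append(name)


class Curve:
    """An ordered gas-exchange record sequence with provenance metadata."""

    def __init__(
        self,
        data: pd.DataFrame,
        role: CurveRole = CurveRole.RACIR,
        direction: Optional[RampDirection] = None,
        meta: Optional[Mapping] = None,
        validate: bool = True,
    ):
        df = data.reset_index(drop=True).copy()
        self.role = CurveRole(role)
        self.direction = RampDirection(direction) if direction is not None else None
        self.meta = dict(meta) if meta else {}
        if validate:
            self._validate(df)
        self._data = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        missing = [c for c in RAW_FIELDS if c not in df.columns]
        if missing:
            raise CurveError(f"curve is missing required raw columns: {missing}")
        if len(df) == 0:
            return
        t = df["elapsed_s"].to_numpy(dtype=float)
        if not np.all(np.diff(t) > 0):
            raise CurveError("elapsed_s must be strictly increasing within a curve")
        for col in ("co2_ref", "co2_sam", "h2o_ref", "h2o_sam"):
            if (df[col].to_numpy(dtype=float) < 0).any():
                raise CurveError(f"negative mole fraction in column {col!r}")
        if (df["h2o_sam"].to_numpy(dtype=float) >= 1000).any():
            raise CurveError("h2o_sam must be below 1000 mmol mol-1")
        if (df["pressure"].to_numpy(dtype=float) <= 0).any():
            raise CurveError("pressure must be positive")

    # -- accessors ---------------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    def __len__(self) -> int:
        return len(self._data)

    def __getitem__(self, column: str) -> np.ndarray:
        return self._data[column].to_numpy(dtype=float)

    def has_derived(self) -> bool:
        return all(c in self._data.columns for c in DERIVED_FIELDS)

    def with_data(self, df: pd.DataFrame, validate: bool = True, **meta_updates) -> "Curve":
        """A new curve with the same provenance but different records."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Curve(df, role=self.role, direction=self.direction, meta=meta, validate=validate)

    def require_nonempty(self) -> "Curve":
        if len(self) == 0:
            raise EmptyCurveError("curve has no records")
        return self

    # -- record-level view -------------------------------------------------

    def records(self) -> list:
        """Materialise the curve as a list of :class:`GasExchangeRecord`."""
        out = []
        for row in self._data.itertuples(index=False):
            d = row._asdict()
            rec = GasExchangeRecord(
                **{k: d[k] for k in RAW_FIELDS},
            )
            for k in DERIVED_FIELDS:
                if k in d and d[k] is not None and np.isfinite(d[k]):
                    setattr(rec, k, float(d[k]))
            out.append(rec)
        return out

    @classmethod
    def from_records(cls, records: Iterable[GasExchangeRecord], **kwargs) -> "Curve":
        rows = []
        for rec in records:
            row = {k: getattr(rec, k) for k in RAW_FIELDS}
            for k in DERIVED_FIELDS:
                v = getattr(rec, k)
                if v is not None:
                    row[k] = v
            rows.append(row)
        return cls(pd.DataFrame(rows), **kwargs)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        d = self.direction.value if self.direction else "?"
        return f"<Curve role={self.role.value} direction={d} n={len(self)}>"
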