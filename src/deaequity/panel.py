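"""Balanced DMU x period panel container, validation, I/O and descriptive statistics.

The panel holds every indicator of a multi-city hospital-resource dataset in long
form: decision-making units (DMUs, e.g. cities), ordered period labels (e.g. years),
and one column of nonnegative values per (dmu, period, indicator) cell.  Indicators
carry a role — ``input`` / ``output`` feed the envelopment models, ``environment``
covariates feed the slack regressions, ``area`` and ``population`` feed the
concentration indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateRecordError,
    InvalidMeasurementError,
    UnbalancedPanelError,
)

ROLES = ("input", "output", "environment", "area", "population")


@dataclass(frozen=True)
class IndicatorSpec:
    """One indicator of the panel: its name, role and (free-text) units."""

    name: str
    role: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown indicator role {self.role!r}; expected one of {ROLES}")


class PanelDataset:
    """A balanced panel of nonnegative indicator values over DMUs and periods.

    Parameters
    ----------
    data :
        Wide frame indexed by a (dmu, period) MultiIndex with one column per
        indicator; or anything :meth:`from_long` accepts via the classmethod.
    specs :
        One :class:`IndicatorSpec` per column of ``data``.

    Ordering of DMUs and periods is preserved as first encountered and is
    semantically meaningful: Malmquist adjacency is list order on periods.
    """

    def __init__(self, data: pd.DataFrame, specs: list[IndicatorSpec],
                 dmus: list[str] | None = None, periods: list[str] | None = None):
        spec_names = [s.name for s in specs]
        if len(set(spec_names)) != len(spec_names):
            raise ValueError("indicator names must be unique")
        missing = set(spec_names) - set(data.columns)
        if missing:
            raise UnbalancedPanelError(f"unbalanced panel: no values for indicators {sorted(missing)}")
        self.indicator_specs = list(specs)
        self.dmus = list(dmus) if dmus is not None else list(dict.fromkeys(data.index.get_level_values(0)))
        self.periods = list(periods) if periods is not None else list(dict.fromkeys(data.index.get_level_values(1)))
        full = pd.MultiIndex.from_product([self.dmus, self.periods], names=["dmu", "period"])
        try:
            self._data = data.loc[full, spec_names].astype(float)
        except KeyError:
            present = set(data.index)
            hole = next(c for c in full if c not in present)
            raise UnbalancedPanelError(f"unbalanced panel: missing cell {hole}") from None
        self._validate()

    # -- construction ---------------------------------------------------------

    @classmethod
    def from_long(cls, frame: pd.DataFrame, specs: list[IndicatorSpec]) -> "PanelDataset":
        """Build a panel from a long frame with columns dmu, period, indicator, value."""
        required = {"dmu", "period", "indicator", "value"}
        if not required.issubset(frame.columns):
            raise ValueError(f"long panel needs columns {sorted(required)}")
        dup = frame.duplicated(subset=["dmu", "period", "indicator"])
        if dup.any():
            row = frame.loc[dup.idxmax()]
            raise DuplicateRecordError(
                f"duplicate record: ({row['dmu']}, {row['period']}, {row['indicator']})")
        dmus = list(dict.fromkeys(frame["dmu"]))
        periods = list(dict.fromkeys(frame["period"]))
        wide = frame.pivot(index=["dmu", "period"], columns="indicator", values="value")
        n_expected = len(dmus) * len(periods)
        if len(wide) != n_expected or wide.isna().any().any():
            if wide.isna().any().any():
                cell = next(zip(*np.where(wide.isna().to_numpy())))
                hole = (wide.index[cell[0]], wide.columns[cell[1]])
            else:
                present = set(wide.index)
                hole = next((d, p) for d in dmus for p in periods if (d, p) not in present)
            raise UnbalancedPanelError(f"unbalanced panel: missing cell {hole}")
        return cls(wide, specs, dmus=dmus, periods=periods)

    def _validate(self) -> None:
        values = self._data.to_numpy()
        if np.isnan(values).any():
            raise UnbalancedPanelError("unbalanced panel: NaN cell")
        if (values < 0).any():
            col = self._data.columns[np.where(values < 0)[1][0]]
            raise InvalidMeasurementError(f"invalid measurement: negative value in {col!r}")
        for spec in self.indicator_specs:
            if spec.role in ("input", "output") and (self._data[spec.name] <= 0).any():
                raise InvalidMeasurementError(
                    f"invalid measurement: nonpositive {spec.role} value in {spec.name!r}")

    # -- accessors -------------------------------------------------------------

    def names(self, role: str) -> list[str]:
        return [s.name for s in self.indicator_specs if s.role == role]

    @property
    def input_names(self) -> list[str]:
        return self.names("input")

    @property
    def output_names(self) -> list[str]:
        return self.names("output")

    @property
    def environment_names(self) -> list[str]:
        return self.names("environment")

    def frame(self) -> pd.DataFrame:
        """The wide (dmu, period)-indexed frame of all indicators (copy)."""
        return self._data.copy()

    def slice(self, period, role: str) -> pd.DataFrame:
        """DMU-indexed frame of one role's indicators for a single period."""
        cols = self.names(role)
        sub = self._data.xs(period, level="period")[cols]
        return sub.loc[self.dmus]

    def period_data(self, period) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(inputs, outputs) frames for one period, DMU-indexed."""
        return self.slice(period, "input"), self.slice(period, "output")

    def to_long(self) -> pd.DataFrame:
        long = (self._data.stack().rename("value").reset_index()
                .rename(columns={"level_2": "indicator"}))
        return long[["dmu", "period", "indicator", "value"]]

    def __eq__(self, other) -> bool:
        return (isinstance(other, PanelDataset)
                and self.dmus == other.dmus and self.periods == other.periods
                and self.indicator_specs == other.indicator_specs
                and self._data.equals(other._data))

    def __repr__(self) -> str:
        return (f"PanelDataset({len(self.dmus)} dmus x {len(self.periods)} periods x "
                f"{len(self.indicator_specs)} indicators)")


def read_panel(path, spec: dict[str, str] | list[IndicatorSpec]) -> PanelDataset:
    """Read a panel CSV (long or wide layout) and validate it.

    ``spec`` maps indicator name -> role, or is a list of :class:`IndicatorSpec`.
    Long layout requires columns dmu, period, indicator, value; any other header is
    treated as wide (dmu, period, one column per indicator).
    """
    if isinstance(spec, dict):
        specs = [IndicatorSpec(name, role) for name, role in spec.items()]
    else:
        specs = list(spec)
    frame = pd.read_csv(path, dtype={"dmu": str, "period": str},
                        float_precision="round_trip")
    if {"dmu", "period", "indicator", "value"}.issubset(frame.columns):
        return PanelDataset.from_long(frame, specs)
    long = frame.melt(id_vars=["dmu", "period"], var_name="indicator", value_name="value")
    long = long[long["indicator"].isin([s.name for s in specs])]
    return PanelDataset.from_long(long, specs)


def write_panel(panel: PanelDataset, path) -> None:
    """Write the panel in long layout at full float precision (round-trip safe)."""
    panel.to_long().to_csv(path, index=False, float_format="%.17g")


def describe(panel: PanelDataset) -> pd.DataFrame:
    """Per-indicator n, mean, sample (n-1) sd, max and min over all cells."""
    data = panel.frame()
    out = pd.DataFrame({
        "n": data.count(),
        "mean": data.mean(),
        "sd": data.std(ddof=1),
        "max": data.max(),
        "min": data.min(),
    })
    out.index.name = "indicator"
    return out.loc[[s.name for s in panel.indicator_specs]]
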