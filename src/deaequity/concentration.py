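"""Health-resource agglomeration (HRAD), population agglomeration (PAD) and
per-capita equity ratios.

HRAD_i = (HR_i / HR_n) / (A_i / A_n) compares a region's share of a resource to
its share of land area (1 = proportional to area); PAD_i does the same for
population.  Their ratio (HR_i/HR_n)/(P_i/P_n) is area-free and measures
per-capita equity: 1 = resources proportional to population, > 1 relative
abundance, < 1 relative scarcity.  Parent totals default to sums over the
supplied regions but can be overridden to score a region list against a larger
reference region (e.g. one province against national totals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyReferenceRegionError

VERDICT_TOL = 1e-9


@dataclass
class RegionEndowment:
    """One region's resource amounts, land area (km^2) and population."""

    region: str
    resources: dict[str, float]
    area: float
    population: float


def _share_ratio(numer: pd.Series, denom: pd.Series, numer_total: float | None,
                 denom_total: float | None, what: str) -> pd.Series:
    nt = float(numer.sum()) if numer_total is None else float(numer_total)
    dt = float(denom.sum()) if denom_total is None else float(denom_total)
    if nt <= 0 or dt <= 0:
        raise EmptyReferenceRegionError(f"empty reference region: zero parent {what}")
    return (numer / nt) / (denom / dt)


def hrad(resources: pd.Series, areas: pd.Series, total_resources: float | None = None,
         total_area: float | None = None) -> pd.Series:
    """Per-region HRAD = (HR_i/HR_n)/(A_i/A_n); zero-resource regions score 0."""
    return _share_ratio(resources, areas, total_resources, total_area, "resource total")


def pad(population: pd.Series, areas: pd.Series, total_population: float | None = None,
        total_area: float | None = None) -> pd.Series:
    """Per-region PAD = (P_i/P_n)/(A_i/A_n)."""
    return _share_ratio(population, areas, total_population, total_area, "population")


def equity_ratio(hrad_values, pad_values):
    """HRAD/PAD — per-capita resource share, independent of the area column."""
    return hrad_values / pad_values


def geographic_verdict(value: float, tol: float = VERDICT_TOL) -> str:
    """1-threshold reading of HRAD (or PAD): proportional / abundant / scarce."""
    if abs(value - 1.0) <= tol:
        return "proportional"
    return "abundant" if value > 1.0 else "scarce"


def population_verdict(ratio: float, tol: float = VERDICT_TOL) -> str:
    """1-threshold reading of HRAD/PAD: sufficient / abundant / scarce."""
    if abs(ratio - 1.0) <= tol:
        return "sufficient"
    return "abundant" if ratio > 1.0 else "scarce"


def concentration_table(resources: pd.DataFrame, areas: pd.Series,
                        population: pd.Series,
                        parent_totals: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-region HRAD and HRAD/PAD ratio for every resource column, plus PAD.

    ``parent_totals`` may supply explicit reference totals keyed by resource
    name, ``"area"`` and ``"population"`` when the regions do not exhaust the
    reference region.  Output mirrors the published layout: for each resource a
    ``<name>_HRAD`` and ``<name>_ratio`` column, then a final ``PAD`` column.
    """
    parent_totals = parent_totals or {}
    ta = parent_totals.get("area")
    tp = parent_totals.get("population")
    p = pad(population, areas, tp, ta)
    out = {}
    for name in resources.columns:
        h = hrad(resources[name], areas, parent_totals.get(name), ta)
        out[f"{name}_HRAD"] = h
        out[f"{name}_ratio"] = equity_ratio(h, p)
    out["PAD"] = p
    return pd.DataFrame(out, index=resources.index)
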