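"""Adjacent-period Malmquist total-factor-productivity indices and decomposition.

For each DMU and adjacent period pair (t, t+1) the input-oriented Farrell
distances D_p(q) — the radial score of the period-q observation against the
period-p frontier — give the standard Färe et al. decomposition:

    EC   = D_{t+1}(t+1) / D_t(t)                      (CRS, catching-up)
    TC   = sqrt[ D_t(t+1)/D_{t+1}(t+1) * D_t(t)/D_{t+1}(t) ]   (frontier shift)
    PECT = D_{t+1}(t+1) / D_t(t)                      (VRS own-period distances)
    SEC  = EC / PECT                                   (scale-efficiency change)
    TFP  = EC * TC = PECT * SEC * TC

Only own-period VRS distances are needed, so the classic cross-period VRS
infeasibility never arises in the default decomposition; a strict mode exposes
the cross-period VRS LPs for diagnostics and raises when they are infeasible.
All period-level and DMU-level averages are geometric means, the only mean under
which the decomposition identities survive aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dea import radial_score
from .panel import PanelDataset

COMPONENTS = ["EC", "TC", "PECT", "SEC", "TFP"]


@dataclass
class DistanceSet:
    """The four CRS and two own-period VRS distances of one (dmu, t, t+1) cell."""

    d_t_t: float
    d_t_t1: float
    d_t1_t: float
    d_t1_t1: float
    d_t_t_vrs: float
    d_t1_t1_vrs: float


@dataclass
class MalmquistRecord:
    dmu: str
    period_pair: tuple
    ec: float
    tc: float
    pect: float
    sec: float
    tfp: float


def cross_distance(panel: PanelDataset, tech_period, eval_period, dmu: str,
                   rts: str = "crs") -> float:
    """Radial score of ``dmu``'s (x, y) in ``eval_period`` against the
    ``tech_period`` frontier.  May exceed 1 for cross-period CRS evaluation;
    raises InfeasibleDistanceError for an infeasible cross-period VRS LP."""
    FX, FY = panel.period_data(tech_period)
    EX, EY = panel.period_data(eval_period)
    return radial_score(FX, FY, EX.loc[dmu], EY.loc[dmu], rts=rts,
                        two_phase=False).theta


def distance_set(panel: PanelDataset, dmu: str, t, t1) -> DistanceSet:
    return DistanceSet(
        d_t_t=cross_distance(panel, t, t, dmu, "crs"),
        d_t_t1=cross_distance(panel, t, t1, dmu, "crs"),
        d_t1_t=cross_distance(panel, t1, t, dmu, "crs"),
        d_t1_t1=cross_distance(panel, t1, t1, dmu, "crs"),
        d_t_t_vrs=cross_distance(panel, t, t, dmu, "vrs"),
        d_t1_t1_vrs=cross_distance(panel, t1, t1, dmu, "vrs"),
    )


def malmquist_pair(panel: PanelDataset, dmu: str, t, t1) -> MalmquistRecord:
    """TFP index and decomposition for one DMU across one adjacent period pair."""
    d = distance_set(panel, dmu, t, t1)
    ec = d.d_t1_t1 / d.d_t_t
    tc = float(np.sqrt((d.d_t_t1 / d.d_t1_t1) * (d.d_t_t / d.d_t1_t)))
    pect = d.d_t1_t1_vrs / d.d_t_t_vrs
    sec = ec / pect
    return MalmquistRecord(dmu=dmu, period_pair=(t, t1),
                           ec=ec, tc=tc, pect=pect, sec=sec, tfp=ec * tc)


def malmquist_panel(panel: PanelDataset) -> list[MalmquistRecord]:
    """Records for every DMU and every adjacent period pair, in panel order.

    Period adjacency is list order on ``panel.periods`` (labels are opaque)."""
    records = []
    for t, t1 in zip(panel.periods[:-1], panel.periods[1:]):
        for dmu in panel.dmus:
            records.append(malmquist_pair(panel, dmu, t, t1))
    return records


def geometric_mean(values) -> float:
    a = np.asarray(values, float)
    return float(np.exp(np.mean(np.log(a))))


def _records_frame(records: list[MalmquistRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "dmu": r.dmu, "pair": f"{r.period_pair[0]}-{r.period_pair[1]}",
        "EC": r.ec, "TC": r.tc, "PECT": r.pect, "SEC": r.sec, "TFP": r.tfp,
    } for r in records])


def aggregate(records: list[MalmquistRecord]) -> dict[str, pd.DataFrame]:
    """Period-pair and DMU tables with geometric-mean "Average value" rows.

    Returns ``{"by_period": ..., "by_dmu": ...}``; each table averages the
    component indices geometrically across the other dimension, and the final
    row is the geometric mean over all records (the grand average).
    """
    frame = _records_frame(records)
    out = {}
    for key, name in (("pair", "by_period"), ("dmu", "by_dmu")):
        order = list(dict.fromkeys(frame[key]))
        tab = (frame.groupby(key, sort=False)[COMPONENTS]
               .agg(geometric_mean).loc[order])
        tab.loc["Average value"] = [geometric_mean(frame[c]) for c in COMPONENTS]
        tab.index.name = name
        out[name] = tab
    return out
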