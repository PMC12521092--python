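"""Input-oriented CCR/BCC envelopment with two-phase slack maximisation.

The radial model solved here is, for an evaluated unit (x0, y0) against frontier
units (x_j, y_j):

    min theta   s.t.  sum_j lambda_j x_j <= theta x0,
                      sum_j lambda_j y_j >= y0,
                      [VRS only] sum_j lambda_j = 1,   lambda_j >= 0.

The non-Archimedean epsilon of the classic formulation is replaced by a second,
lexicographic phase: with theta fixed at its optimum, total slack
e's- + e's+ is maximised.  Phase 2 is solved over lambda alone (the slacks are
affine in lambda at fixed theta), which avoids ill-conditioned equality
constraints.  Both phases operate on column-mean-normalised data, so every
reported quantity is invariant to the units of measurement; slacks are rescaled
back to raw units on output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .exceptions import InfeasibleDistanceError, InternalLPError, MalformedProblemError

#: tolerance for "equal to 1" classifications of efficiency scores and lambda sums
EFFICIENCY_TOL = 1e-6


@dataclass
class DEAResult:
    """Optimal radial score, peer weights and slacks for one DMU.

    theta is the Farrell input efficiency (<= 1 against an own-period frontier);
    lambdas are intensity weights over the frontier DMUs; slacks are the residual
    input excess / output shortfall after the radial contraction, in raw units.
    """

    dmu: str
    theta: float
    lambdas: pd.Series
    input_slacks: pd.Series
    output_slacks: pd.Series
    rts_model: str  # "crs" or "vrs"

    @property
    def lambda_sum(self) -> float:
        return float(self.lambdas.sum())

    @property
    def is_efficient(self) -> bool:
        return (self.theta >= 1.0 - EFFICIENCY_TOL
                and float(self.input_slacks.sum() + self.output_slacks.sum()) <= EFFICIENCY_TOL)


@dataclass
class EfficiencyDecomposition:
    """TE = PTE x SE split with returns-to-scale and relative-efficiency labels."""

    dmu: str
    te: float
    pte: float
    se: float
    rts_label: str              # constant | increasing | decreasing
    relative_efficiency: str    # efficient | weakly-effective | ineffective


@dataclass
class Projection:
    """Frontier targets ("ideal values"): theta*x - s- for inputs, y + s+ for outputs."""

    dmu: str
    input_targets: pd.Series
    output_targets: pd.Series


def _radial_lp(FX: np.ndarray, FY: np.ndarray, x0: np.ndarray, y0: np.ndarray,
               vrs: bool) -> tuple[float, np.ndarray]:
    """Phase 1: minimise theta. Returns (theta, lambda) on normalised data."""
    n = FX.shape[0]
    c = np.zeros(n + 1)
    c[0] = 1.0
    A_ub = np.vstack([
        np.hstack([-x0[:, None], FX.T]),      # Xl - theta x0 <= 0
        np.hstack([np.zeros((FY.shape[1], 1)), -FY.T]),  # -Yl <= -y0
    ])
    b_ub = np.concatenate([np.zeros(len(x0)), -y0])
    A_eq = b_eq = None
    if vrs:
        A_eq = np.hstack([[0.0], np.ones(n)])[None, :]
        b_eq = [1.0]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * (n + 1), method="highs")
    if res.status == 2:
        raise InfeasibleDistanceError("VRS cross-period infeasible")
    if res.status == 3:
        raise MalformedProblemError("malformed problem: envelopment LP unbounded")
    if not res.success:
        raise InternalLPError(f"internal LP failure: {res.message}")
    return float(res.x[0]), res.x[1:]


def _slack_max_lp(FX: np.ndarray, FY: np.ndarray, x0: np.ndarray, y0: np.ndarray,
                  theta: float, vrs: bool, lam0: np.ndarray) -> np.ndarray:
    """Phase 2: at fixed theta, maximise total slack; returns optimal lambda."""
    n = FX.shape[0]
    c = FX.sum(axis=1) - FY.sum(axis=1)  # minimising this maximises total slack
    A_ub = np.vstack([FX.T, -FY.T])
    A_eq = np.ones((1, n)) if vrs else None
    b_eq = [1.0] if vrs else None
    for relax in (0.0, 1e-9, 1e-7):
        b_ub = np.concatenate([theta * (1 + relax) * x0 + relax, -y0])
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=[(0, None)] * n, method="highs")
        if res.success:
            return res.x
    return lam0  # phase-1 vertex is feasible by construction; accept its slacks


def radial_score(frontier_inputs: pd.DataFrame, frontier_outputs: pd.DataFrame,
                 x0: pd.Series, y0: pd.Series, rts: str = "vrs",
                 two_phase: bool = True) -> DEAResult:
    """Radial input-oriented score of point (x0, y0) against an arbitrary frontier.

    The evaluated point need not belong to the frontier set (cross-period Malmquist
    distances evaluate period t+1 units against the period t technology), in which
    case theta may exceed 1 under CRS.
    """
    rts = rts.lower()
    if rts not in ("crs", "vrs"):
        raise ValueError(f"rts must be 'crs' or 'vrs', got {rts!r}")
    FX_raw = frontier_inputs.to_numpy(float)
    FY_raw = frontier_outputs.to_numpy(float)
    x_scale = FX_raw.mean(axis=0)
    y_scale = FY_raw.mean(axis=0)
    FX, FY = FX_raw / x_scale, FY_raw / y_scale
    x0n = x0.to_numpy(float) / x_scale
    y0n = y0.to_numpy(float) / y_scale

    theta, lam = _radial_lp(FX, FY, x0n, y0n, vrs=(rts == "vrs"))
    if two_phase:
        lam = _slack_max_lp(FX, FY, x0n, y0n, theta, rts == "vrs", lam)
    s_minus = np.clip(theta * x0n - FX.T @ lam, 0.0, None) * x_scale
    s_plus = np.clip(FY.T @ lam - y0n, 0.0, None) * y_scale
    return DEAResult(
        dmu=str(x0.name),
        theta=theta,
        lambdas=pd.Series(lam, index=frontier_inputs.index),
        input_slacks=pd.Series(s_minus, index=frontier_inputs.columns),
        output_slacks=pd.Series(s_plus, index=frontier_outputs.columns),
        rts_model=rts,
    )


def solve_envelopment(inputs: pd.DataFrame, outputs: pd.DataFrame, dmu: str,
                      rts: str = "vrs") -> DEAResult:
    """Solve the two-phase envelopment LP for one DMU of a single-period slice.

    ``inputs`` / ``outputs`` are DMU-indexed frames (one row per DMU of the
    period).  theta is clipped into (0, 1] at the classification tolerance, as a
    DMU can never lie strictly outside a frontier it belongs to.
    """
    res = radial_score(inputs, outputs, inputs.loc[dmu], outputs.loc[dmu], rts=rts)
    if res.theta > 1.0:
        if res.theta > 1.0 + 1e-6:
            raise InternalLPError(f"own-period theta {res.theta} exceeds 1")
        res.theta = 1.0
    return res


def solve_period(inputs: pd.DataFrame, outputs: pd.DataFrame,
                 rts: str = "vrs") -> dict[str, DEAResult]:
    """Envelopment results for every DMU of one period (needs >= 2 DMUs... or 1,
    which is trivially self-efficient)."""
    return {d: solve_envelopment(inputs, outputs, d, rts=rts) for d in inputs.index}


def classify_rts(crs_result: DEAResult, tol: float = EFFICIENCY_TOL) -> str:
    """Returns-to-scale label from the lambda sum at the CCR optimum.

    sum(lambda) = 1 -> constant; < 1 -> increasing; > 1 -> decreasing.  Ties at
    the tolerance boundary are classified constant.
    """
    s = crs_result.lambda_sum
    if abs(s - 1.0) <= tol:
        return "constant"
    return "increasing" if s < 1.0 else "decreasing"


def classify_relative(te: float, pte: float, total_slack: float = 0.0,
                      tol: float = EFFICIENCY_TOL) -> str:
    """Relative-efficiency label: efficient / weakly-effective / ineffective."""
    if te >= 1.0 - tol and total_slack <= tol:
        return "efficient"
    if pte >= 1.0 - tol:
        return "weakly-effective"
    return "ineffective"


def decompose_efficiency(crs: DEAResult, vrs: DEAResult) -> EfficiencyDecomposition:
    """TE/PTE/SE decomposition of paired CCR and BCC results for one DMU."""
    if crs.dmu != vrs.dmu:
        raise ValueError(f"results are for different DMUs: {crs.dmu!r} vs {vrs.dmu!r}")
    te, pte = crs.theta, vrs.theta
    se = te / pte
    total_slack = float(crs.input_slacks.sum() + crs.output_slacks.sum())
    return EfficiencyDecomposition(
        dmu=crs.dmu, te=te, pte=pte, se=se,
        rts_label=classify_rts(crs),
        relative_efficiency=classify_relative(te, pte, total_slack),
    )


def project(x0: pd.Series, y0: pd.Series, result: DEAResult) -> Projection:
    """Frontier targets for one DMU: inputs theta*x - s-, outputs y + s+."""
    return Projection(
        dmu=result.dmu,
        input_targets=result.theta * x0 - result.input_slacks,
        output_targets=y0 + result.output_slacks,
    )


def efficiency_table(inputs: pd.DataFrame, outputs: pd.DataFrame) -> pd.DataFrame:
    """Per-DMU TE/PTE/SE table with scale-returns and relative-efficiency labels.

    Mirrors the standard published layout: efficient DMUs show "-" in the
    scale-returns column.  Values are full precision; display rounding belongs to
    the report layer.
    """
    crs = solve_period(inputs, outputs, rts="crs")
    vrs = solve_period(inputs, outputs, rts="vrs")
    rows = []
    for dmu in inputs.index:
        d = decompose_efficiency(crs[dmu], vrs[dmu])
        rows.append({
            "dmu": dmu, "TE": d.te, "PTE": d.pte, "SE": d.se,
            "scale_returns": "-" if d.relative_efficiency == "efficient" else {
                "constant": "crs", "increasing": "irs", "decreasing": "drs"}[d.rts_label],
            "relative_efficiency": d.relative_efficiency,
        })
    return pd.DataFrame(rows).set_index("dmu")
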