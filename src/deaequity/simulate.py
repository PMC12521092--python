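"""Seeded generator of province-like hospital-resource panels with known truth.

The generator emulates the study conditions the published bulletins describe —
a balanced 14-city x 7-year panel whose indicator magnitudes match the published
mean/sd — while exposing the ground truth no real bulletin provides: true
management efficiency, the environment-driven part of every input excess, and
the noise draws.  The data-generating process is:

1.  A per-city size factor links all indicators (big cities have more of
    everything); each indicator is marginally lognormal with moment-matched
    (mean, sd).
2.  Frontier ("efficient") input bundles x* are drawn at a scale such that the
    *realised* inputs match the published means after inflation.
3.  Efficient outputs come from per-output Cobb-Douglas frontiers with
    exponents summing to 1 (a CRS technology, so a noiseless panel is entirely
    DEA-efficient), times a per-period drift factor that shifts the frontier.
4.  Realised inputs are x* inflated by exp(u + eta + v): half-normal management
    inefficiency u (shared across inputs within a city-year), an environment
    effect eta driven by the covariates' standardised scores, and Gaussian
    noise v per input.  This is exactly the structure the stage-2 slack
    regressions are designed to strip out.

Areas are drawn once per city and held fixed; the ``population`` indicator for
concentration analysis is the resident-population covariate in persons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import DEFAULT_DMUS, DEFAULT_INDICATOR_TARGETS, DEFAULT_PERIODS
from .exceptions import ConfigError
from .panel import IndicatorSpec, PanelDataset

_SQRT_2_PI = float(np.sqrt(2.0 / np.pi))

#: per-output Cobb-Douglas exponents over the four inputs (each row sums to 1)
DEFAULT_FRONTIER_EXPONENTS = {
    "tcm_prescriptions": (0.35, 0.15, 0.15, 0.35),
    "tcm_consultations": (0.40, 0.20, 0.20, 0.20),
    "tcm_discharges": (0.30, 0.10, 0.10, 0.50),
}

#: log-slack inflation per 1-sd increase of each environment covariate's score
DEFAULT_ENV_EFFECTS = {
    "gdp_per_capita": 0.08,
    "resident_population": 0.05,
    "tcm_outpatient_share": -0.04,
}


@dataclass
class GeneratorConfig:
    """Study-condition knobs of the synthetic panel.

    sigma_u / sigma_v are log-scale half-normal inefficiency and Gaussian noise
    scales; drift is the per-period multiplicative frontier shift (values < 1 =
    technical regress, matching the mild productivity decline of the emulated
    setting); env_effects link standardised covariate scores to log input
    inflation.  Same seed => bit-identical panel.
    """

    n_dmus: int = 14
    n_periods: int = 7
    seed: int = 0
    sigma_u: float = 0.15
    sigma_v: float = 0.05
    drift: float = 0.955
    size_corr: float = 0.9
    frontier_exponents: dict = field(default_factory=lambda: dict(DEFAULT_FRONTIER_EXPONENTS))
    env_effects: dict = field(default_factory=lambda: dict(DEFAULT_ENV_EFFECTS))
    indicator_targets: dict = field(default_factory=lambda: dict(DEFAULT_INDICATOR_TARGETS))

    def __post_init__(self) -> None:
        if self.sigma_u < 0 or self.sigma_v < 0:
            raise ConfigError("noise scales must be nonnegative")
        if not (0 <= self.size_corr <= 1):
            raise ConfigError("size_corr must lie in [0, 1]")
        for name, (role, units, mean, sd, mx, mn) in self.indicator_targets.items():
            if mn > mx:
                raise ConfigError(f"infeasible scale targets for {name!r}: min {mn} > max {mx}")
            if mean <= 0 or sd < 0:
                raise ConfigError(f"infeasible scale targets for {name!r}: mean/sd")
        n_inputs = sum(1 for t in self.indicator_targets.values() if t[0] == "input")
        outputs = [n for n, t in self.indicator_targets.items() if t[0] == "output"]
        if set(outputs) != set(self.frontier_exponents):
            raise ConfigError("frontier_exponents must cover exactly the output indicators")
        for out, exps in self.frontier_exponents.items():
            e = np.asarray(exps, float)
            if len(e) != n_inputs or (e <= 0).any() or abs(e.sum() - 1.0) > 1e-9:
                raise ConfigError(f"frontier exponents for {out!r} must be positive, "
                                  "one per input, and sum to 1")


@dataclass
class GroundTruth:
    """What the generator knows and real data never reveals."""

    true_efficiency: pd.DataFrame          # dmu x period, exp(-u) in (0, 1]
    env_log_component: pd.DataFrame        # dmu x period, shared eta (before per-input scaling)
    noise: dict[str, pd.DataFrame]         # per input: dmu x period v draws
    sigma_u: float
    sigma_v: float
    env_effects: dict[str, float]
    drift: float
    frontier_exponents: dict

    def to_json(self) -> str:
        payload = {
            "sigma_u": self.sigma_u, "sigma_v": self.sigma_v, "drift": self.drift,
            "env_effects": self.env_effects,
            "frontier_exponents": {k: list(v) for k, v in self.frontier_exponents.items()},
            "true_efficiency": self.true_efficiency.to_dict(),
            "env_log_component": self.env_log_component.to_dict(),
            "noise": {k: v.to_dict() for k, v in self.noise.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and sd (moment matching)."""
    v = sd * sd
    sigma2 = np.log1p(v / (mean * mean))
    mu = np.log(mean) - 0.5 * sigma2
    return mu, float(np.sqrt(sigma2))


def _expected_inflation(cfg: GeneratorConfig) -> float:
    """E[exp(u + eta + v)] under the configured scales (for mean calibration)."""
    from scipy.stats import norm
    su = cfg.sigma_u
    e_u = 2.0 * np.exp(su * su / 2.0) * norm.cdf(su) if su > 0 else 1.0
    s2 = cfg.sigma_v ** 2 + sum(d * d for d in cfg.env_effects.values())
    return float(e_u * np.exp(s2 / 2.0))


def generate(config: GeneratorConfig | None = None) -> tuple[PanelDataset, GroundTruth]:
    """Draw one panel plus its ground truth.  Deterministic in ``config.seed``.

    One seed sequence per indicator (split in fixed declaration order), so adding
    an indicator at the end of the target table does not perturb earlier draws.
    """
    cfg = config or GeneratorConfig()
    targets = cfg.indicator_targets
    dmus = (DEFAULT_DMUS[:cfg.n_dmus] if cfg.n_dmus <= len(DEFAULT_DMUS)
            else [f"D{i:02d}" for i in range(cfg.n_dmus)])
    periods = (DEFAULT_PERIODS[:cfg.n_periods] if cfg.n_periods <= len(DEFAULT_PERIODS)
               else [str(2018 + i) for i in range(cfg.n_periods)])
    nd, np_ = cfg.n_dmus, cfg.n_periods

    root = np.random.SeedSequence(cfg.seed)
    names = ["_size", "_inefficiency"] + list(targets) + ["_noise"]
    streams = {name: np.random.default_rng(child)
               for name, child in zip(names, root.spawn(len(names)))}

    size = streams["_size"].standard_normal(nd)            # per-city size factor
    rho = cfg.size_corr
    idx = pd.Index(dmus, name="dmu")
    cols = pd.Index(periods, name="period")

    def cell_scores(rng, per_period: bool = True) -> np.ndarray:
        """(nd, np) standard-normal scores correlated across indicators via size."""
        e = rng.standard_normal((nd, np_)) if per_period else \
            np.repeat(rng.standard_normal((nd, 1)), np_, axis=1)
        return rho * size[:, None] + np.sqrt(1.0 - rho * rho) * e

    # environment covariates and their standardised scores
    env_scores: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    for name, (role, units, mean, sd, mx, mn) in targets.items():
        if role in ("environment", "area"):
            mu, s = _lognormal_params(mean, sd)
            z = cell_scores(streams[name], per_period=(role != "area"))
            values[name] = np.exp(mu + s * z)
            if role == "environment":
                env_scores[name] = z

    # shared log inflation per city-year
    u = np.abs(streams["_inefficiency"].standard_normal((nd, np_))) * cfg.sigma_u
    eta = np.zeros((nd, np_))
    for cov, delta in cfg.env_effects.items():
        if cov in env_scores:
            eta += delta * env_scores[cov]

    # frontier input bundles, scaled so realised inputs hit the published means
    infl = _expected_inflation(cfg)
    input_names = [n for n, t in targets.items() if t[0] == "input"]
    x_star: dict[str, np.ndarray] = {}
    noise: dict[str, pd.DataFrame] = {}
    noise_rng = streams["_noise"]
    for name in input_names:
        _, units, mean, sd, mx, mn = targets[name]
        mu, s = _lognormal_params(mean / infl, sd / infl)
        x_star[name] = np.exp(mu + s * cell_scores(streams[name]))
        v = noise_rng.standard_normal((nd, np_)) * cfg.sigma_v
        noise[name] = pd.DataFrame(v, index=idx, columns=cols)
        values[name] = x_star[name] * np.exp(u + eta + v)

    # efficient outputs from the Cobb-Douglas frontiers, with period drift
    drift_factor = cfg.drift ** np.arange(np_)[None, :]
    for name, (role, units, mean, sd, mx, mn) in targets.items():
        if role != "output":
            continue
        exps = np.asarray(cfg.frontier_exponents[name], float)
        raw = np.ones((nd, np_))
        for e, xn in zip(exps, input_names):
            raw = raw * x_star[xn] ** e
        raw = raw * drift_factor
        values[name] = raw * (mean / raw.mean())

    specs = [IndicatorSpec(n, t[0], t[1]) for n, t in targets.items()
             if t[0] != "population"]
    if "resident_population" in values:
        # population in persons for concentration analysis (covariate unit is 1e4)
        values["population"] = values["resident_population"] * 1e4
        specs.append(IndicatorSpec("population", "population", "persons"))

    long_rows = []
    for name in [s.name for s in specs]:
        df = pd.DataFrame(values[name], index=idx, columns=cols)
        melted = df.stack().rename("value").reset_index()
        melted["indicator"] = name
        long_rows.append(melted)
    long = pd.concat(long_rows, ignore_index=True)[["dmu", "period", "indicator", "value"]]
    panel = PanelDataset.from_long(long, specs)

    truth = GroundTruth(
        true_efficiency=pd.DataFrame(np.exp(-u), index=idx, columns=cols),
        env_log_component=pd.DataFrame(eta, index=idx, columns=cols),
        noise=noise,
        sigma_u=cfg.sigma_u, sigma_v=cfg.sigma_v,
        env_effects=dict(cfg.env_effects), drift=cfg.drift,
        frontier_exponents=dict(cfg.frontier_exponents),
    )
    return panel, truth


def drift_series(config: GeneratorConfig | None = None) -> list[float]:
    """Expected TFP per adjacent period pair in the noiseless frontier-only case.

    With all units on a CRS frontier shifted by ``drift`` each period, EC = 1 and
    TC = drift, so expected TFP is the drift factor for every pair.
    """
    cfg = config or GeneratorConfig()
    return [cfg.drift] * (cfg.n_periods - 1)


def roles_config(config: GeneratorConfig | None = None) -> dict[str, str]:
    """Indicator -> role mapping matching :func:`generate`'s output (for CLI configs)."""
    cfg = config or GeneratorConfig()
    roles = {n: t[0] for n, t in cfg.indicator_targets.items() if t[0] != "population"}
    roles["population"] = "population"
    return roles
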