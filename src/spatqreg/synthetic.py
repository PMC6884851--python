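"""Synthetic DHS-like birth-weight data with known ground truth.

The generator emulates the structure of a 2010 Malawi-style survey
extract: ~28 districts arranged on a rook-neighbour grid, maternal
covariates with realistic category frequencies, mother age roughly
uniform over 15-49 and antenatal visits Poisson-like, and a birth
weight built from the additive quantile model the package fits —
intercept + dummy fixed effects + nonlinear age and visit effects +
a spatially correlated district effect + noise.

Two noise modes:

* ``"gaussian"`` — heteroscedastic normal noise whose log scale is
  linear in chosen covariates (wealth by default).  Extreme-quantile
  effects then differ from mean effects, the phenomenon that motivates
  quantile regression: with a zero mean effect the tau = 0.05 and
  tau = 0.95 coefficients of a scale covariate have opposite signs.
* ``"ald"`` — asymmetric Laplace noise at a stated tau, so the linear
  predictor IS the true tau-quantile: the exact calibration target for
  the sampler.

All effect magnitudes are in kilograms; the default residual spread is
about 0.5 kg.  Fixed seeds give bit-identical datasets.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import ald
from .data_model import AdjacencyGraph, DataSchema, Dataset, default_schema
from .gmrf import icar_precision, sample_gmrf

__all__ = [
    "CovariateProfile",
    "SyntheticTruth",
    "gen_adjacency",
    "gen_covariates",
    "simulate_dataset",
    "default_fixed_effects",
    "default_hetero_effects",
]


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------

def _grid_shape(K: int) -> tuple[int, int, int]:
    """Most balanced r x c factorization; prime-ish K is padded."""
    best = None
    for r in range(2, int(math.isqrt(K)) + 1):
        if K % r == 0:
            best = (r, K // r)
    if best is not None:
        return best[0], best[1], K
    r = max(2, round(math.sqrt(K)))
    c = math.ceil(K / r)
    return r, c, r * c


def gen_adjacency(kind: str = "grid", K: int = 28,
                  seed: int | None = None) -> AdjacencyGraph:
    """Connected district graph: ``grid`` (rook neighbours) or ``ring``.

    ``seed`` is accepted for interface symmetry; both layouts are
    deterministic.  A K with no balanced grid factorization is padded
    to the nearest r x c with a warning.
    """
    if K < 2:
        raise ValueError("need at least 2 districts")
    if kind == "ring":
        labels = [f"D{i + 1:02d}" for i in range(K)]
        nbrs = {labels[i]: {labels[(i - 1) % K], labels[(i + 1) % K]}
                for i in range(K)}
        return AdjacencyGraph(nodes=labels, neighbours=nbrs)
    if kind != "grid":
        raise ValueError(f"unknown adjacency kind {kind!r}")
    r, c, K_used = _grid_shape(K)
    if K_used != K:
        warnings.warn(f"no r x c grid with {K} cells; using {r} x {c} = {K_used}")
    labels = [f"D{i + 1:02d}" for i in range(K_used)]
    nbrs: dict[str, set[str]] = {lab: set() for lab in labels}
    for i in range(r):
        for j in range(c):
            k = i * c + j
            for di, dj in ((1, 0), (0, 1)):
                ii, jj = i + di, j + dj
                if ii < r and jj < c:
                    a, b = labels[k], labels[ii * c + jj]
                    nbrs[a].add(b)
                    nbrs[b].add(a)
    return AdjacencyGraph(nodes=labels, neighbours=nbrs)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

@dataclass
class CovariateProfile:
    """Category frequencies of the emulated survey population.

    Defaults are of the magnitude seen in DHS-style extracts: wealth
    quintiles equal at 20%, low smoking prevalence, mostly primary
    education, BMI mostly in the normal band.
    """

    category_probs: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "bmi_class": {"<18.5": 0.09, "18.5-25": 0.72, ">25": 0.19},
        "smoking": {"no": 0.97, "yes": 0.03},
        "birth_order": {"1": 0.25, "2-3": 0.35, "4-5": 0.22, "6+": 0.18},
        "education": {"none": 0.17, "primary": 0.64, "secondary": 0.16,
                      "higher": 0.03},
        "wealth": {"poorest": 0.20, "poor": 0.20, "rich": 0.20,
                   "richer": 0.20, "richest": 0.20},
        "height_class": {"<150": 0.12, ">=150": 0.88},
        "weight_class": {"<45": 0.08, "45-70": 0.85, ">70": 0.07},
    })
    age_range: tuple[int, int] = (15, 49)
    visits_mean: float = 3.5
    visits_max: int = 15
    district_probs: np.ndarray | None = None   # uniform when None

    def __post_init__(self) -> None:
        for name, probs in self.category_probs.items():
            total = sum(probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"probabilities of {name!r} sum to {total}")


def gen_covariates(n: int, K: int, seed: int | np.random.Generator,
                   profile: CovariateProfile | None = None) -> pd.DataFrame:
    """Draw covariate records (no response, no truth).

    Mother age is discrete uniform over the profile's range, antenatal
    visits Poisson(mean) truncated at the profile maximum, categorical
    covariates multinomial, districts multinomial over ``K`` labels.
    """
    if n < 1:
        raise ValueError("n must be positive")
    profile = profile or CovariateProfile()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    df = pd.DataFrame(index=range(n))
    for name, probs in profile.category_probs.items():
        levels = list(probs)
        df[name] = rng.choice(levels, size=n, p=[probs[l] for l in levels])
    lo, hi = profile.age_range
    df["mother_age"] = rng.integers(lo, hi + 1, size=n).astype(float)
    df["antenatal_visits"] = np.minimum(
        rng.poisson(profile.visits_mean, size=n), profile.visits_max
    ).astype(float)
    labels = np.array([f"D{i + 1:02d}" for i in range(K)])
    p = profile.district_probs
    df["district"] = rng.choice(labels, size=n, p=p)
    return df


# ---------------------------------------------------------------------------
# truth and simulation
# ---------------------------------------------------------------------------

def default_fixed_effects() -> dict[str, dict[str, float]]:
    """True per-level coefficients (kg) of the deterministic mechanism.

    Wealth is left at zero on purpose: under heteroscedastic noise its
    influence is purely through the scale, so its extreme-quantile
    effects flip sign between the tails.
    """
    return {
        "bmi_class": {"18.5-25": 0.20, ">25": 0.25},
        "smoking": {"yes": -0.12},
        "birth_order": {"2-3": 0.05, "4-5": 0.08, "6+": 0.10},
        "education": {"primary": 0.05, "secondary": 0.10, "higher": 0.15},
        "wealth": {},
        "height_class": {">=150": 0.20},
        "weight_class": {"45-70": 0.10, ">70": 0.15},
    }


def default_hetero_effects() -> dict[str, dict[str, float]]:
    """Per-level offsets of log residual scale (gaussian mode)."""
    return {"wealth": {"poorest": 0.25, "poor": 0.10, "rich": 0.0,
                       "richer": -0.10, "richest": -0.25}}


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated dataset.

    ``smooth`` tables the centred true nonlinear effects on the observed
    covariate grids; ``spatial`` is the centred true district effect in
    graph node order.  ``quantile(tau, df)`` evaluates the true
    conditional tau-quantile for arbitrary records, monotone in tau.
    """

    intercept: float
    fixed: dict[str, dict[str, float]]
    smooth: dict[str, np.ndarray]
    smooth_grids: dict[str, np.ndarray]
    spatial: np.ndarray
    spatial_labels: list[str]
    noise: str                       # "gaussian" | "ald"
    sigma0: float                    # base residual scale (kg)
    hetero: dict[str, dict[str, float]]
    tau_gen: float | None = None     # ald mode's generating tau

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        out = np.full(len(df), self.intercept)
        for name, effects in self.fixed.items():
            for level, coef in effects.items():
                out += coef * (df[name].to_numpy() == level)
        for name, values in self.smooth.items():
            grid = self.smooth_grids[name]
            x = df[name].to_numpy(dtype=float)
            obs = np.isfinite(x)
            idx = np.searchsorted(grid, x[obs])
            idx = np.clip(idx, 0, len(grid) - 1)
            out[obs] += values[idx]
        lut = {lab: i for i, lab in enumerate(self.spatial_labels)}
        out += self.spatial[[lut[d] for d in df["district"]]]
        return out

    def scale(self, df: pd.DataFrame) -> np.ndarray:
        log_s = np.full(len(df), math.log(self.sigma0))
        for name, effects in self.hetero.items():
            for level, off in effects.items():
                log_s += off * (df[name].to_numpy() == level)
        return np.exp(log_s)

    def quantile(self, tau: float, df: pd.DataFrame) -> np.ndarray:
        """True conditional tau-quantile of birth weight per record."""
        lp = self.linear_predictor(df)
        if self.noise == "gaussian":
            return lp + norm.ppf(tau) * self.scale(df)
        return lp + ald.ald_ppf(tau, 0.0, self.sigma0, self.tau_gen)

    def to_json(self, path) -> None:
        payload = {
            "intercept": self.intercept,
            "fixed": self.fixed,
            "smooth": {k: v.tolist() for k, v in self.smooth.items()},
            "smooth_grids": {k: v.tolist() for k, v in self.smooth_grids.items()},
            "spatial": self.spatial.tolist(),
            "spatial_labels": self.spatial_labels,
            "noise": self.noise,
            "sigma0": self.sigma0,
            "hetero": self.hetero,
            "tau_gen": self.tau_gen,
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _default_sigma_ald(tau: float, target_sd: float = 0.5) -> float:
    """ALD scale giving a residual standard deviation of ``target_sd`` kg."""
    var_unit = (1.0 - 2.0 * tau + 2.0 * tau ** 2) / (tau * (1.0 - tau)) ** 2
    return target_sd / math.sqrt(var_unit)


def _centered_smooth(grid: np.ndarray, fn) -> np.ndarray:
    vals = fn(grid)
    return vals - vals.mean()


def simulate_dataset(n: int, graph: AdjacencyGraph, *,
                     noise: str = "gaussian", tau: float = 0.05,
                     seed: int = 0,
                     profile: CovariateProfile | None = None,
                     schema: DataSchema | None = None,
                     intercept: float = 3.1,
                     fixed_effects: dict[str, dict[str, float]] | None = None,
                     hetero_effects: dict[str, dict[str, float]] | None = None,
                     smooth_amplitude: float = 0.15,
                     delta_spatial: float = 4.0,
                     sigma: float | None = None,
                     missing_rate: float = 0.0,
                     ) -> tuple[Dataset, SyntheticTruth]:
    """Simulate records plus their generating truth.

    ``delta_spatial`` is the ICAR precision of the true district effect
    (4.0 gives district shifts of a few tenths of a kg).  In gaussian
    mode ``sigma`` is the base residual scale (default 0.4 kg before
    heteroscedastic offsets); in ald mode it is the ALD scale (default
    chosen so the residual sd is about 0.5 kg at the stated tau).
    ``missing_rate`` knocks out covariate values at random to exercise
    the missing-data conventions.
    """
    if noise not in ("gaussian", "ald"):
        raise ValueError(f"unknown noise mode {noise!r}")
    schema = schema or default_schema()
    rng = np.random.default_rng(seed)
    df = gen_covariates(n, graph.n, rng, profile)

    fixed = fixed_effects if fixed_effects is not None else default_fixed_effects()
    hetero = (hetero_effects if hetero_effects is not None
              else (default_hetero_effects() if noise == "gaussian" else {}))

    age_grid = np.unique(df["mother_age"].to_numpy(dtype=float))
    vis_grid = np.unique(df["antenatal_visits"].to_numpy(dtype=float))
    a = smooth_amplitude
    smooth = {
        "mother_age": _centered_smooth(
            age_grid, lambda x: a * np.sin(2.0 * np.pi * (x - 15.0) / 34.0)),
        "antenatal_visits": _centered_smooth(
            vis_grid, lambda x: a * (x - 3.5) / 3.5 - a * ((x - 3.5) / 3.5) ** 2 / 4),
    }
    smooth_grids = {"mother_age": age_grid, "antenatal_visits": vis_grid}

    prior = icar_precision(graph)
    spatial = sample_gmrf(prior, delta_spatial, rng)
    spatial = spatial - spatial.mean()

    if noise == "gaussian":
        sigma0 = 0.4 if sigma is None else float(sigma)
    else:
        sigma0 = _default_sigma_ald(tau) if sigma is None else float(sigma)

    truth = SyntheticTruth(
        intercept=float(intercept), fixed=fixed, smooth=smooth,
        smooth_grids=smooth_grids, spatial=spatial,
        spatial_labels=list(graph.nodes), noise=noise, sigma0=sigma0,
        hetero=hetero, tau_gen=(tau if noise == "ald" else None))

    lp = truth.linear_predictor(df)
    if noise == "gaussian":
        eps = rng.standard_normal(n) * truth.scale(df)
    else:
        eps = ald.ald_rvs(rng, 0.0, sigma0, tau, size=n)
    y = lp + eps

    out = pd.DataFrame({schema.response: y})
    category_levels = {}
    for name, levels in schema.categoricals.items():
        out[name] = df[name].to_numpy()
        category_levels[name] = list(levels)
    for name in schema.metricals:
        out[name] = df[name].to_numpy(dtype=float)
    out[schema.district] = df["district"].to_numpy()

    if missing_rate > 0:
        for name in schema.categoricals:
            mask = rng.uniform(size=n) < missing_rate
            if mask.any():
                out.loc[mask, name] = "missing"
                if "missing" not in category_levels[name]:
                    category_levels[name] = category_levels[name] + ["missing"]
        for name in schema.metricals:
            mask = rng.uniform(size=n) < missing_rate
            out.loc[mask, name] = np.nan

    data = Dataset(df=out, schema=schema, category_levels=category_levels)
    return data, truth
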