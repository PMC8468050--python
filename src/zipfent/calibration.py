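"""Calibration of the invertible forward model between distance and M.

The estimator needs a map from the mean coincidence distance D of a
rank-r symbol to the alphabet size M that would produce it.  The map is
built by simulation: for each M on a grid, draw an ensemble of i.i.d.
sequences from the chosen family, measure the mean recurrence distance
of the rank-r symbol, and least-squares fit a parametric forward model
M = G(theta; D) per rank.  Two forms are supported:

* ``power``: M = a * D^b + c, invertible in closed form,
  D = ((M - c)/a)^(1/b).
* ``polynomial``: M = sum_i theta_i D^i, inverted numerically (the
  forward map must be strictly increasing on the calibrated range).

The shipped default calibration uses the polynomial form for the
Zipfian families: over a decade of alphabet sizes the distance-to-M
curve bends away from any single power law (M grows nearly
exponentially in D), and a degree-6 polynomial tracks it to a fraction
of a percent, which the entropy estimates inherit.  The equiprobable
family is exactly linear (D = M + 1) and ships as a power model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, brentq, curve_fit

from .simulate import RNG_ALGORITHM, sample_codes
from .zipf_models import make_family


class CalibrationFitError(RuntimeError):
    """The ensemble cannot support a monotone forward model."""


class ExtrapolationWarning(UserWarning):
    """A prediction was requested outside the calibrated distance range."""


@dataclass(frozen=True)
class SimulationConfig:
    """Ensemble protocol: Nv trials of Ns symbols at each grid M."""

    seed: int = 1
    trials: int = 50
    samples: int = 100_000
    M_grid: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.trials < 1 or self.samples < 2:
            raise ValueError("trials >= 1 and samples >= 2 required")
        if any(m < 2 for m in self.M_grid):
            raise ValueError("all grid alphabet sizes must be >= 2")


def log_grid(lo: float, hi: float, n: int) -> tuple[int, ...]:
    """n log-spaced integer alphabet sizes in [lo, hi], deduplicated."""
    g = np.unique(np.round(np.geomspace(lo, hi, n)).astype(int))
    return tuple(int(m) for m in g)


def simulate_distance_ensemble(
    family: str, config: SimulationConfig, ranks=(1,)
) -> pd.DataFrame:
    """Mean observed distance of each ranked symbol at each grid M.

    Returns a DataFrame with one row per (M, rank): the across-trial
    mean of the per-trial mean distances and its spread.  Ranks are
    assigned *empirically* within each trial, exactly as the estimator
    will assign them on observed data, so the mild selection effect of
    picking the empirically most frequent symbol cancels between
    calibration and estimation.
    """
    from .coincidence import empirical_rank_order

    ranks = sorted(set(int(r) for r in ranks))
    if not config.M_grid:
        raise ValueError("config.M_grid is empty")
    if min(config.M_grid) < max(ranks):
        raise ValueError("every grid M must be >= the largest rank")
    rng = np.random.default_rng(config.seed)
    rows = []
    for M in config.M_grid:
        dist = make_family(family, M)
        trial_means = {r: [] for r in ranks}
        for _ in range(config.trials):
            codes = sample_codes(dist, config.samples, rng)
            order = empirical_rank_order(codes, dist.M_support)
            for r in ranks:
                if r > order.size:
                    raise CalibrationFitError(
                        f"fewer than {r} distinct symbols observed at M={M}"
                    )
                pos = np.flatnonzero(codes == order[r - 1])
                if pos.size < 2:
                    raise CalibrationFitError(
                        f"rank-{r} symbol never repeated within "
                        f"{config.samples} samples at M={M}"
                    )
                trial_means[r].append(float(np.mean(np.diff(pos) + 1)))
        for r in ranks:
            tm = np.asarray(trial_means[r])
            rows.append(
                {
                    "family": family,
                    "M": float(M),
                    "rank": r,
                    "D_mean": tm.mean(),
                    "D_sd": tm.std(ddof=1) if tm.size > 1 else 0.0,
                    "trials": config.trials,
                }
            )
    return pd.DataFrame(rows)


def _fit_power(D: np.ndarray, M: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of M = a D^b + c, log-log initialized, c0 = 0."""
    slope, intercept = np.polyfit(np.log(D), np.log(M), 1)
    p0 = (float(np.exp(intercept)), float(slope), 0.0)

    def model(d, a, b, c):
        return a * np.power(d, b) + c

    with warnings.catch_warnings():
        # noiseless inputs make the covariance singular; only theta is used
        warnings.simplefilter("ignore", OptimizeWarning)
        theta, _ = curve_fit(model, D, M, p0=p0, maxfev=20000)
    return tuple(float(t) for t in theta)


def _fit_polynomial(D: np.ndarray, M: np.ndarray, degree: int) -> tuple[float, ...]:
    """Weighted polynomial fit of M on D (weights 1/M balance relative error)."""
    coeffs = np.polyfit(D, M, deg=degree, w=1.0 / M)
    return tuple(float(c) for c in coeffs[::-1])  # ascending powers


@dataclass
class CalibrationModel:
    """Fitted invertible forward model M = G(theta; D), one theta per rank."""

    dist_family: str
    form: str  # "power" or "polynomial"
    params: dict[int, tuple[float, ...]]
    valid_range: dict[int, tuple[float, float]]
    metadata: dict = field(default_factory=dict)

    # -- forward ---------------------------------------------------------
    def _eval(self, D: float, r: int) -> float:
        theta = self.params[r]
        if self.form == "power":
            a, b, c = theta
            return a * D**b + c
        return float(np.polynomial.polynomial.polyval(D, theta))

    def _eval_slope(self, D: float, r: int) -> float:
        theta = self.params[r]
        if self.form == "power":
            a, b, _ = theta
            return a * b * D ** (b - 1)
        der = np.polynomial.polynomial.polyder(np.asarray(theta))
        return float(np.polynomial.polynomial.polyval(D, der))

    def extrapolates(self, D: float, r: int) -> bool:
        lo, hi = self.valid_range[r]
        return D < lo or D > hi

    def predict_M(self, D: float, r: int = 1, warn: bool = True) -> float:
        """Estimated alphabet size for an observed mean distance.

        Outside the calibrated range the polynomial form is continued
        linearly from the range edge (high-degree polynomials diverge
        when extrapolated); the power form is evaluated as-is.  Either
        way an :class:`ExtrapolationWarning` is emitted.
        """
        if r not in self.params:
            raise KeyError(f"rank {r} not present in calibration")
        if D <= 0:
            raise ValueError("distance must be positive")
        lo, hi = self.valid_range[r]
        if self.extrapolates(D, r):
            if warn:
                warnings.warn(
                    f"D={D:.4g} outside calibrated range [{lo:.4g}, {hi:.4g}] "
                    f"for rank {r}",
                    ExtrapolationWarning,
                    stacklevel=2,
                )
            if self.form == "polynomial":
                edge = lo if D < lo else hi
                return self._eval(edge, r) + self._eval_slope(edge, r) * (D - edge)
        return self._eval(D, r)

    # -- inverse ---------------------------------------------------------
    def predict_D(self, M: float, r: int = 1) -> float:
        """Distance at which the forward model returns M."""
        if r not in self.params:
            raise KeyError(f"rank {r} not present in calibration")
        if self.form == "power":
            a, b, c = self.params[r]
            if M <= c:
                raise ValueError(f"M={M} not above the fitted offset c={c:.4g}")
            return ((M - c) / a) ** (1.0 / b)
        lo, hi = self.valid_range[r]
        f = lambda d: self._eval(d, r) - M
        span = hi - lo
        a_, b_ = lo - 0.25 * span, hi + 0.25 * span
        if f(a_) * f(b_) > 0:
            raise ValueError(
                f"M={M} outside the invertible range of the polynomial model"
            )
        return float(brentq(f, a_, b_, xtol=1e-12))

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "dist_family": self.dist_family,
            "form": self.form,
            "ranks": {
                str(r): {
                    "params": list(self.params[r]),
                    "valid_range": list(self.valid_range[r]),
                }
                for r in sorted(self.params)
            },
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def from_dict(cls, payload: dict) -> "CalibrationModel":
        params = {int(r): tuple(v["params"]) for r, v in payload["ranks"].items()}
        ranges = {
            int(r): tuple(v["valid_range"]) for r, v in payload["ranks"].items()
        }
        return cls(
            dist_family=payload["dist_family"],
            form=payload["form"],
            params=params,
            valid_range=ranges,
            metadata=payload.get("metadata", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def fit_forward_model(
    ensemble: pd.DataFrame, form: str = "power", degree: int = 6
) -> CalibrationModel:
    """Fit the per-rank forward model to a simulated distance ensemble.

    The ensemble must be strictly increasing in D with M for every rank
    (a non-monotone ensemble cannot yield an invertible model and is
    rejected with a diagnostic).
    """
    if form not in {"power", "polynomial"}:
        raise ValueError("form must be 'power' or 'polynomial'")
    families = ensemble["family"].unique()
    if len(families) != 1:
        raise ValueError("ensemble mixes distribution families")
    params: dict[int, tuple[float, ...]] = {}
    ranges: dict[int, tuple[float, float]] = {}
    residuals: dict[str, float] = {}
    for r, grp in ensemble.groupby("rank"):
        grp = grp.sort_values("M")
        D = grp["D_mean"].to_numpy(float)
        M = grp["M"].to_numpy(float)
        if len(D) < 3:
            raise CalibrationFitError(f"rank {r}: need >= 3 grid points")
        if not np.all(np.diff(D) > 0):
            raise CalibrationFitError(
                f"rank {r}: ensemble distances are not strictly increasing "
                f"with M (D = {np.round(D, 4).tolist()})"
            )
        deg = min(degree, len(D) - 2)
        if form == "power":
            theta = _fit_power(D, M)
        else:
            theta = _fit_polynomial(D, M, deg)
        model = CalibrationModel(
            str(families[0]), form, {int(r): theta},
            {int(r): (float(D[0]), float(D[-1]))},
        )
        dense = np.linspace(D[0], D[-1], 256)
        slopes = np.array([model._eval_slope(d, int(r)) for d in dense])
        if np.any(slopes <= 0):
            raise CalibrationFitError(
                f"rank {r}: fitted {form} model is not strictly increasing "
                "on the calibrated range"
            )
        fit_vals = np.array([model._eval(d, int(r)) for d in D])
        residuals[str(int(r))] = float(np.max(np.abs(fit_vals - M) / M))
        params[int(r)] = theta
        ranges[int(r)] = (float(D[0]), float(D[-1]))
    meta = {
        "M_grid": sorted(ensemble["M"].unique().tolist()),
        "trials": int(ensemble["trials"].iloc[0]),
        "rng": RNG_ALGORITHM,
        "max_relative_residual": residuals,
        "ensemble": {
            "M": ensemble["M"].tolist(),
            "rank": ensemble["rank"].tolist(),
            "D_mean": ensemble["D_mean"].tolist(),
            "D_sd": ensemble["D_sd"].tolist(),
        },
    }
    return CalibrationModel(str(families[0]), form, params, ranges, meta)


def calibrate(
    family: str,
    config: SimulationConfig,
    ranks=(1,),
    form: str = "polynomial",
    degree: int = 6,
) -> CalibrationModel:
    """Simulate an ensemble and fit the forward model in one step."""
    ensemble = simulate_distance_ensemble(family, config, ranks)
    model = fit_forward_model(ensemble, form=form, degree=degree)
    model.metadata["samples"] = config.samples
    model.metadata["seed"] = config.seed
    return model


DEFAULT_CALIBRATION_RESOURCE = "default_calibration.json"


@lru_cache(maxsize=None)
def _load_default_bundle() -> dict:
    from importlib.resources import files

    text = (files("zipfent") / "data" / DEFAULT_CALIBRATION_RESOURCE).read_text(
        encoding="utf-8"
    )
    return json.loads(text)


def default_calibration(family: str = "zml") -> CalibrationModel:
    """The calibration model shipped with the package for a family.

    Regenerable with ``zipfent calibrate``; the bundle records the full
    protocol (grid, trials, samples, seed) in its metadata.
    """
    bundle = _load_default_bundle()
    if family not in bundle:
        raise KeyError(
            f"no default calibration for family {family!r}; "
            f"available: {sorted(bundle)}"
        )
    return CalibrationModel.from_dict(bundle[family])
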