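"""Wavelength selection: CARS, UVE, and the CARS->UVE (CU) cascade.

CARS (competitive adaptive reweighted sampling) runs a fixed number of
Monte-Carlo iterations; each iteration fits PLS1 on a row subsample of the
currently retained bands, shrinks the retained set according to an
exponentially decreasing retention schedule (forced top-|coefficient|
truncation followed by adaptive reweighted sampling), and records the
cross-validated RMSECV of the new set. The final selection is the retained
set of the minimum-RMSECV iteration.

UVE (uninformative variable elimination) appends as many tiny-amplitude
white-noise bands as there are real bands, refits PLS over resampled splits,
and keeps real bands whose coefficient stability (mean/sd across splits)
exceeds the largest stability observed among the noise bands.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pls import pls_fit, rmsecv_path

__all__ = ["CarsTrace", "UveResult", "cars_select", "uve_select", "cu_cascade",
           "cars_retention_schedule"]

log = logging.getLogger(__name__)


@dataclass
class CarsTrace:
    """Per-iteration record of a CARS run."""

    n_runs: int
    ratios: np.ndarray              # exponentially decreasing retention ratios
    forced_counts: np.ndarray       # ratio * p, the pre-sampling band budget
    retained: list[np.ndarray]      # retained band indices after each run
    rmsecv: np.ndarray              # cross-validated RMSE of each retained set
    n_components_used: np.ndarray   # RMSECV-minimizing component count per run
    coef_magnitude: list[np.ndarray]  # |PLS coefficients| ranking each run
    best_run: int
    selected: np.ndarray

    def to_jsonable(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "ratios": self.ratios.tolist(),
            "forced_counts": self.forced_counts.tolist(),
            "retained_counts": [int(len(r)) for r in self.retained],
            "rmsecv": self.rmsecv.tolist(),
            "n_components_used": self.n_components_used.tolist(),
            "best_run": int(self.best_run),
            "selected": self.selected.tolist(),
        }


@dataclass
class UveResult:
    """Stability scores and the noise-derived cutoff of a UVE run."""

    stability: np.ndarray        # real bands, length p
    noise_stability: np.ndarray  # appended noise bands, length p
    cutoff: float
    selected: np.ndarray
    n_components: int

    def to_jsonable(self) -> dict:
        return {
            "stability": self.stability.tolist(),
            "noise_stability": self.noise_stability.tolist(),
            "cutoff": self.cutoff,
            "selected": self.selected.tolist(),
            "n_components": self.n_components,
        }


def cars_retention_schedule(p: int, n_runs: int) -> np.ndarray:
    """Exponentially decreasing retention ratios r_i = a * exp(-k * i).

    Constants are fixed so that r_1 = 1 (all p bands kept at the first run)
    and r_N * p = 2 (two bands at the last run):

        k = ln(p/2) / (N - 1),  a = e^k  =>  r_i = (p/2)^((1 - i)/(N - 1))
    """
    if p < 2:
        raise ValueError("schedule needs p >= 2")
    if n_runs < 2:
        raise ValueError("schedule needs n_runs >= 2")
    i = np.arange(1, n_runs + 1, dtype=float)
    return (p / 2.0) ** ((1.0 - i) / (n_runs - 1))


def _best_component_count(X, y, a_max, k_folds, seed):
    path = rmsecv_path(X, y, a_max=a_max, k_folds=k_folds, seed=seed)
    a = int(np.argmin(path)) + 1
    return a, float(path[a - 1])


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    k_folds: int = 10,
    a_max: int = 10,
    subsample_ratio: float = 0.8,
    seed: int = 0,
) -> CarsTrace:
    """Competitive adaptive reweighted sampling. Deterministic given seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("CARS needs at least 2 bands")
    if n_runs < 2:
        raise ValueError("CARS needs at least 2 runs")
    rng = np.random.default_rng(seed)

    ratios = cars_retention_schedule(p, n_runs)
    forced_counts = np.maximum(2, np.rint(ratios * p).astype(int))
    retained = np.arange(p)

    trace_retained: list[np.ndarray] = []
    trace_coef: list[np.ndarray] = []
    trace_rmsecv = np.empty(n_runs)
    trace_a = np.empty(n_runs, dtype=int)

    n_sub = max(2, int(round(subsample_ratio * n)))
    for i in range(n_runs):
        rows = rng.choice(n, size=n_sub, replace=False)
        a_fit = min(a_max, n_sub - 1, len(retained))
        model = pls_fit(X[np.ix_(rows, retained)], y[rows], a_fit)
        coef = np.abs(model.coefficients)
        trace_coef.append(coef)

        forced = min(forced_counts[i], len(retained))
        if forced < len(retained):
            top = retained[np.argsort(coef)[::-1][:forced]]
            top_w = coef[np.argsort(coef)[::-1][:forced]]
            # adaptive reweighted sampling: weighted draw with replacement,
            # keep bands picked at least once
            if top_w.sum() > 0:
                probs = top_w / top_w.sum()
                picked = np.unique(rng.choice(top, size=forced, replace=True, p=probs))
            else:
                picked = top
            if len(picked) < 2:
                log.debug("run %d: retained set clamped at 2 bands", i + 1)
                picked = top[:2]
            retained = np.sort(picked)
        # forced >= current size: ratio keeps everything, no shrink

        a_cv = min(a_max, len(retained))
        a_best, cv = _best_component_count(X[:, retained], y, a_cv, k_folds, seed)
        trace_retained.append(retained.copy())
        trace_rmsecv[i] = cv
        trace_a[i] = a_best

    best_run = int(np.argmin(trace_rmsecv))
    return CarsTrace(
        n_runs=n_runs,
        ratios=ratios,
        forced_counts=forced_counts,
        retained=trace_retained,
        rmsecv=trace_rmsecv,
        n_components_used=trace_a,
        coef_magnitude=trace_coef,
        best_run=best_run,
        selected=trace_retained[best_run].copy(),
    )


def uve_select(
    X: np.ndarray,
    y: np.ndarray,
    a_max: int = 10,
    n_splits: int | None = None,
    cutoff_factor: float = 1.0,
    noise_scale: float = 1e-10,
    seed: int = 0,
) -> UveResult:
    """Uninformative variable elimination. Deterministic given seed.

    Appends p standard-normal noise bands scaled to ``noise_scale`` times the
    data scale (coefficient stability is scale-invariant, so tiny noise probes
    chance-level stability without perturbing predictions), refits PLS1 over
    leave-one-out splits (n <= 200) or repeated 5-fold splits otherwise, and
    keeps real bands with |stability| above ``cutoff_factor`` times the largest
    noise-band |stability|.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)

    scale = np.abs(X).max()
    noise = rng.standard_normal((n, p)) * (noise_scale * (scale if scale > 0 else 1.0))
    Xa = np.hstack([X, noise])

    a_star, _ = _best_component_count(X, y, min(a_max, p, n - 2), k_folds=min(5, n), seed=seed)

    if n_splits is None:
        splits: list[np.ndarray] = []
        if n <= 200:
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                splits.append(np.flatnonzero(mask))
        else:
            for rep in range(10):
                perm = rng.permutation(n)
                for block in np.array_split(perm, 5):
                    mask = np.ones(n, dtype=bool)
                    mask[block] = False
                    splits.append(np.flatnonzero(mask))
    else:
        if not 2 <= n_splits <= n:
            raise ValueError(f"n_splits must be in [2, {n}]")
        perm = rng.permutation(n)
        splits = []
        for block in np.array_split(perm, n_splits):
            mask = np.ones(n, dtype=bool)
            mask[block] = False
            splits.append(np.flatnonzero(mask))

    coefs = np.empty((len(splits), 2 * p))
    for s_i, rows in enumerate(splits):
        a_fit = min(a_star, len(rows) - 1)
        m = pls_fit(Xa[rows], y[rows], a_fit)
        coefs[s_i] = m.coefficients

    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stab = mean / sd
    zero_sd = sd == 0
    if np.any(zero_sd):
        warnings.warn(
            f"{int(zero_sd.sum())} band(s) had zero coefficient spread across splits; "
            "stability set to signed infinity (always retained)"
        )
        stab[zero_sd] = np.sign(mean[zero_sd]) * np.inf
        stab[zero_sd & (mean == 0)] = 0.0

    stability, noise_stability = stab[:p], stab[p:]
    finite_noise = noise_stability[np.isfinite(noise_stability)]
    cutoff = float(cutoff_factor * (np.abs(finite_noise).max() if len(finite_noise) else 0.0))
    selected = np.flatnonzero(np.abs(stability) > cutoff)
    return UveResult(
        stability=stability,
        noise_stability=noise_stability,
        cutoff=cutoff,
        selected=selected,
        n_components=a_star,
    )


def cu_cascade(
    X: np.ndarray,
    y: np.ndarray,
    cars_params: dict | None = None,
    uve_params: dict | None = None,
) -> tuple[np.ndarray, CarsTrace, UveResult]:
    """CARS then UVE on the CARS-selected columns only.

    Returns the final band indices in original coordinates plus both stage
    traces; the final set is a subset of the CARS selection by construction.
    """
    cars_params = dict(cars_params or {})
    uve_params = dict(uve_params or {})
    trace = cars_select(X, y, **cars_params)
    uve = uve_select(X[:, trace.selected], y, **uve_params)
    final = trace.selected[uve.selected]
    return np.sort(final), trace, uve
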