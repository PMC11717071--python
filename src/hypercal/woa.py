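"""Whale Optimization Algorithm (WOA) and the network hyperparameter harness.

WOA is a swarm minimizer over a bounded box. Each iteration every whale
draws p ~ U[0,1] and l ~ U[-1,1] and moves by one of three rules relative to
the best position found so far, X*:

* encircling (p < 0.5, |A| < 1):   X <- X* - A * |C*X* - X|
* random search (p < 0.5, |A| >= 1): X <- X_rand - A * |C*X_rand - X|
* logarithmic spiral (p >= 0.5):   X <- |X* - X| * e^(b l) * cos(2 pi l) + X*

with A = 2a*r1 - a, C = 2*r2 (r1, r2 uniform per dimension) and the
convergence factor a decreasing linearly from 2 to 0 over the run. Positions
are clamped to the box after every move; the best-so-far is elitist.

The tuning harness decodes whale positions into network hyperparameter
configurations (integer dimensions rounded half-up, the learning rate moved
on a log10 scale), trains the regressor, and returns the validation MSE as
the fitness.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .network import BiLSTMAttention, NetConfig

__all__ = [
    "Dimension",
    "SearchSpace",
    "WoaResult",
    "woa_minimize",
    "a_schedule",
    "encircle_update",
    "spiral_update",
    "default_search_space",
    "tune_network",
    "TuneResult",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    integer: bool = False
    log10: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"dimension '{self.name}': low must be < high")
        if self.log10 and self.low <= 0:
            raise ValueError(f"dimension '{self.name}': log10 scale needs positive bounds")


@dataclass(frozen=True)
class SearchSpace:
    """Bounded, possibly mixed-integer search box.

    Whale motion happens in internal coordinates (log10 for log-scaled
    dimensions); :meth:`decode` maps a position to named parameter values,
    rounding integer dimensions half-up and clamping to the bounds.
    """

    dims: tuple[Dimension, ...]

    @property
    def d(self) -> int:
        return len(self.dims)

    def internal_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([np.log10(d.low) if d.log10 else d.low for d in self.dims])
        hi = np.array([np.log10(d.high) if d.log10 else d.high for d in self.dims])
        return lo, hi

    def decode(self, position: np.ndarray) -> dict[str, float | int]:
        out: dict[str, float | int] = {}
        for x, dim in zip(position, self.dims):
            v = 10.0**x if dim.log10 else float(x)
            if dim.integer:
                v = int(np.floor(v + 0.5))  # round half up
                v = int(min(max(v, dim.low), dim.high))
            else:
                v = float(min(max(v, dim.low), dim.high))
            out[dim.name] = v
        return out


@dataclass
class WoaResult:
    best_position: np.ndarray
    best_fitness: float
    best_curve: np.ndarray            # best-so-far after init and each iteration
    n_evaluations: int
    trail: list[dict] = field(default_factory=list)  # every (iteration, whale, position, fitness)


def a_schedule(t: int, max_iterations: int) -> float:
    """Convergence factor: linear from a(0) = 2 down to a(T) = 0."""
    return 2.0 * (1.0 - t / max_iterations)


def encircle_update(x: np.ndarray, target: np.ndarray, A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Encircling/search move toward a target position (X* or X_rand)."""
    D = np.abs(C * target - x)
    return target - A * D


def spiral_update(x: np.ndarray, best: np.ndarray, b: float, l: float) -> np.ndarray:
    """Bubble-net spiral move; at l = 0 this returns X* + |X* - X| exactly."""
    Dp = np.abs(best - x)
    return Dp * np.exp(b * l) * np.cos(2.0 * np.pi * l) + best


def woa_minimize(
    fitness_fn,
    space: SearchSpace,
    n_whales: int = 10,
    max_iterations: int = 10,
    seed: int = 0,
    spiral_b: float = 1.0,
    init_positions: np.ndarray | None = None,
) -> WoaResult:
    """Minimize ``fitness_fn(position)`` over the search box.

    ``fitness_fn`` receives a position in internal coordinates. NaN fitness is
    treated as +inf with a warning. ``init_positions`` may pin the first rows
    of the initial swarm (warm starts). Deterministic given seed.
    """
    if n_whales < 2:
        raise ValueError("n_whales must be >= 2")
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = space.internal_bounds()
    d = space.d

    pos = rng.uniform(lo, hi, size=(n_whales, d))
    if init_positions is not None:
        init_positions = np.atleast_2d(np.asarray(init_positions, dtype=float))
        k = min(len(init_positions), n_whales)
        pos[:k] = np.clip(init_positions[:k], lo, hi)

    def evaluate(x, it, w):
        f = float(fitness_fn(x))
        if np.isnan(f):
            warnings.warn("fitness returned NaN; treated as +inf")
            f = np.inf
        trail.append({"iteration": it, "whale": w, "position": x.tolist(), "fitness": f})
        return f

    trail: list[dict] = []
    fitness = np.array([evaluate(pos[w], 0, w) for w in range(n_whales)])
    best_i = int(np.argmin(fitness))
    best_pos = pos[best_i].copy()
    best_fit = float(fitness[best_i])
    curve = [best_fit]

    for t in range(max_iterations):
        a = a_schedule(t, max_iterations)
        for w in range(n_whales):
            r1 = rng.random(d)
            r2 = rng.random(d)
            A = 2.0 * a * r1 - a
            C = 2.0 * r2
            p = rng.random()
            l = rng.uniform(-1.0, 1.0)
            if p < 0.5:
                if np.linalg.norm(A) < 1.0:
                    new = encircle_update(pos[w], best_pos, A, C)
                else:
                    x_rand = pos[rng.integers(n_whales)]
                    new = encircle_update(pos[w], x_rand, A, C)
            else:
                new = spiral_update(pos[w], best_pos, spiral_b, l)
            pos[w] = np.clip(new, lo, hi)
            fitness[w] = evaluate(pos[w], t + 1, w)
            if fitness[w] < best_fit:
                best_fit = float(fitness[w])
                best_pos = pos[w].copy()
        curve.append(best_fit)

    return WoaResult(
        best_position=best_pos,
        best_fitness=best_fit,
        best_curve=np.asarray(curve),
        n_evaluations=len(trail),
        trail=trail,
    )


# -- network hyperparameter search --------------------------------------------


def default_search_space(include_attention: bool = True) -> SearchSpace:
    """Hyperparameter box for the BiLSTM-Attention regressor.

    Epochs/batch/hidden/dense bounds follow the published search settings;
    the learning rate moves on a log10 scale over [1e-3, 1e-1] (the linear
    [0.01, 0.1] box cannot contain learning rates below 0.01, yet smaller
    values are routinely optimal); the attention width, which has no stated
    bound, searches [1, 50] and can be dropped for attention-free models.
    """
    dims = [
        Dimension("lr", 1e-3, 1e-1, log10=True),
        Dimension("num_epochs", 10, 100, integer=True),
        Dimension("batch_size", 16, 128, integer=True),
        Dimension("hidden1", 1, 20, integer=True),
        Dimension("hidden2", 1, 20, integer=True),
        Dimension("dense", 1, 100, integer=True),
    ]
    if include_attention:
        dims.append(Dimension("attn_dim", 1, 50, integer=True))
    return SearchSpace(tuple(dims))


#: Untuned BiLSTM-Attention reference configuration (published comparison row).
DEFAULT_ATTENTION_CONFIG = NetConfig(
    lr=0.01, num_epochs=30, batch_size=16, hidden1=10, hidden2=10,
    dense=20, attn_dim=20,
)


@dataclass
class TuneResult:
    best_config: NetConfig
    best_fitness: float
    woa: WoaResult
    audit: list[dict]  # every evaluated configuration with its fitness


def _encode_config(cfg: NetConfig, space: SearchSpace) -> np.ndarray:
    vals = []
    for dim in space.dims:
        v = float(getattr(cfg, dim.name))
        v = min(max(v, dim.low), dim.high)
        vals.append(np.log10(v) if dim.log10 else v)
    return np.asarray(vals)


def tune_network(
    space: SearchSpace,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_whales: int = 10,
    max_iterations: int = 10,
    seed: int = 0,
    base_config: NetConfig | None = None,
    warm_start: bool = True,
) -> TuneResult:
    """WOA search over network hyperparameters; fitness = validation MSE.

    Every candidate trains from the same parameter-initialization seed
    (derived from ``seed``) so fitness differences reflect hyperparameters,
    not initialization luck. With ``warm_start`` the first whale starts at
    ``base_config`` so the search can only improve on the untuned reference.
    Candidates that diverge score +inf and the search continues.
    """
    base = base_config or DEFAULT_ATTENTION_CONFIG
    net_seed = int(np.random.default_rng(seed).integers(2**31 - 1))
    seq_len = X_train.shape[1]
    audit: list[dict] = []

    def fitness(position: np.ndarray) -> float:
        params = space.decode(position)
        cfg = replace(base, seed=net_seed, **params)
        try:
            model = BiLSTMAttention(cfg, seq_len)
            model.fit(X_train, y_train, track_history=False)
            f = model.validation_mse(X_val, y_val)
        except FloatingPointError as exc:
            log.warning("candidate diverged (%s); fitness set to +inf", exc)
            f = np.inf
        audit.append({"config": params, "fitness": f})
        return f

    init = _encode_config(replace(base, seed=net_seed), space)[None, :] if warm_start else None
    result = woa_minimize(
        fitness, space, n_whales=n_whales, max_iterations=max_iterations,
        seed=seed, init_positions=init,
    )
    best_cfg = replace(base, seed=net_seed, **space.decode(result.best_position))
    return TuneResult(
        best_config=best_cfg,
        best_fitness=result.best_fitness,
        woa=result,
        audit=audit,
    )
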