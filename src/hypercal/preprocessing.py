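"""Reflectance correction and spectral preprocessing operators.

Implements the dark/white reference correction

    I_c = (I_r - I_b) / (I_w - I_b)

and the six preprocessing operators used in near-infrared chemometrics —
mean centering (MC), standardization (SS), min-max scaling (MMS),
Savitzky-Golay smoothing (SG), and first/second derivatives (D1/D2) —
composable into ordered chains. Column statistics (means, sds, min/max)
are learned from the calibration matrix only and reused on test spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["black_white_correct", "PreprocessChain", "Step", "KNOWN_OPS"]

KNOWN_OPS = ("MC", "SS", "MMS", "SG", "D1", "D2")


def black_white_correct(raw, dark, white) -> np.ndarray:
    """Dark/white reference correction, elementwise (raw - dark)/(white - dark).

    ``dark`` and ``white`` may be single reference rows broadcast across a 2-D
    ``raw`` matrix. A zero denominator anywhere raises, listing the offending
    band indices — values are never silently clipped.
    """
    raw = np.asarray(raw, dtype=float)
    dark = np.broadcast_to(np.asarray(dark, dtype=float), raw.shape)
    white = np.broadcast_to(np.asarray(white, dtype=float), raw.shape)
    denom = white - dark
    if np.any(denom == 0):
        bands = np.unique(np.argwhere(np.atleast_2d(denom) == 0)[:, -1])
        raise ZeroDivisionError(
            f"white - dark is zero at band indices {bands.tolist()}"
        )
    return (raw - dark) / denom


@dataclass
class Step:
    """One preprocessing operator with its parameters and fitted statistics."""

    op: str
    window: int = 11       # SG/D1/D2: filter window length (odd, >= 3)
    order: int = 2         # SG/D1/D2: polynomial order (< window)
    mode: str = "sg"       # D1/D2: 'sg' (Savitzky-Golay derivative) or 'diff'
    state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.op = self.op.upper().replace("-", "").replace("_", "")
        aliases = {"SAVGOL": "SG", "1STDER": "D1", "2NDDER": "D2"}
        self.op = aliases.get(self.op, self.op)
        if self.op not in KNOWN_OPS:
            raise ValueError(f"unknown preprocessing op '{self.op}'; known: {KNOWN_OPS}")
        if self.op in ("SG", "D1", "D2"):
            if self.window < 3 or self.window % 2 == 0:
                raise ValueError(f"{self.op}: window must be odd and >= 3, got {self.window}")
            if not 0 <= self.order < self.window:
                raise ValueError(f"{self.op}: polynomial order must be < window")
            if self.op in ("D1", "D2") and self.mode not in ("sg", "diff"):
                raise ValueError(f"{self.op}: mode must be 'sg' or 'diff'")

    # -- fitting ----------------------------------------------------------

    def fit(self, X: np.ndarray) -> None:
        if self.op == "MC":
            self.state = {"mean": X.mean(axis=0)}
        elif self.op == "SS":
            sd = X.std(axis=0)
            self._check_nonconstant(sd, "SS")
            self.state = {"mean": X.mean(axis=0), "sd": sd}
        elif self.op == "MMS":
            lo, hi = X.min(axis=0), X.max(axis=0)
            self._check_nonconstant(hi - lo, "MMS")
            self.state = {"min": lo, "range": hi - lo}
        else:  # SG/D1/D2 are stateless filters
            self.state = {"stateless": True}

    @staticmethod
    def _check_nonconstant(scale: np.ndarray, op: str) -> None:
        if np.any(scale == 0):
            bands = np.flatnonzero(scale == 0)
            raise ValueError(
                f"{op}: constant column(s) at band indices {bands.tolist()} "
                "(zero scale, division impossible)"
            )

    @property
    def fitted(self) -> bool:
        return bool(self.state)

    # -- application ------------------------------------------------------

    def apply(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError(f"step {self.op} applied before fitting")
        if self.op == "MC":
            return X - self.state["mean"]
        if self.op == "SS":
            return (X - self.state["mean"]) / self.state["sd"]
        if self.op == "MMS":
            return (X - self.state["min"]) / self.state["range"]
        if self.op == "SG":
            return savgol_filter(X, self.window, self.order, axis=1)
        deriv = 1 if self.op == "D1" else 2
        if self.mode == "sg":
            return savgol_filter(X, self.window, self.order, deriv=deriv, axis=1)
        return np.diff(X, n=deriv, axis=1)  # shrinks band count by `deriv`

    def expected_cols_after(self, p: int) -> int:
        if self.op in ("D1", "D2") and self.mode == "diff":
            return p - (1 if self.op == "D1" else 2)
        return p

    def to_config(self) -> dict:
        cfg: dict[str, Any] = {"op": self.op}
        if self.op in ("SG", "D1", "D2"):
            cfg.update(window=self.window, order=self.order)
            if self.op != "SG":
                cfg["mode"] = self.mode
        return cfg

    def state_to_jsonable(self) -> dict:
        return {k: (v if isinstance(v, bool) else np.asarray(v).tolist())
                for k, v in self.state.items()}

    def state_from_jsonable(self, state: dict) -> None:
        self.state = {k: (v if isinstance(v, bool) else np.asarray(v, dtype=float))
                      for k, v in state.items()}


class PreprocessChain:
    """Ordered chain of preprocessing steps, fitted once on calibration data.

    ``fit`` learns each step's statistics sequentially (each step sees the
    output of the previous ones, matching how the chain is later applied);
    ``apply`` replays the steps in order, reusing the fitted statistics — test
    spectra are never refit.
    """

    def __init__(self, steps: list[Step]):
        self.steps = steps
        self._fit_cols: int | None = None

    @classmethod
    def from_config(cls, config: list[dict | str]) -> "PreprocessChain":
        steps = []
        for entry in config:
            if isinstance(entry, str):
                steps.append(Step(op=entry))
            else:
                steps.append(Step(**entry))
        return cls(steps)

    def to_config(self) -> list[dict]:
        return [s.to_config() for s in self.steps]

    @property
    def fitted(self) -> bool:
        return self._fit_cols is not None and all(s.fitted for s in self.steps)

    def fit(self, X: np.ndarray) -> "PreprocessChain":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 2 and any(s.op in ("MC", "SS", "MMS") for s in self.steps):
            raise ValueError("fitting MC/SS/MMS statistics needs at least 2 rows")
        self._fit_cols = X.shape[1]
        for step in self.steps:
            step.fit(X)
            X = step.apply(X)
        return self

    def apply(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("chain applied before fitting")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self._fit_cols:
            raise ValueError(
                f"band count {X.shape[1]} does not match fitted chain ({self._fit_cols})"
            )
        for step in self.steps:
            X = step.apply(X)
        return X

    def fit_apply(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).apply(X)

    def output_cols(self) -> int:
        if self._fit_cols is None:
            raise RuntimeError("chain not fitted")
        p = self._fit_cols
        for step in self.steps:
            p = step.expected_cols_after(p)
        return p

    # -- serialization (text artifacts for the CLI) -----------------------

    def to_jsonable(self) -> dict:
        return {
            "steps": self.to_config(),
            "states": [s.state_to_jsonable() for s in self.steps],
            "fit_cols": self._fit_cols,
        }

    @classmethod
    def from_jsonable(cls, payload: dict) -> "PreprocessChain":
        chain = cls.from_config(payload["steps"])
        for step, state in zip(chain.steps, payload["states"]):
            step.state_from_jsonable(state)
        chain._fit_cols = payload["fit_cols"]
        return chain
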