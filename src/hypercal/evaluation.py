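"""Calibration metrics, classical baselines, and model-comparison reports.

Metrics follow standard chemometric usage: RC²/RMSEC on the calibration
(training) set, RP²/RMSEP on the prediction (test) set, and RPD. RPD is
computed as 1/sqrt(1 - RP²), which at full precision is identical to
sd(y_test)/RMSEP when R² comes from the same predictions (the printed-table
convention); recomputing it from rounded printed R² values differs in the
third decimal, so reports carry a scale tag and four significant figures.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.svm import SVR

__all__ = [
    "rmse",
    "r_squared",
    "rpd",
    "percent_change",
    "MetricsReport",
    "evaluate_predictions",
    "fit_baselines",
    "compare_report",
    "render_report_table",
]


def rmse(y, yhat) -> float:
    """Root mean squared error sqrt(sum((y - yhat)^2)/n)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(y) == 0 or len(y) != len(yhat):
        raise ValueError(f"length mismatch or empty: {len(y)} vs {len(yhat)}")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SSE/SST (can be negative, never > 1)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(y) < 2 or len(y) != len(yhat):
        raise ValueError("r_squared needs two equal-length vectors of length >= 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("y is constant; R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def rpd(rp2: float) -> float:
    """Relative percent deviation 1/sqrt(1 - RP²); requires RP² < 1."""
    if rp2 >= 1.0:
        raise ValueError(f"RPD undefined for R^2 >= 1 (got {rp2})")
    return float(1.0 / np.sqrt(1.0 - rp2))


def percent_change(reference: float, value: float, direction: str = "increase") -> float:
    """Percent change of ``value`` relative to ``reference``.

    ``increase``: (value - reference)/reference * 100;
    ``decrease``: (reference - value)/reference * 100.
    """
    if reference == 0:
        raise ZeroDivisionError("percent change needs a nonzero reference")
    if direction == "increase":
        return (value - reference) / reference * 100.0
    if direction == "decrease":
        return (reference - value) / reference * 100.0
    raise ValueError("direction must be 'increase' or 'decrease'")


@dataclass
class MetricsReport:
    """Calibration/prediction metric quadruple plus RPD for one model."""

    model: str
    rc2: float
    rmsec: float
    rp2: float
    rmsep: float
    rpd: float
    scale: str = "g/100g"   # or "standardized"
    n_train: int = 0
    n_test: int = 0

    def to_jsonable(self) -> dict:
        return asdict(self)


def evaluate_predictions(
    model: str,
    y_train, yhat_train, y_test, yhat_test,
    scale: str = "g/100g",
) -> MetricsReport:
    rp2 = r_squared(y_test, yhat_test)
    return MetricsReport(
        model=model,
        rc2=r_squared(y_train, yhat_train),
        rmsec=rmse(y_train, yhat_train),
        rp2=rp2,
        rmsep=rmse(y_test, yhat_test),
        rpd=rpd(rp2) if rp2 < 1.0 else float("inf"),
        scale=scale,
        n_train=len(np.asarray(y_train).ravel()),
        n_test=len(np.asarray(y_test).ravel()),
    )


def fit_baselines(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    which: tuple[str, ...] = ("PLSR", "PCA-PLSR", "SVR"),
    scale: str = "g/100g",
) -> list[MetricsReport]:
    """Classical baselines with their published comparison settings.

    PLSR: 3 latent components; PCA-PLSR: PCA to 2 scores feeding a PLSR
    (components capped by the score dimension, max_iter 10); SVR: RBF kernel
    with library defaults. Delegates the fits to scikit-learn.
    """
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    y_train = np.asarray(y_train, float).ravel()
    y_test = np.asarray(y_test, float).ravel()
    reports = []
    for name in which:
        if name == "PLSR":
            m = PLSRegression(n_components=min(3, X_train.shape[1]), scale=False)
            m.fit(X_train, y_train)
            tr, te = m.predict(X_train).ravel(), m.predict(X_test).ravel()
        elif name == "PCA-PLSR":
            pca = PCA(n_components=min(2, X_train.shape[1]))
            Ztr = pca.fit_transform(X_train)
            Zte = pca.transform(X_test)
            m = PLSRegression(n_components=min(10, Ztr.shape[1]), scale=False, max_iter=10)
            m.fit(Ztr, y_train)
            tr, te = m.predict(Ztr).ravel(), m.predict(Zte).ravel()
        elif name == "SVR":
            m = SVR(kernel="rbf")
            m.fit(X_train, y_train)
            tr, te = m.predict(X_train), m.predict(X_test)
        else:
            raise ValueError(f"unknown baseline '{name}'")
        reports.append(
            evaluate_predictions(name, y_train, tr, y_test, te, scale=scale)
        )
    return reports


def compare_report(
    reports: list[MetricsReport],
    pairs: list[tuple[str, str, str, str]],
) -> list[dict]:
    """Pairwise percent-change rows.

    Each pair is ``(reference_model, candidate_model, metric, direction)``
    with metric one of rc2/rmsec/rp2/rmsep/rpd.
    """
    byname = {r.model: r for r in reports}
    rows = []
    for ref_name, cand_name, metric, direction in pairs:
        for name in (ref_name, cand_name):
            if name not in byname:
                raise KeyError(f"unknown model '{name}' in comparison pairs")
        ref = getattr(byname[ref_name], metric)
        cand = getattr(byname[cand_name], metric)
        rows.append({
            "reference": ref_name,
            "candidate": cand_name,
            "metric": metric,
            "direction": direction,
            "reference_value": ref,
            "candidate_value": cand,
            "percent_change": percent_change(ref, cand, direction),
        })
    return rows


def _sig4(x: float) -> str:
    return f"{x:.4g}"


def render_report_table(reports: list[MetricsReport], comparisons: list[dict] | None = None) -> str:
    """Aligned text table in the conventional calibration-report layout."""
    header = f"{'Model':<28} {'RC2':>8} {'RMSEC':>8} {'RP2':>8} {'RMSEP':>8} {'RPD':>8}  scale"
    lines = [header, "-" * len(header)]
    for r in reports:
        lines.append(
            f"{r.model:<28} {_sig4(r.rc2):>8} {_sig4(r.rmsec):>8} "
            f"{_sig4(r.rp2):>8} {_sig4(r.rmsep):>8} {_sig4(r.rpd):>8}  {r.scale}"
        )
    if comparisons:
        lines.append("")
        lines.append(f"{'Comparison':<40} {'metric':>8} {'change %':>10}")
        lines.append("-" * 60)
        for c in comparisons:
            label = f"{c['candidate']} vs {c['reference']} ({c['direction']})"
            lines.append(f"{label:<40} {c['metric']:>8} {c['percent_change']:>10.3g}")
    return "\n".join(lines)
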