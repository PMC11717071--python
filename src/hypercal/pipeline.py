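"""Config-driven pipeline: generate/load -> split -> preprocess -> select ->
tune/train -> evaluate, with reproducibility metadata.

Every run directory receives text artifacts (dataset, fitted chain, selected
wavelengths, tuning audit, metrics, report) plus a MANIFEST recording the
config hash and all derived seeds, so re-running an identical config
reproduces the deterministic stages bit-for-bit.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import yaml

from . import datasets as ds_mod
from .datasets import SpectralDataset, SyntheticSpec, generate_synthetic, read_spectra, train_test_split, write_spectra
from .evaluation import MetricsReport, compare_report, evaluate_predictions, fit_baselines, render_report_table
from .network import BiLSTMAttention, NetConfig
from .preprocessing import PreprocessChain
from .selection import cars_select, cu_cascade, uve_select
from .woa import SearchSpace, Dimension, default_search_space, tune_network

__all__ = ["load_config", "default_config", "config_hash", "derive_seeds", "run_pipeline",
           "StageError", "build_net_config", "ConfigError"]

log = logging.getLogger("hypercal")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed."""


_MODEL_KINDS = ("lstm", "bilstm", "bilstm_attention")


def default_config() -> dict:
    """Run configuration with every published setting as the default."""
    return {
        "seed": 0,
        "data": {"synthetic": {}},
        "split": {"ratio": 0.7, "stratify": True},
        "preprocess": [{"op": "MC"}],
        "selection": {
            "method": "CU",
            "cars": {"n_runs": 50, "k_folds": 10, "a_max": 10, "subsample_ratio": 0.8},
            "uve": {"a_max": 10, "cutoff_factor": 1.0},
        },
        "model": {
            "kind": "bilstm_attention",
            "tune": False,
            "val_fraction": 0.2,
            "woa": {"n_whales": 10, "max_iterations": 10},
            "config": {},
        },
        "baselines": [],
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        user = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    cfg = _merge(default_config(), user)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    data = cfg.get("data", {})
    if ("synthetic" in data) == ("path" in data):
        raise ConfigError("data: exactly one of 'synthetic' or 'path' must be given")
    if not 0 < cfg["split"]["ratio"] < 1:
        raise ConfigError("split.ratio must be in (0, 1)")
    method = cfg["selection"]["method"]
    if method not in ("CARS", "UVE", "CU", "none"):
        raise ConfigError(f"selection.method must be CARS/UVE/CU/none, got {method!r}")
    kind = cfg["model"]["kind"]
    if kind not in _MODEL_KINDS:
        raise ConfigError(f"model.kind must be one of {_MODEL_KINDS}, got {kind!r}")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


_SEED_NAMES = ("split", "cars", "uve", "net", "tune", "val_split")


def derive_seeds(seed: int) -> dict[str, int]:
    """Named per-stage seeds, all derived from one master seed."""
    rng = np.random.default_rng(seed)
    return {name: int(rng.integers(2**31 - 1)) for name in _SEED_NAMES}


def build_net_config(kind: str, overrides: dict, seed: int) -> NetConfig:
    """Model-kind defaults mirror the published comparison rows."""
    if kind == "lstm":
        base = dict(lr=0.01, num_epochs=20, batch_size=16, hidden1=10, hidden2=10,
                    dense=12, bidirectional=False, attention=False)
    elif kind == "bilstm":
        base = dict(lr=0.01, num_epochs=20, batch_size=16, hidden1=10, hidden2=10,
                    dense=12, bidirectional=True, attention=False)
    else:
        base = dict(lr=0.01, num_epochs=30, batch_size=16, hidden1=10, hidden2=10,
                    dense=20, attn_dim=20, bidirectional=True, attention=True)
    base.update(overrides or {})
    base["seed"] = seed
    return NetConfig(**base)


# -- stages -------------------------------------------------------------------


def stage_data(cfg: dict, seed: int) -> SpectralDataset:
    data = cfg["data"]
    if "path" in data:
        p = Path(data["path"])
        if not p.exists():
            raise StageError(f"expected spectra file not found: {p}")
        return read_spectra(p)
    spec_kwargs = dict(data["synthetic"] or {})
    spec_kwargs.setdefault("seed", seed)
    return generate_synthetic(SyntheticSpec(**spec_kwargs))


def stage_select(X: np.ndarray, y: np.ndarray, cfg: dict, seeds: dict) -> tuple[np.ndarray, dict]:
    sel = cfg["selection"]
    method = sel["method"]
    if method == "none":
        return np.arange(X.shape[1]), {"method": "none"}
    cars_params = dict(sel.get("cars") or {})
    uve_params = dict(sel.get("uve") or {})
    cars_params.setdefault("seed", seeds["cars"])
    uve_params.setdefault("seed", seeds["uve"])
    if method == "CARS":
        trace = cars_select(X, y, **cars_params)
        return trace.selected, {"method": "CARS", "cars": trace.to_jsonable()}
    if method == "UVE":
        res = uve_select(X, y, **uve_params)
        return res.selected, {"method": "UVE", "uve": res.to_jsonable()}
    final, trace, uve = cu_cascade(X, y, cars_params, uve_params)
    return final, {"method": "CU", "cars": trace.to_jsonable(), "uve": uve.to_jsonable()}


def _holdout_split(n: int, frac: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = max(1, int(round(frac * n)))
    return np.sort(perm[k:]), np.sort(perm[:k])


def run_pipeline(cfg: dict, outdir) -> dict:
    """Execute all stages; write artifacts; return the metrics payload."""
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(cfg["seed"])
    manifest: dict = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seeds": seeds,
        "stages": {},
        "artifacts": [],
    }

    def _mark(stage: str, t0: float) -> None:
        manifest["stages"][stage] = {"wall_s": round(time.perf_counter() - t0, 3)}
        log.info("stage=%s seed=%s wall=%.2fs", stage, cfg["seed"], time.perf_counter() - t0)

    def _artifact(path: Path) -> None:
        manifest["artifacts"].append(str(path.relative_to(outdir)))

    try:
        # data
        t0 = time.perf_counter()
        ds = stage_data(cfg, cfg["seed"])
        write_spectra(ds, outdir / "dataset.csv")
        _artifact(outdir / "dataset.csv")
        _mark("data", t0)

        # split
        t0 = time.perf_counter()
        train, test = train_test_split(
            ds, ratio=cfg["split"]["ratio"], seed=seeds["split"],
            stratify=cfg["split"]["stratify"],
        )
        (outdir / "split.json").write_text(json.dumps(
            {"train_ids": train.ids.tolist(), "test_ids": test.ids.tolist()}, indent=2))
        _artifact(outdir / "split.json")
        _mark("split", t0)

        # preprocess
        t0 = time.perf_counter()
        chain = PreprocessChain.from_config(cfg["preprocess"])
        Xtr = chain.fit_apply(train.reflectance)
        Xte = chain.apply(test.reflectance)
        (outdir / "chain.json").write_text(json.dumps(chain.to_jsonable()))
        _artifact(outdir / "chain.json")
        _mark("preprocess", t0)

        # wavelength selection
        t0 = time.perf_counter()
        sel_idx, sel_trace = stage_select(Xtr, train.analyte, cfg, seeds)
        wl_sel = ds.wavelengths[sel_idx] if len(sel_idx) and Xtr.shape[1] == ds.p else sel_idx.astype(float)
        np.savetxt(outdir / "selected_wavelengths.txt", np.c_[sel_idx, wl_sel],
                   header="band_index wavelength_nm", fmt=["%d", "%.6f"])
        (outdir / "selection_trace.json").write_text(json.dumps(sel_trace))
        _artifact(outdir / "selected_wavelengths.txt")
        _artifact(outdir / "selection_trace.json")
        Xtr_s, Xte_s = Xtr[:, sel_idx], Xte[:, sel_idx]
        _mark("select", t0)

        # model
        t0 = time.perf_counter()
        mcfg = cfg["model"]
        kind = mcfg["kind"]
        tune_info = None
        if mcfg.get("tune"):
            tr_rows, val_rows = _holdout_split(len(train.analyte), mcfg["val_fraction"], seeds["val_split"])
            base = build_net_config(kind, mcfg.get("config") or {}, seeds["net"])
            space = _space_from_cfg(mcfg.get("space"), attention=base.attention)
            tr = tune_network(
                space,
                Xtr_s[tr_rows], train.analyte[tr_rows],
                Xtr_s[val_rows], train.analyte[val_rows],
                n_whales=mcfg["woa"].get("n_whales", 10),
                max_iterations=mcfg["woa"].get("max_iterations", 10),
                seed=seeds["tune"],
                base_config=base,
            )
            net_config = tr.best_config
            (outdir / "best_config.json").write_text(json.dumps(asdict(net_config), indent=2))
            _artifact(outdir / "best_config.json")
            with open(outdir / "woa_audit.csv", "w", newline="") as fh:
                writer = csv.writer(fh)
                names = [d.name for d in space.dims]
                writer.writerow(["iteration", "whale", *names, "fitness"])
                for entry, audit in zip(tr.woa.trail, tr.audit):
                    writer.writerow([entry["iteration"], entry["whale"],
                                     *[audit["config"][nm] for nm in names],
                                     entry["fitness"]])
            _artifact(outdir / "woa_audit.csv")
            tune_info = {
                "best_fitness": tr.best_fitness,
                "n_evaluations": tr.woa.n_evaluations,
                "best_curve": tr.woa.best_curve.tolist(),
            }
        else:
            net_config = build_net_config(kind, mcfg.get("config") or {}, seeds["net"])
        model = BiLSTMAttention(net_config, Xtr_s.shape[1])
        history = model.fit(Xtr_s, train.analyte, Xte_s, test.analyte)
        model.save(outdir / "model")
        _artifact(outdir / "model/params.npz")
        _artifact(outdir / "model/config.json")
        (outdir / "history.json").write_text(json.dumps(
            {"train_mse": history.train_mse, "val_mse": history.val_mse}))
        _artifact(outdir / "history.json")
        _mark("model", t0)

        # evaluation
        t0 = time.perf_counter()
        reports = [evaluate_predictions(
            kind, train.analyte, model.predict(Xtr_s), test.analyte, model.predict(Xte_s))]
        if cfg.get("baselines"):
            reports.extend(fit_baselines(
                Xtr_s, train.analyte, Xte_s, test.analyte, which=tuple(cfg["baselines"])))
        comparisons = []
        if len(reports) > 1:
            ref = reports[1].model
            comparisons = compare_report(
                reports,
                [(ref, reports[0].model, "rp2", "increase"),
                 (ref, reports[0].model, "rmsep", "decrease")],
            )
        payload = {
            "reports": [r.to_jsonable() for r in reports],
            "comparisons": comparisons,
            "selected_bands": int(len(sel_idx)),
            "tuning": tune_info,
        }
        (outdir / "metrics.json").write_text(json.dumps(payload, indent=2))
        _artifact(outdir / "metrics.json")
        (outdir / "report.txt").write_text(render_report_table(reports, comparisons) + "\n")
        _artifact(outdir / "report.txt")
        _mark("evaluate", t0)
    except Exception:
        (outdir / "FAILED").write_text("pipeline failed; partial artifacts retained\n")
        raise
    manifest_path = outdir / "MANIFEST.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return payload


def _space_from_cfg(space_cfg, attention: bool) -> SearchSpace:
    if not space_cfg:
        return default_search_space(include_attention=attention)
    dims = [Dimension(**d) for d in space_cfg]
    return SearchSpace(tuple(dims))
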