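"""End-to-end orchestration: simulate -> summarize -> fit -> predict.

A run is described by a single YAML/JSON config; every stochastic stage
derives its seed deterministically from the global seed and the stage
name, and a manifest JSON records the config echo, the per-stage seeds
and SHA-256 digests of every output file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import io as bio
from .data import CountData
from .mcmc import MCMCSettings
from .model import BurstingModel
from .scaling import make_scaling_curves
from .simulate import generate_scenario
from .stats import summarize_counts, summary_table
from .zinb import BurstModelParams, ZINBParams

__all__ = ["derive_seed", "load_config", "run_pipeline"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)


def _scenario_from_config(entries: list[dict]) -> list[tuple]:
    spec = []
    for entry in entries:
        label = entry["condition"]
        kind = entry.get("kind", "zinb")
        n_cells = int(entry["n_cells"])
        params = entry["params"]
        if kind == "zinb":
            spec.append((label, ZINBParams(**params), n_cells))
        elif kind == "ssa":
            spec.append((label, BurstModelParams(**params), n_cells))
        else:
            raise ValueError(f"unknown generator kind {kind!r}")
    return spec


def run_pipeline(config: dict, out_dir: str | Path, verbose: bool = True) -> dict:
    """Execute all configured stages; returns the manifest dict.

    Any stage failure aborts with the stage name; the partial manifest is
    persisted before the exception propagates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    max_count = int(config.get("filter_max_count", 150))
    manifest: dict = {"config": config, "global_seed": seed, "stages": {}, "outputs": {}}
    manifest_path = out_dir / "manifest.json"

    def log(msg: str) -> None:
        if verbose:
            print(msg)

    def record(stage: str, path: Path) -> None:
        manifest["outputs"][str(path.name)] = bio.file_digest(path)
        manifest["stages"].setdefault(stage, {})["done"] = True

    stage = "simulate"
    try:
        # --- simulate ------------------------------------------------------
        if "scenario" in config:
            s_seed = derive_seed(seed, stage)
            manifest["stages"][stage] = {"seed": s_seed}
            data = generate_scenario(_scenario_from_config(config["scenario"]), seed=s_seed)
            counts_path = out_dir / "counts.csv"
            bio.write_counts(data, counts_path)
            record(stage, counts_path)
            log(f"[simulate] wrote {data.n_cells} cells, {len(data.conditions)} conditions")
        elif "counts" in config:
            data = bio.read_counts(config["counts"])
            manifest["stages"][stage] = {"input": str(config["counts"])}
        else:
            raise ValueError("config needs either 'scenario' or 'counts'")

        # --- summarize ------------------------------------------------------
        stage = "summarize"
        s_seed = derive_seed(seed, stage)
        manifest["stages"][stage] = {"seed": s_seed}
        boot = config.get("bootstrap", {})
        stats = summarize_counts(
            data,
            max_count=max_count,
            n_boot=int(boot.get("n_boot", 10_000)),
            seed=s_seed,
        )
        summary_path = out_dir / "summary.csv"
        summary_table(stats).to_csv(summary_path, index=False, lineterminator="\n")
        record(stage, summary_path)
        for s in stats.values():
            log(
                f"[summarize] {s.condition}: n={s.n_cells_used} mu={s.mu:.3f} "
                f"CV2={s.cv2:.3f} F={s.fano:.3f}"
            )

        # --- fit -------------------------------------------------------------
        stage = "fit"
        mcmc_cfg = dict(config.get("mcmc", {}))
        for condition in data.conditions:
            c_seed = derive_seed(seed, f"fit:{condition}")
            settings = MCMCSettings(seed=c_seed, **mcmc_cfg)
            model = BurstingModel(data, max_count=max_count, condition=condition)
            res = model.fit(settings)
            manifest["stages"].setdefault(stage, {})[condition] = {"seed": c_seed}
            chain_path = out_dir / f"chain_{condition}.csv"
            res.chain_frame().to_csv(chain_path, index=False, lineterminator="\n")
            fit_path = out_dir / f"fit_{condition}.json"
            fit_path.write_text(json.dumps(bio._jsonable(res.to_dict()), indent=2) + "\n")
            record(stage, chain_path)
            record(stage, fit_path)
            rep = res.diagnostics() if len(res.chain) >= 200 else None
            ess_txt = (
                " ess=" + ",".join(f"{k}:{v:.0f}" for k, v in rep.ess.items()) if rep else ""
            )
            log(
                f"[fit] {condition}: accept={res.chain.acceptance_rate:.3f}"
                f" freq={res.kinetics.burst_frequency:.3g}"
                f" size={res.kinetics.burst_size:.3g} omega={res.params.omega:.3g}{ess_txt}"
            )

        # --- predict ----------------------------------------------------------
        stage = "predict"
        for entry in config.get("predict", []):
            curve = make_scaling_curves(
                entry["regime"],
                K=float(entry.get("K", 1000.0)),
                nu=entry.get("nu"),
                lam=entry.get("lam"),
            )
            curve_path = out_dir / f"curve_{entry['regime']}.csv"
            curve.to_frame().to_csv(curve_path, index=False, lineterminator="\n")
            record(stage, curve_path)
            log(f"[predict] wrote {curve_path.name}")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        bio.write_manifest(manifest_path, manifest)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bio.write_manifest(manifest_path, manifest)
    manifest["outputs"]["manifest.json"] = "self"
    return manifest
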