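"""End-to-end experiment driver: generate -> preprocess -> grid-train ->
select best -> complexity -> LRP -> analytics, with a manifest.

The whole run is a pure function of the experiment configuration: all
stage seeds derive from the global seed, so re-running the same config
reproduces every numeric output.  Outputs land in a run directory:

    data/        generated dataset (long CSV), channel stats, exclusion report
    models/      grid results CSV, best-model parameters (HDF5)
    relevance/   per-arch class-conditional input relevance, accumulated totals
    analysis/    quadrant tallies, hidden-unit relevance matrices, complexity
    manifest.json  config hash, seeds, content hash of every output file
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .analysis import (
    QuadrantPoint,
    hidden_relevance_matrix,
    accumulated_input_relevance,
    quadrant_assign,
    relevance_count,
    zero_crossing_rate,
)
from .complexity import complexity_table
from .dims import ARCHS
from .lrp import LRPConfig, classwise_mean_relevance, lrp, normalize_temporal
from .networks import forward, predict, save_params
from .preprocessing import preprocess
from .synthetic import ConfigurationError, GeneratorConfig
from .training import GridSpec, TrainConfig, run_grid, select_best

__all__ = ["ExperimentConfig", "validate_config", "run_experiment"]

logger = logging.getLogger("dynhar")


@dataclass
class ExperimentConfig:
    generator: GeneratorConfig
    grid: GridSpec
    training: TrainConfig
    lrp: LRPConfig
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    train_only_stats: bool = False
    quantile: float = 0.70
    highlight_threshold: float = 0.55
    sort_class: int = 0
    seed: int = 0
    output_dir: str = "run"

    def validate(self) -> None:
        self.generator.validate()
        self.grid.validate()
        self.training.validate()
        self.lrp.validate()
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigurationError(f"fractions must sum to 1: {self.fractions}")
        if not 0.0 < self.quantile < 1.0:
            raise ConfigurationError(f"quantile must be in (0, 1): {self.quantile}")
        if not 0.0 < self.highlight_threshold < 1.0:
            raise ConfigurationError(
                f"highlight_threshold must be in (0, 1): {self.highlight_threshold}"
            )


def _build_config(d: dict) -> ExperimentConfig:
    try:
        gen_d = dict(d.get("generator", {}))
        if "class_specs" not in gen_d:
            gen_d["class_specs"] = [
                {
                    "class_id": s.class_id,
                    "name": s.name,
                    "fundamental_hz": s.fundamental_hz,
                    "channel_amplitudes": list(s.channel_amplitudes),
                    "channel_phases": list(s.channel_phases),
                    "harmonic_weights": list(s.harmonic_weights),
                    "channel_fundamentals": dict(s.channel_fundamentals),
                }
                for s in synthetic.default_class_specs()
            ]
        seed = int(d.get("seed", 0))
        gen_d.setdefault("seed", seed)
        generator = synthetic._config_from_dict(gen_d)
        grid_d = d.get("grid", {})
        grid = GridSpec(
            architectures=tuple(grid_d.get("architectures", ARCHS)),
            delays=tuple(int(x) for x in grid_d.get("delays", (30,))),
            hidden_sizes=tuple(int(x) for x in grid_d.get("hidden_sizes", (4,))),
            repetitions=int(grid_d.get("repetitions", 1)),
            base_seed=int(grid_d.get("base_seed", seed)),
        )
        tr_d = d.get("training", {})
        training = TrainConfig(
            learning_rate=float(tr_d.get("learning_rate", 1e-3)),
            max_epochs=int(tr_d.get("max_epochs", 200)),
            patience=int(tr_d.get("patience", 10)),
            batch_size=int(tr_d.get("batch_size", 32)),
            seed=seed,
        )
        lrp_d = d.get("lrp", {})
        if "epsilon" in lrp_d and float(lrp_d["epsilon"]) <= 0:
            raise ConfigurationError(
                f"lrp.epsilon must be > 0, got {lrp_d['epsilon']}"
            )
        lrp_cfg = LRPConfig(
            epsilon=float(lrp_d.get("epsilon", 1e-6)),
            gate_policy=str(lrp_d.get("gate_policy", "signal-takes-all")),
        )
        pp = d.get("preprocessing", {})
        return ExperimentConfig(
            generator=generator,
            grid=grid,
            training=training,
            lrp=lrp_cfg,
            fractions=tuple(float(x) for x in pp.get("fractions", (0.70, 0.15, 0.15))),
            train_only_stats=bool(pp.get("train_only_stats", False)),
            quantile=float(d.get("analysis", {}).get("quantile", 0.70)),
            highlight_threshold=float(
                d.get("analysis", {}).get("highlight_threshold", 0.55)
            ),
            sort_class=int(d.get("analysis", {}).get("sort_class", 0)),
            seed=seed,
            output_dir=str(d.get("output_dir", "run")),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"invalid experiment config: {exc}") from exc


def validate_config(path) -> ExperimentConfig:
    """Parse, default and invariant-check an experiment YAML file."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise ConfigurationError("experiment config must be a YAML mapping")
    cfg = _build_config(d)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    config.validate()
    out = Path(out_dir if out_dir is not None else config.output_dir)
    for sub in ("data", "models", "relevance", "analysis"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timers: dict[str, float] = {}

    def stage(name):
        logger.info("stage: %s", name)
        timers[name] = time.perf_counter()

    def done(name):
        timers[name] = time.perf_counter() - timers[name]

    # 1. generate
    stage("generate")
    dataset = synthetic.generate_dataset(config.generator)
    synthetic.save_dataset_csv(dataset, out / "data" / "dataset.csv")
    written.append(out / "data" / "dataset.csv")
    done("generate")

    # 2. preprocess
    stage("preprocess")
    split, report = preprocess(
        dataset,
        seed=config.seed,
        fractions=config.fractions,
        train_only_stats=config.train_only_stats,
    )
    split.stats.to_json(out / "data" / "channel_stats.json")
    (out / "data" / "exclusions.json").write_text(json.dumps(report, indent=2))
    written += [out / "data" / "channel_stats.json", out / "data" / "exclusions.json"]
    done("preprocess")

    # 3. grid training
    stage("grid")
    results = run_grid(config.grid, split, config.training)
    frame = results.to_frame()
    frame.to_csv(out / "models" / "grid_results.csv", index=False)
    written.append(out / "models" / "grid_results.csv")
    done("grid")

    # 4. best-model selection + complexity
    stage("select")
    best = {}
    for arch in config.grid.architectures:
        rec = select_best(results.records, arch)
        idx = results.records.index(rec)
        best[arch] = (rec, results.params[idx])
        path = out / "models" / f"best_{arch}.h5"
        save_params(path, arch, rec.dims, results.params[idx])
        written.append(path)
    dims_list = sorted({rec.dims for rec, _ in best.values()}, key=lambda d: (d.nd, d.nh))
    ctable = complexity_table(list(config.grid.architectures), dims_list)
    ctable.to_csv(out / "analysis" / "complexity.csv", index=False)
    written.append(out / "analysis" / "complexity.csv")
    done("select")

    # 5. LRP + analytics per best model
    stage("lrp")
    fs = config.generator.fs
    X_test, y_test = split.test.to_arrays()
    for arch, (rec, params) in best.items():
        input_norms, hidden_norms, preds = [], [], []
        for w in split.test.windows:
            trace = forward(arch, params, w, rec.dims)
            preds.append(predict(trace))
            rmap = lrp(params, trace, config.lrp)
            rmap.window_id = w.window_id
            input_norms.append(normalize_temporal(rmap, "input"))
            hidden_norms.append(normalize_temporal(rmap, "hidden"))
        preds = np.array(preds)
        labels = split.test.labels()

        per_class = classwise_mean_relevance(input_norms, labels, preds)
        per_class.index = list(synthetic.CHANNEL_NAMES)
        per_class.to_csv(out / "relevance" / f"{arch}_input_classwise.csv")
        accumulated = accumulated_input_relevance(per_class)
        accumulated.to_csv(
            out / "relevance" / f"{arch}_input_accumulated.csv", header=["relevance"]
        )
        written += [
            out / "relevance" / f"{arch}_input_classwise.csv",
            out / "relevance" / f"{arch}_input_accumulated.csv",
        ]

        # quadrant analysis: per (channel, class) mean ZCR over the class's
        # correctly predicted test windows x summed top-quantile counts
        points = []
        for cid in sorted(split.test.class_names):
            idx = np.where((labels == cid) & (preds == cid))[0]
            if idx.size == 0:
                continue
            counts = np.zeros(rec.dims.ni, dtype=int)
            zcrs = np.zeros(rec.dims.ni)
            for i in idx:
                counts += relevance_count(input_norms[i], config.quantile)
                for ch in range(rec.dims.ni):
                    zcrs[ch] += zero_crossing_rate(X_test[i][:, ch], fs)
            zcrs /= idx.size
            for ch in range(rec.dims.ni):
                points.append(QuadrantPoint(ch, cid, float(zcrs[ch]), int(counts[ch])))
        _, tally = quadrant_assign(points)
        tally.to_csv(out / "analysis" / f"{arch}_quadrants.csv")
        written.append(out / "analysis" / f"{arch}_quadrants.csv")

        hmat = hidden_relevance_matrix(
            hidden_norms,
            labels,
            preds,
            sort_class=config.sort_class,
            highlight_threshold=config.highlight_threshold,
        )
        hdf = pd.DataFrame(
            hmat.values[hmat.row_order],
            columns=[split.test.class_names[c] for c in hmat.class_ids],
            index=[f"unit_{u}" for u in hmat.row_order],
        )
        hdf.to_csv(out / "analysis" / f"{arch}_hidden_classwise.csv")
        written.append(out / "analysis" / f"{arch}_hidden_classwise.csv")
    done("lrp")

    manifest = {
        "config_hash": config.generator.content_hash(),
        "seed": config.seed,
        "grid": {
            "architectures": list(config.grid.architectures),
            "delays": list(config.grid.delays),
            "hidden_sizes": list(config.grid.hidden_sizes),
            "repetitions": config.grid.repetitions,
            "cardinality": config.grid.cardinality,
        },
        "best": {
            arch: {
                "val_acc": rec.val_acc,
                "test_acc": rec.test_acc,
                "nd": rec.dims.nd,
                "nh": rec.dims.nh,
                "seed": rec.seed,
            }
            for arch, (rec, _) in best.items()
        },
        "stage_seconds": {k: round(v, 3) for k, v in timers.items()},
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in written
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
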