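"""End-to-end orchestration and the ``glycopore`` command-line interface.

``run_pipeline`` wires the stages (simulate → extract → kinetics → train →
predict/gate → report) from a JSON-serializable configuration; each stage
writes its outputs plus a sidecar recording the configuration hash and seed,
so every artifact on disk is traceable. The CLI subcommands mirror the
stages and exchange the text formats defined in ``trace_io``.

Exit codes: 2 for configuration/validation errors (raised before any
computation), 1 for computation failures.
"""

from __future__ import annotations

import argparse
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, event_detection, features, kinetics, ood_gate, synthetic_data, trace_io
from .trace_io import ValidationError

logger = logging.getLogger("glycopore")

__all__ = ["run_pipeline", "main", "config_hash"]

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {"classes": ["GT1c", "GT1b", "GT1a", "GT1aα"], "duration": 10.0,
                 "background": False},
    "qc": {},
    # min_dwell_ms: feature-QC duration cutoff for the identification
    # workflow — an event must span at least one 8-sample spectral window
    # (0.16 ms at 50 kHz); shorter blockades carry no intra-event
    # fluctuation information.
    # models: optional subset of the zoo (names); None evaluates all ten.
    "ml": {"per_class_n": 10_000, "top_k": 12, "cv_repeats": 1, "denoise": True,
           "min_dwell_ms": 0.16, "models": None},
    "gate": {"coverage": 0.70, "enabled": True},
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _merge(default: dict, override: dict) -> dict:
    out = dict(default)
    for k, v in override.items():
        out[k] = _merge(default[k], v) if isinstance(v, dict) and isinstance(default.get(k), dict) else v
    return out


def _validate_config(config: dict) -> dict:
    config = _merge(DEFAULT_CONFIG, config or {})
    presets = synthetic_data.class_presets()
    for name in config["simulate"]["classes"]:
        if name not in presets or name == "background":
            raise ValidationError(f"unknown class preset {name!r}")
    if not (0.0 <= config["gate"]["coverage"] <= 1.0):
        raise ValidationError("gate coverage must lie in [0, 1]")
    if config["ml"]["top_k"] > len(features.FEATURE_NAMES):
        raise ValidationError("top_k exceeds the feature count")
    return config


def _write_provenance(out_dir: Path, config: dict, stage: str, info: dict) -> None:
    payload = {"stage": stage, "config_hash": config_hash(config),
               "seed": config["seed"], **info}
    (out_dir / f"{stage}.provenance.json").write_text(json.dumps(payload, indent=1))


def run_pipeline(config: dict, out_dir, stages=("simulate", "extract", "train", "predict")) -> dict:
    """Run the requested stages in order; returns the report dictionary.

    Synthetic traces stand in for recordings: ``simulate`` writes a labelled
    event population per class, ``extract`` turns it into feature tables,
    ``train`` runs selection/preprocessing/denoising/model bake-off, and
    ``predict`` applies the bundle plus KDE gate to a held-out mixture.
    A stage failure stops the run and leaves a resumable state marker.
    """
    config = _validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(config["seed"])
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(("simulate", "extract", "train", "predict"),
                                seed_seq.spawn(4))}
    report: dict = {"config_hash": config_hash(config), "seed": config["seed"],
                    "stages": {}}
    state_path = out_dir / "pipeline.state.json"

    try:
        tables_by_class = None
        for stage in stages:
            t0 = time.monotonic()
            if stage == "simulate":
                presets = synthetic_data.class_presets()
                specs = [presets[name] for name in config["simulate"]["classes"]]
                n_per_class = min(config["ml"]["per_class_n"], 10_000)
                events = synthetic_data.simulate_labeled_events(
                    specs, n_per_class, seeds["simulate"]
                )
                table = features.extract_feature_table(events)
                table = table[table["dwell_time"] >= config["ml"]["min_dwell_ms"]]
                tables_by_class = {
                    name: table[table["label"] == name].reset_index(drop=True)
                    for name in config["simulate"]["classes"]
                }
                for name, tbl in tables_by_class.items():
                    trace_io.write_feature_table(tbl, out_dir / f"features_{name}.csv")
                info = {"n_events": int(len(table))}
            elif stage == "extract":
                if tables_by_class is None:
                    tables_by_class = {
                        p.stem.removeprefix("features_"): trace_io.read_feature_table(p)
                        for p in sorted(out_dir.glob("features_*.csv"))
                    }
                    if not tables_by_class:
                        raise ValidationError(f"no feature tables found in {out_dir}")
                info = {"classes": sorted(tables_by_class)}
            elif stage == "train":
                data, split = classify.assemble_dataset(
                    tables_by_class, config["ml"]["per_class_n"], seeds["train"]
                )
                train_tbl = data.iloc[split.train]
                ranked = classify.rank_features_anova(train_tbl)
                selected = classify.select_top_k(ranked, config["ml"]["top_k"])
                pp = classify.fit_preprocessor(train_tbl, selected)
                X_train = classify.apply_preprocessor(pp, train_tbl)
                retained = (classify.denoise_training(X_train, seed=seeds["train"])
                            if config["ml"]["denoise"] else None)
                y = train_tbl["label"].to_numpy()
                Xr = X_train if retained is None else X_train[retained]
                yr = y if retained is None else y[retained]
                zoo = classify.default_model_zoo(seeds["train"])
                if config["ml"]["models"]:
                    zoo = {k: zoo[k] for k in config["ml"]["models"]}
                cv_report = classify.evaluate_models(
                    Xr, classify.LabelEncoder().fit(yr).transform(yr),
                    zoo=zoo, seed=seeds["train"], n_repeats=config["ml"]["cv_repeats"],
                )
                bundle = classify.train_final(
                    train_tbl, selected, seed=seeds["train"], cv_report=cv_report,
                    preprocessor=pp, retained_idx=retained,
                )
                classify.save_bundle(bundle, out_dir / "bundle")
                gate = None
                if config["gate"]["enabled"]:
                    val_tbl = data.iloc[split.validation]
                    gate = ood_gate.fit_gate(Xr, yr)
                    gate = ood_gate.calibrate_gate(
                        gate, classify.apply_preprocessor(pp, val_tbl),
                        val_tbl["label"].to_numpy(), config["gate"]["coverage"],
                    )
                report["train"] = {
                    "chosen_model": cv_report.chosen,
                    "cv_metrics": cv_report.metrics[cv_report.chosen],
                    "selected_features": selected,
                    "retained_fraction": (1.0 if retained is None
                                          else float(retained.size / X_train.shape[0])),
                }
                report["_test_table"] = data.iloc[split.test]
                report["_bundle"], report["_gate"] = bundle, gate
                info = {"chosen_model": cv_report.chosen}
            elif stage == "predict":
                bundle, gate = report.get("_bundle"), report.get("_gate")
                if bundle is None:
                    bundle = classify.load_bundle(out_dir / "bundle")
                test_tbl = report.get("_test_table")
                if test_tbl is None:
                    raise ValidationError("predict stage needs a trained run or a test table")
                labels, _ = classify.predict_events(bundle, test_tbl)
                X_test = classify.apply_preprocessor(bundle.preprocessor, test_tbl)
                if gate is not None:
                    gated, accepted, _ = ood_gate.apply_gate(gate, labels, X_test)
                    metrics = ood_gate.accepted_only_metrics(
                        test_tbl["label"].to_numpy(), labels, accepted
                    )
                    composition = ood_gate.mixture_composition(gated)
                else:
                    metrics = ood_gate.accepted_only_metrics(
                        test_tbl["label"].to_numpy(), labels,
                        np.ones(len(test_tbl), dtype=bool),
                    )
                    composition = ood_gate.mixture_composition(labels)
                report["predict"] = {"metrics": metrics,
                                     "composition": composition.to_dict()}
                pd.DataFrame({"predicted": labels}).to_csv(out_dir / "calls.csv", index=False)
                info = {"n_events": int(len(test_tbl))}
            else:
                raise ValidationError(f"unknown stage {stage!r}")
            elapsed = time.monotonic() - t0
            report["stages"][stage] = {"seconds": round(elapsed, 2), **info}
            logger.info("stage %s done in %.1fs: %s", stage, elapsed, info)
            _write_provenance(out_dir, config, stage, info)
            state_path.write_text(json.dumps({"completed_through": stage}))
    except Exception:
        state_path.write_text(json.dumps({"failed_at": stage}))
        raise
    for key in ("_bundle", "_gate", "_test_table"):
        report.pop(key, None)
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _load_config(path) -> dict:
    if path is None:
        return {}
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"config file not found: {p}")
    return json.loads(p.read_text())


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        prog="glycopore",
        description="Nanopore glycan-event analysis: simulate, extract, fit, train, predict.",
    )
    parser.add_argument("--log-level", default="INFO")
    sub = parser.add_subparsers(dest="command", required=True)

    p_sim = sub.add_parser("simulate", help="generate a synthetic trace + truth table")
    p_sim.add_argument("--config", default=None)
    p_sim.add_argument("--seed", type=int, default=0)
    p_sim.add_argument("--out", required=True)

    p_ext = sub.add_parser("extract", help="detect/segment events and extract features")
    p_ext.add_argument("--trace", required=True)
    p_ext.add_argument("--events", default=None, help="Clampfit-style boundary CSV; omit to auto-detect")
    p_ext.add_argument("--out", required=True)

    p_kin = sub.add_parser("kinetics", help="population fits from a feature table")
    p_kin.add_argument("--features", required=True)
    p_kin.add_argument("--fits", required=True)

    for name in ("train", "predict", "report"):
        p = sub.add_parser(name, help=f"{name} stage of the ML workflow")
        p.add_argument("--config", default=None)
        p.add_argument("--out", required=True)

    args = parser.parse_args(argv)
    logging.basicConfig(level=args.log_level, format="%(levelname)s %(name)s: %(message)s")

    try:
        if args.command == "simulate":
            cfg = _validate_config(_load_config(args.config))
            cfg["seed"] = args.seed
            presets = synthetic_data.class_presets()
            gen = synthetic_data.GeneratorConfig(
                classes=tuple((presets[n], 1.0 / len(cfg["simulate"]["classes"]))
                              for n in cfg["simulate"]["classes"]),
                duration=cfg["simulate"]["duration"],
                background=(synthetic_data.background_preset()
                            if cfg["simulate"]["background"] else None),
                seed=args.seed,
            )
            trace, truth = synthetic_data.simulate_trace(gen)
            out = Path(args.out)
            out.mkdir(parents=True, exist_ok=True)
            trace_io.write_trace(trace, out / "trace.bin")
            trace_io.write_event_boundaries(truth, out / "truth.csv")
        elif args.command == "extract":
            trace = trace_io.read_trace(args.trace)
            qc = event_detection.QCConfig()
            boundaries = (trace_io.read_event_boundaries(args.events, trace)
                          if args.events else event_detection.detect_events(trace, qc))
            records = event_detection.segment_events(trace, boundaries, qc)
            table = features.extract_feature_table(records, trace.sampling_rate)
            trace_io.write_feature_table(table, args.out)
        elif args.command == "kinetics":
            table = trace_io.read_feature_table(args.features)
            ok = table[~table["excluded"]]
            amp = kinetics.fit_gaussian_amplitude(ok["delta_ratio"])
            dwells = ok["dwell_time"].dropna()
            single = kinetics.fit_exponential_dwell(dwells)
            out = {
                "amplitude": {"mu": amp.mu, "sigma": amp.sigma, "n": amp.n},
                "dwell_single": {"tau": single.tau, "se": single.se, "aic": single.aic,
                                 "n": single.n},
            }
            if len(dwells) >= 100:
                bi = kinetics.fit_biexponential_dwell(dwells)
                out["dwell_biexponential"] = {
                    "tau_slow": bi.tau_slow, "tau_fast": bi.tau_fast, "w_slow": bi.w_slow,
                    "aic": bi.aic, "prefers_single": bi.prefers_single, "n": bi.n,
                }
            Path(args.fits).write_text(json.dumps(out, indent=1))
        elif args.command in ("train", "predict", "report"):
            cfg = _load_config(args.config)
            stages = {"train": ("extract", "train"),
                      "predict": ("extract", "train", "predict"),
                      "report": ("simulate", "extract", "train", "predict")}[args.command]
            run_pipeline(cfg, args.out, stages=stages)
    except (ValidationError, trace_io.FormatError) as exc:
        print(f"configuration/validation error: {exc}", file=sys.stderr)
        return 2
    except Exception as exc:  # computation failure
        print(f"error: {exc}", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    sys.exit(main())
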