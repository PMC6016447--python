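"""End-to-end workflow driver: load -> featurize -> MODI gate -> train panel
-> evaluate -> (optional) y-randomization -> AD fit -> enumerate -> screen.

Configured by a YAML/JSON file; every stage logs its inputs and seeds, and a
failure halts with the stage name and a remediation hint.  Reruns with the
same config are deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .chem import enumerate_library, load_building_blocks, load_compounds, write_csv
from .descriptors import Featurizer, feature_matrix_to_csv, labels_to_binary, modi
from .domain import ApplicabilityDomain
from .fixtures import build_demo, default_building_blocks
from .metrics import evaluate, format_report_table
from .modeling import (
    CONSENSUS_FAMILIES,
    ModelConfig,
    train_panel,
    y_randomization,
)
from .screening import screen

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "gelscreen_out",
    "data": {"demo": True, "demo_noise": 0.1},
    "descriptors": {"radius": 2, "n_bits": 1024},
    "modi": {"threshold": 0.65, "halt_below_threshold": False},
    "models": {"families": list(CONSENSUS_FAMILIES), "repeats": 10},
    "y_randomization": {"enabled": False, "n_shuffles": 10},
    "applicability_domain": {"tolerance": 0.0, "coverage_threshold": 0.95},
    "library": {"blocks": None, "include_monopeptides": True},
    "screening": {"m_gelators": 4, "m_non_gelators": 5},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}" + (f" (hint: {hint})" if hint else ""))


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
    return _merge(DEFAULT_CONFIG, user)


def run_pipeline(config, output_dir=None) -> dict:
    """Execute the full workflow; returns a summary dict of artifact paths
    and headline numbers.  ``config`` is a path or an already-merged dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merge(DEFAULT_CONFIG, config)
    seed = int(config["seed"])
    outdir = Path(output_dir or config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("gelscreen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "seed": seed, "output_dir": str(outdir)}
    try:
        # ---- load -------------------------------------------------------
        data_cfg = config["data"]
        if data_cfg.get("demo"):
            suite = build_demo(seed=seed, noise=float(data_cfg.get("demo_noise", 0.1)))
            train, test = suite.train, suite.test
            logger.info("demo fixtures: train n=%d, test n=%d (synthetic labels)",
                        len(train), len(test))
        else:
            try:
                train = load_compounds(data_cfg["train"], source="training")
            except (KeyError, FileNotFoundError) as exc:
                raise PipelineError("load", f"training set unavailable: {exc}",
                                    "set data.train to a CSV with id,smiles,label")
            test = None
            if data_cfg.get("test"):
                try:
                    test = load_compounds(data_cfg["test"], source="test")
                except FileNotFoundError as exc:
                    raise PipelineError("load", f"test set unavailable: {exc}",
                                        "fix data.test or remove it")
        write_csv(train, outdir / "train.csv")
        if test:
            write_csv(test, outdir / "test.csv")

        # ---- featurize --------------------------------------------------
        desc = config["descriptors"]
        featurizer = Featurizer(radius=int(desc["radius"]), n_bits=int(desc["n_bits"]))
        fm_train = featurizer.fit_transform(train)
        y_train = labels_to_binary(train)
        feature_matrix_to_csv(fm_train, outdir / "features_train.csv")

        # ---- MODI gate --------------------------------------------------
        modi_value = modi(fm_train.physchem, y_train)
        summary["modi"] = modi_value
        (outdir / "modi.json").write_text(json.dumps({"modi": modi_value}))
        threshold = float(config["modi"]["threshold"])
        if modi_value <= threshold:
            msg = f"MODI = {modi_value:.2f} <= {threshold}: data may not be modelable"
            logger.warning(msg)
            if config["modi"]["halt_below_threshold"]:
                raise PipelineError("modi", msg, "set modi.halt_below_threshold: false to continue")

        # ---- train panel ------------------------------------------------
        mcfg = config["models"]
        panel = train_panel(
            fm_train, y_train,
            families=tuple(mcfg["families"]),
            seed=seed, repeats=int(mcfg["repeats"]), modi_value=modi_value,
        )
        cv_rows = {
            fam: {
                "h_mean": res.h_mean, "h_sd": res.h_sd,
                "best_hyperparameters": res.best_hyperparameters,
                "train_evaluation": model.evaluation.to_dict(),
            }
            for fam, (res, model) in panel.items()
        }
        (outdir / "cv_results.json").write_text(json.dumps(cv_rows, indent=1, default=str))
        train_reports = {fam: model.evaluation for fam, (_, model) in panel.items()}
        (outdir / "train_report.txt").write_text(format_report_table(train_reports))
        summary["train_reports"] = {f: r.to_dict() for f, r in train_reports.items()}

        # ---- evaluate on test -------------------------------------------
        models = [model for _, model in panel.values()]
        if test:
            fm_test = featurizer.transform(test)
            y_test = labels_to_binary(test)
            test_reports = {}
            for fam, (_, model) in panel.items():
                p = model.predict_proba(fm_test)
                test_reports[fam] = evaluate(y_test, (p >= 0.5).astype(int), p)
            (outdir / "test_report.txt").write_text(format_report_table(test_reports))
            summary["test_reports"] = {f: r.to_dict() for f, r in test_reports.items()}

        # ---- y-randomization -------------------------------------------
        yr = config["y_randomization"]
        if yr.get("enabled"):
            fam = mcfg["families"][0]
            reports = y_randomization(
                fm_train, y_train,
                ModelConfig(family=fam, seed=seed, repeats=int(mcfg["repeats"])),
                n_shuffles=int(yr["n_shuffles"]), seed=seed + 1,
                fm_test=featurizer.transform(test) if test else None,
                y_test=labels_to_binary(test) if test else None,
            )
            (outdir / "y_randomization.json").write_text(
                json.dumps([r.to_dict() for r in reports], indent=1)
            )
            summary["y_randomization_kappa"] = [r.kappa for r in reports]

        # ---- AD fit ------------------------------------------------------
        ad_cfg = config["applicability_domain"]
        ad = ApplicabilityDomain.fit(
            train, radius=int(desc["radius"]), n_bits=int(desc["n_bits"]),
            tolerance=float(ad_cfg["tolerance"]),
            coverage_threshold=float(ad_cfg["coverage_threshold"]),
        )

        # ---- enumerate ---------------------------------------------------
        lib_cfg = config["library"]
        blocks = (
            load_building_blocks(lib_cfg["blocks"])
            if lib_cfg.get("blocks")
            else default_building_blocks()
        )
        caps = [b for b in blocks if b.kind == "cap"]
        aas = [b for b in blocks if b.kind == "amino_acid"]
        library = enumerate_library(
            caps, aas, include_monopeptides=bool(lib_cfg["include_monopeptides"])
        )
        summary["n_enumerated"] = len(library)

        # ---- screen ------------------------------------------------------
        scr = config["screening"]
        report = screen(
            library, models, ad, featurizer,
            m_gelators=int(scr["m_gelators"]),
            m_non_gelators=int(scr["m_non_gelators"]),
        )
        report.write_csv(outdir / "screen.csv")
        (outdir / "screen.json").write_text(report.to_json())
        summary["n_in_domain"] = report.n_in_domain
        summary["candidates"] = [
            {"id": r.id, "smiles": r.smiles, "call": r.call, "likelihood": r.likelihood}
            for r in report.selected_candidates
        ]
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
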