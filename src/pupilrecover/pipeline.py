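"""End-to-end orchestration: simulate -> clean -> extract -> fit -> classify.

A single :class:`RunConfig` drives every stage; one global seed derives
per-stage seeds deterministically (stable stage-name hashing), so rerunning
the same config reproduces bitwise-identical CSV/JSON artifacts.  Every
intermediate artifact is written to disk and listed in a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import amplitude as amp_mod
from . import classify as cls_mod
from . import lmm as lmm_mod
from . import preprocess as pre_mod
from . import synth
from .protocol import build_protocol, protocol_to_json

__all__ = ["RunConfig", "run_pipeline", "plot_recovery", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    out_dir: str = "runs/default"
    seed: int = 0
    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    cleaning: pre_mod.CleaningConfig = field(default_factory=pre_mod.CleaningConfig)
    roi: amp_mod.RoiConfig = field(default_factory=amp_mod.RoiConfig)
    variant: str = "base"
    cv: cls_mod.CVConfig = field(default_factory=cls_mod.CVConfig)
    include_age_features: bool = False

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest.

    Any stage failure aborts with the stage name attached and the partial
    manifest persisted.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "global_seed": cfg.seed,
        "stage_seeds": {},
        "stages": {},
    }
    manifest_path = out / "manifest.json"

    def persist() -> None:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1)

    stage = "protocol"
    try:
        protocol = build_protocol()
        path = out / "protocol.json"
        protocol_to_json(protocol, path)
        manifest["stages"][stage] = {"path": str(path), "n_epochs": len(protocol.epochs)}

        stage = "simulate"
        seed = stage_seed(cfg.seed, stage)
        manifest["stage_seeds"][stage] = seed
        cohort = dataclasses.replace(cfg.cohort, seed=seed)
        subjects, recordings = synth.simulate_cohort(cohort, protocol)
        subj_path = out / "subjects.csv"
        synth.subjects_to_frame(subjects).to_csv(subj_path, index=False)
        rec_path = out / "recordings.csv"
        synth.write_recordings_csv(recordings, rec_path)
        manifest["stages"][stage] = {
            "subjects": str(subj_path),
            "recordings": str(rec_path),
            "n_subjects": len(subjects),
        }

        stage = "amplitude"
        cleaned = [pre_mod.clean(r, cfg.cleaning) for r in recordings]
        table = amp_mod.build_table(cleaned, protocol, subjects, cfg.roi)
        table = amp_mod.average_eyes(table)
        amp_path = out / "amplitudes.csv"
        table.to_csv(amp_path, index=False)
        manifest["stages"][stage] = {
            "path": str(amp_path),
            "n_rows": int(len(table)),
            "n_missing": int((table["missing_reason"] != "").sum()),
        }

        stage = "stats"
        results = lmm_mod.fit_lmm(table, variant=cfg.variant)
        fit_path = out / "fit.json"
        results.to_json(fit_path)
        (out / "fit.txt").write_text(results.summary() + "\n")
        anova_path = out / "anova.csv"
        results.anova().to_csv(anova_path, index=False)
        manifest["stages"][stage] = {
            "fit": str(fit_path),
            "anova": str(anova_path),
            "converged": results.converged,
            "n_obs": int(results.n_obs),
        }

        stage = "classify"
        seed = stage_seed(cfg.seed, stage)
        manifest["stage_seeds"][stage] = seed
        cv_cfg = dataclasses.replace(cfg.cv, seed=seed)
        features = cls_mod.build_features(table, include_age=cfg.include_age_features)
        cv_result = cls_mod.cross_validate(features, cv_cfg)
        cv_path = out / "cv.json"
        cv_result.to_json(cv_path)
        manifest["stages"][stage] = {
            "path": str(cv_path),
            "mean_accuracy": cv_result.mean_accuracy,
        }
        persist()
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        persist()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return manifest


def plot_recovery(table: pd.DataFrame, out_path) -> None:
    """Per-group mean recovery curve with an SD band vs dark duration."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if table.empty:
        raise ValueError("amplitude table is empty")
    groups = [g for g in ("Control", "AMD") if g in set(table["group"])]
    if not groups:
        groups = sorted(table["group"].unique())
    colors = {"Control": "0.6", "AMD": "0.1"}
    fig, ax = plt.subplots(figsize=(6, 4))
    for g in groups:
        curve = amp_mod.recovery_curve(table, g)
        c = colors.get(g, None)
        ax.plot(curve["dark_ms"] / 1000.0, curve["mean_amplitude"], color=c, label=g)
        ax.fill_between(
            curve["dark_ms"] / 1000.0,
            curve["mean_amplitude"] - curve["sd"],
            curve["mean_amplitude"] + curve["sd"],
            color=c,
            alpha=0.25,
            linewidth=0,
        )
    ax.set_xlabel("dark duration (s)")
    ax.set_ylabel("PLR amplitude (mm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
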