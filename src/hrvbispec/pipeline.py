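"""End-to-end orchestration: manifest -> features -> selection -> models -> reports.

The pipeline consumes a cohort manifest (CSV with subject_id, ahi, age,
severity, path columns, where each path points to a plain-text RR file), runs
every stage with one configuration object whose defaults are the protocol
constants (15 min trimming, 0.33-1.5 s / 0.66 s rejection, 3.41 Hz
resampling, 1024-sample Hamming windows with 50% overlap and a 2048-point
FFT, B = 1000 bootstrap votes with a > 500 threshold, the 680-point MLP
grid), and writes per-stage artifacts stamped with a configuration hash and
seed.  Every function here is importable on its own; the pipeline is plumbing
around the analysis modules, not a separate implementation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, evaluate, features, preprocess, selection
from .bispectrum import SegmentPlan

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("subject_id", "ahi", "age", "severity", "path")


@dataclass
class PipelineConfig:
    """All stage defaults; every value with a protocol counterpart matches it."""

    trim_minutes: float = 15.0
    min_hours: float = 3.0
    fs_out: float = 3.41
    rr_bounds: tuple[float, float] = (0.33, 1.5)
    max_rr_delta: float = 0.66
    window_len: int = 1024
    overlap: float = 0.5
    nfft: int = 2048
    phase_bins: int = 64
    fcbf_B: int = 1000
    fcbf_threshold: int = 500
    fcbf_bins: int = 10
    mlp_B: int = 1000
    cutoffs: tuple[float, ...] = (1.0, 5.0, 10.0)
    grid: list[tuple[int, float]] = field(default_factory=classify.default_grid)
    seed: int = 0

    def plan(self) -> SegmentPlan:
        return SegmentPlan(
            window_len=self.window_len, overlap=self.overlap, nfft=self.nfft
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid" in raw:
            raw["grid"] = [tuple(g) for g in raw["grid"]]
        for key in ("rr_bounds", "cutoffs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def load_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing required columns: {missing}")
    return manifest


def preprocess_cohort(
    manifest: pd.DataFrame, config: PipelineConfig
) -> list[tuple[dict, preprocess.UniformHRV]]:
    """Read, clean and resample every subject; failures are logged and dropped."""
    subjects = []
    for _, row in manifest.iterrows():
        try:
            rr = preprocess.read_rr_text(row["path"])
            x = preprocess.preprocess_rr(
                rr,
                trim_minutes=config.trim_minutes,
                min_hours=config.min_hours,
                fs=config.fs_out,
            )
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            logger.warning("subject %s excluded: %s", row["subject_id"], exc)
            continue
        labels = {k: row[k] for k in ("subject_id", "ahi", "age", "severity")}
        subjects.append((labels, x))
    return subjects


def run_pipeline(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict[str, object]:
    """Execute all stages and write artifacts under ``out_dir``.

    Artifacts: features_classic.csv / features_specific.csv (42/38 feature
    columns plus labels), selection_{classic,specific}.csv + .json,
    model_{catalog}_{cutoff}.json, reports_{catalog}.csv, run.json (config
    hash, seed, subject counts).  Returns the in-memory stage outputs.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(manifest_path)

    subjects = preprocess_cohort(manifest, config)
    if not subjects:
        raise ValueError("no subject survived preprocessing")
    classic, specific = features.extract_feature_table(
        subjects, plan=config.plan(), phase_bins=config.phase_bins
    )
    classic.to_csv(out / "features_classic.csv")
    specific.to_csv(out / "features_specific.csv")

    results: dict[str, object] = {
        "classic": classic,
        "specific": specific,
        "selection": {},
        "models": {},
        "reports": {},
    }
    for catalog, table in (("classic", classic), ("specific", specific)):
        X = features.feature_matrix(table)
        sel = selection.bootstrap_select(
            X,
            table["severity"].to_numpy(),
            B=config.fcbf_B,
            threshold=config.fcbf_threshold,
            seed=config.seed,
            n_bins=config.fcbf_bins,
        )
        sel.to_frame().to_csv(out / f"selection_{catalog}.csv", index=False)
        (out / f"selection_{catalog}.json").write_text(
            json.dumps(
                {
                    "seed": config.seed,
                    "B": sel.B,
                    "threshold": sel.threshold,
                    "selected": sel.selected,
                    "discretization": f"equal-frequency/{config.fcbf_bins}",
                    "config_hash": config.config_hash(),
                }
            )
        )
        results["selection"][catalog] = sel
        chosen = sel.selected or list(X.columns)

        ahi = table["ahi"].to_numpy(dtype=float)
        Xsel = X[chosen].to_numpy(dtype=float)
        for cutoff in config.cutoffs:
            y = classify.severity_label(ahi, cutoff)
            if np.unique(y).size < 2:
                logger.warning(
                    "cutoff %s e/h: single-class cohort, model skipped", cutoff
                )
                continue
            best, _ = classify.optimize_hyperparams(
                Xsel, y, grid=config.grid, B=config.mlp_B, seed=config.seed
            )
            model = classify.train_mlp(
                Xsel, y, classify.MLPSpec(best[0], best[1], seed=config.seed)
            )
            model.to_json(out / f"model_{catalog}_{int(cutoff)}.json")
            post = classify.predict_posterior(model, Xsel)
            report = evaluate.diagnostic_metrics(y, post)
            results["models"][(catalog, cutoff)] = (model, report)

        results["reports"][catalog] = evaluate.characterization_report(
            table, chosen
        )
        results["reports"][catalog].to_csv(out / f"reports_{catalog}.csv")

    (out / "run.json").write_text(
        json.dumps(
            {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "n_manifest": int(len(manifest)),
                "n_retained": len(subjects),
                "n_classic_features": len(features.catalog_columns("classic")),
                "n_specific_features": len(features.catalog_columns("specific")),
            }
        )
    )
    return results
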