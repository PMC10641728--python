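"""End-to-end orchestration: simulate or load a cohort, extract, compare.

``run_pipeline`` is the programmatic twin of the command-line
interface: it takes a :class:`RunConfig`, produces per-subject feature
CSVs, the group comparison table (CSV + JSON) and a JSON run log, and
returns the fitted comparison results.  All outputs are deterministic
given the configuration (including the seed).
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import DEFAULT_CONFIG, FeatureConfig, extract_features
from .io_edf import read_cohort, write_cohort
from .profiles import SpectralProfile
from .scenarios import study_cohort_spec
from .simulate import CohortSpec, GroupSpec, synthesize_cohort
from .stats import GroupComparison, GroupComparisonResults


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run.

    Exactly one input source is used: ``scenario`` (a named study
    comparison, simulate mode) or ``input_dir`` (a directory of EDF
    files with a manifest, analyze mode).
    """

    mode: str = "simulate"  # "simulate" | "analyze"
    scenario: str = "surgery"  # simulate mode: "surgery" | "delirium"
    input_dir: "str | None" = None  # analyze mode
    output_dir: str = "qeeg_out"
    seed: int = 0
    duration_s: float = 120.0
    fs: float = 256.0
    dispersion: str = "matched"
    write_recordings: bool = False  # simulate mode: also dump EDFs
    feature_config: FeatureConfig = DEFAULT_CONFIG

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError("mode must be 'simulate' or 'analyze'")
        if self.mode == "analyze" and not self.input_dir:
            raise ValueError("analyze mode needs input_dir")


def load_config(path: "str | Path") -> RunConfig:
    """Read a :class:`RunConfig` from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    feat = raw.pop("feature_config", None)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if feat:
        unknown = set(feat) - set(FeatureConfig.__dataclass_fields__)
        if unknown:
            raise KeyError(f"unknown feature_config keys: {sorted(unknown)}")
        feat = {k: tuple(v) if isinstance(v, list) else v for k, v in feat.items()}
        cfg = replace(cfg, feature_config=FeatureConfig(**feat))
    return cfg


def features_to_frame(features) -> pd.DataFrame:
    """Tidy per-subject table (one row per subject, channel means)."""
    rows = []
    for f in features:
        row = {"subject_id": f.subject_id, "group": f.group_label}
        row.update(f.mean.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> GroupComparisonResults:
    """Run one full simulate-or-analyze pass; write all report files.

    Outputs under ``config.output_dir``:

    - ``features.csv`` — per-subject channel-averaged features
    - ``comparison.csv`` / ``comparison.json`` — the group table with
      mean ± SEM per group and Welch/ANOVA statistics
    - ``run_log.json`` — config, seed and library versions
    - ``recordings/`` — per-subject EDFs + manifest (simulate mode,
      when ``write_recordings`` is set)
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fc = config.feature_config

    if config.mode == "simulate":
        spec = study_cohort_spec(
            comparison=config.scenario,
            seed=config.seed,
            duration_s=config.duration_s,
            fs=config.fs,
            dispersion=config.dispersion,
            config=fc,
        )
        recordings = synthesize_cohort(spec)
        if config.write_recordings:
            write_cohort(recordings, out / "recordings")
    else:
        recordings = read_cohort(config.input_dir)

    features = []
    for rec in recordings:
        try:
            features.append(extract_features(rec, fc))
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for subject {rec.subject_id!r}: {exc}"
            ) from exc

    frame = features_to_frame(features)
    frame.to_csv(out / "features.csv", index=False, float_format="%.6f")

    results = GroupComparison.from_dataframe(
        frame.drop(columns=["subject_id"]), group_col="group"
    ).fit()
    results.table.to_csv(out / "comparison.csv", float_format="%.6g")
    (out / "comparison.json").write_text(
        json.dumps(json.loads(results.table.to_json(orient="index")), indent=2)
    )

    import scipy

    log = {
        "config": _config_dict(config),
        "n_subjects": len(features),
        "groups": {
            s.label: s.n for s in results.group_summaries
        },
        "versions": {
            "qeegpod": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return results


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["feature_config"] = asdict(config.feature_config)
    return d
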