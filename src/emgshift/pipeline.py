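"""Configuration-driven experiment runner.

Reproduces the features x shift-schemes evaluation design: for every
requested feature family and shift configuration, a recording (loaded from
file or synthesized) is windowed, the pipeline is fitted on the training
partition, and classification accuracy, confusion matrices, RCS and — for
CSP families — grid-shaped spatial-pattern maps are written to an output
directory together with a JSON provenance manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierSpec, WindowingConfig, evaluate_shift
from .csp import spatial_patterns
from .exceptions import InvalidArgumentError
from .extract import FEATURE_KINDS, FeatureSpec, make_pipeline
from .features import segment
from .grid import SHIFT_SCHEME_NAMES, build_grid, make_shift_scheme
from .io import LabeledRecording, read_recording
from .synth import make_motion_model, simulate_session

__all__ = ["ExperimentConfig", "run_experiment", "summarize", "export_patterns"]

#: Motion name order used for confusion-matrix headers when there are
#: exactly 11 classes (hand/wrist motion vocabulary; NM = no movement).
MOTION_NAMES_11 = ["HC", "HO", "KG", "TP", "WF", "WE", "RD", "UD", "FS", "FP",
                   "NM"]


@dataclass
class SynthSpec:
    """Synthetic-session parameters (defaults mirror the study protocol at
    reduced per-trial duration)."""

    n_rows: int = 8
    n_cols: int = 24
    ied_mm: float = 10.0
    n_motions: int = 11
    n_sources: int = 3
    n_trials: int = 3
    duration_s: float = 2.0
    fs: float = 2048.0
    spread_mm: float = 15.0
    noise_sd: float = 0.3


@dataclass
class ExperimentConfig:
    """Everything needed to rerun one evaluation exactly."""

    seed: int = 0
    input_path: "str | None" = None         # mutually exclusive with synth
    synth: "SynthSpec | None" = field(default_factory=SynthSpec)
    features: list = field(default_factory=lambda: list(FEATURE_KINDS))
    schemes: list = field(
        default_factory=lambda: ["ST", "SL", "ST1", "ST2", "SL1", "SL2"])
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    cv_folds: int = 5
    cv_grouping: str = "window"
    with_rcs: bool = True
    out_dir: str = "results"

    def validate(self) -> None:
        for f in self.features:
            if f not in FEATURE_KINDS:
                raise InvalidArgumentError(f"unknown feature set {f!r}")
        for s in self.schemes:
            if s.upper() not in SHIFT_SCHEME_NAMES:
                raise InvalidArgumentError(f"unknown shift scheme {s!r}")
        if self.input_path is None and self.synth is None:
            raise InvalidArgumentError("need an input path or a synth spec")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kwargs = dict(raw)
        if "synth" in kwargs and kwargs["synth"] is not None:
            kwargs["synth"] = SynthSpec(**kwargs["synth"])
        if "windowing" in kwargs:
            kwargs["windowing"] = WindowingConfig(**kwargs["windowing"])
        if "classifier" in kwargs:
            kwargs["classifier"] = ClassifierSpec(**kwargs["classifier"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_or_simulate(config: ExperimentConfig) -> LabeledRecording:
    if config.input_path is not None:
        return read_recording(config.input_path)
    s = config.synth
    grid = build_grid(s.n_rows, s.n_cols, s.ied_mm)
    model = make_motion_model(
        grid, n_motions=s.n_motions, n_sources=s.n_sources, seed=config.seed,
        spread_mm=s.spread_mm, noise_sd=s.noise_sd,
    )
    return simulate_session(model, n_trials=s.n_trials,
                            duration_s=s.duration_s, fs=s.fs,
                            seed=config.seed + 1)


def _motion_names(n: int) -> list[str]:
    return MOTION_NAMES_11 if n == 11 else [f"M{i}" for i in range(n)]


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the full features x schemes evaluation and write result tables.

    Writes to ``config.out_dir``: ``accuracy.csv`` (one row per evaluation,
    with RCS where defined), per-evaluation confusion matrices, CSP pattern
    maps as grid-shaped CSVs, and ``manifest.json`` recording the config,
    its hash, the seed and package versions.  Returns the accuracy table.
    Errors in one (feature, scheme) cell are recorded in the table and do
    not discard completed cells.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recording = _load_or_simulate(config)
    names = _motion_names(len(np.unique(recording.labels)))

    rows = []
    errors = []
    window_cache: dict = {}
    for kind in config.features:
        spec = FeatureSpec(kind=kind)
        for scheme_name in config.schemes:
            scheme = make_shift_scheme(recording.grid, scheme_name)
            try:
                ev = evaluate_shift(
                    recording, scheme, spec,
                    classifier_spec=config.classifier,
                    windowing=config.windowing,
                    cv_folds=config.cv_folds,
                    cv_grouping=config.cv_grouping,
                    seed=config.seed,
                    with_rcs=config.with_rcs,
                    window_cache=window_cache,
                )
            except Exception as exc:  # keep partial results
                errors.append({"feature": kind, "scheme": scheme_name,
                               "error": f"{type(exc).__name__}: {exc}"})
                continue
            rows.append({
                "feature": kind,
                "scheme": scheme.name,
                "accuracy": ev.accuracy,
                "n_train": ev.n_train,
                "n_test": ev.n_test,
                "rcs": np.nan if ev.rcs is None else ev.rcs,
            })
            conf = pd.DataFrame(ev.confusion,
                                index=[names[i] for i in ev.class_labels],
                                columns=[names[i] for i in ev.class_labels])
            conf.to_csv(out / f"confusion_{kind}_{scheme.name}.csv")
            if kind.startswith("CSP") and not scheme.is_control:
                _write_pattern_maps(out, recording, scheme, spec, kind)

    table = pd.DataFrame(
        rows, columns=["feature", "scheme", "accuracy", "n_train", "n_test",
                       "rcs"])
    table.to_csv(out / "accuracy.csv", index=False, float_format="%.10g")
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "errors": errors,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table


def _partition_shape(scheme) -> tuple[int, int]:
    grid = scheme.grid
    if scheme.axis == "transversal":
        return grid.n_rows, grid.n_cols // 2
    if scheme.axis == "longitudinal":
        return grid.n_rows // 2, grid.n_cols
    return grid.n_rows, grid.n_cols


def _write_pattern_maps(out, recording, scheme, spec, kind) -> None:
    """Export selected CSP patterns reshaped onto the partition grid.

    OvO: the *last* pattern (max-variance filter of the second class) per
    bank; OvR: the *first* pattern (max-variance filter of the active class)
    per class.
    """
    ws = segment(recording, channels=scheme.train_channels)
    pipeline = make_pipeline(spec, recording.grid).fit(ws)
    shape = _partition_shape(scheme)
    pat_dir = out / "patterns"
    pat_dir.mkdir(exist_ok=True)
    for bank in pipeline.model.banks:
        pats = spatial_patterns(bank)
        col = 1 if pipeline.model.scheme == "OvO" else 0
        j, k = bank.class_pair
        tag = f"{kind}_{scheme.name}_class{j}v{'R' if k < 0 else k}"
        np.savetxt(pat_dir / f"{tag}.csv", pats[:, col].reshape(shape),
                   delimiter=",", fmt="%.6g")


def summarize(csv_paths: "list[str | Path]") -> pd.DataFrame:
    """Average accuracy/RCS tables from several runs (e.g. several seeds)."""
    frames = [pd.read_csv(p) for p in csv_paths]
    allruns = pd.concat(frames, ignore_index=True)
    return (allruns.groupby(["feature", "scheme"], as_index=False)
            .agg(accuracy=("accuracy", "mean"),
                 accuracy_sd=("accuracy", "std"),
                 rcs=("rcs", "mean"),
                 n_runs=("accuracy", "size")))


def export_patterns(recording: LabeledRecording, scheme_name: str,
                    kind: str, out_dir: "str | Path",
                    png: bool = True) -> list[Path]:
    """Fit CSP on a scheme's training partition and export pattern maps.

    Writes one grid-shaped CSV per (bank, selected filter) and, optionally,
    a PNG heat map normalized to [-1, 1].
    """
    scheme = make_shift_scheme(recording.grid, scheme_name)
    spec = FeatureSpec(kind=kind)
    ws = segment(recording, channels=scheme.train_channels)
    pipeline = make_pipeline(spec, recording.grid).fit(ws)
    shape = _partition_shape(scheme)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for bank in pipeline.model.banks:
        pats = spatial_patterns(bank)
        j, k = bank.class_pair
        for col, side in ((0, "first"), (1, "last")):
            grid_map = pats[:, col].reshape(shape)
            tag = f"{kind}_{scheme.name}_class{j}v{'R' if k < 0 else k}_{side}"
            path = out / f"{tag}.csv"
            np.savetxt(path, grid_map, delimiter=",", fmt="%.6g")
            written.append(path)
            if png:
                import matplotlib
                matplotlib.use("Agg")
                import matplotlib.pyplot as plt

                fig, ax = plt.subplots(figsize=(6, 2.5))
                im = ax.imshow(grid_map, cmap="RdBu_r", vmin=-1, vmax=1,
                               aspect="equal")
                ax.set_title(tag)
                fig.colorbar(im, ax=ax, shrink=0.8)
                fig.savefig(out / f"{tag}.png", dpi=120,
                            bbox_inches="tight")
                plt.close(fig)
                written.append(out / f"{tag}.png")
    return written
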