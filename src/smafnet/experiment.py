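"""End-to-end reproducible experiments: simulate/load -> split -> train -> eval.

The transfer protocol mirrors how the fixed architecture is applied to
multiple adulterant datasets: one binary dataset per colorant (pure samples
plus samples adulterated with that colorant), each SPXY-split at the same
ratio, each trained from a fresh seed-fixed initialization of the *same*
architecture (structure transfers, weights do not), each evaluated on its own
validation split.

Every run writes, per dataset, a metrics JSON (rounded metrics + raw
confusion counts) and, once per run, the fully resolved configuration and a
log recording seed, package version and per-stage timing.  Metric and config
files are deterministic; only the log contains wall-clock times.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .metrics import evaluate, write_metrics_json
from .model import SMAFNetConfig, save_checkpoint
from .spectra import SpectraSet, read_spectra_csv
from .spxy import spxy_split
from .synth import SyntheticDesign, generate_dataset
from .training import TrainConfig, train_model

__all__ = ["ExperimentConfig", "run_experiment", "load_experiment_yaml"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun one experiment bit-identically."""

    design: SyntheticDesign | None = None
    data_csv: str | None = None
    split_ratio: float = 0.75
    model: SMAFNetConfig = field(default_factory=SMAFNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    datasets: tuple[tuple[str, str], ...] = (
        ("sunset_yellow", "sunset_yellow"),
        ("tartrazine", "tartrazine"),
        ("ponceau_4r", "ponceau_4r"),
    )
    out_dir: str = "runs/experiment"

    def __post_init__(self) -> None:
        if (self.design is None) == (self.data_csv is None):
            raise ValueError("provide exactly one of design / data_csv")
        names = [name for name, _ in self.datasets]
        if len(names) != len(set(names)):
            raise ValueError("dataset names must be unique")


def _resolved_config(cfg: ExperimentConfig) -> dict:
    out = {
        "split_ratio": cfg.split_ratio,
        "model": cfg.model.to_dict(),
        "train": cfg.train.__dict__,
        "datasets": [list(pair) for pair in cfg.datasets],
        "out_dir": cfg.out_dir,
    }
    if cfg.design is not None:
        d = {k: v for k, v in cfg.design.__dict__.items() if k != "wavelengths"}
        d["concentrations"] = list(d["concentrations"])
        d["colorants"] = list(d["colorants"])
        d["colorant_band"] = {k: list(v) for k, v in d["colorant_band"].items()}
        d["band_centers"] = list(d["band_centers"])
        d["band_widths"] = list(d["band_widths"])
        d["band_amplitudes"] = list(d["band_amplitudes"])
        d["wavelengths"] = [float(w) for w in cfg.design.wavelengths]
        out["design"] = d
    else:
        out["data_csv"] = cfg.data_csv
    return out


def run_experiment(cfg: ExperimentConfig) -> dict[str, dict]:
    """Run the full per-colorant protocol; returns {name: metrics payload}.

    Side effects: writes ``<out_dir>/config.json``, ``<out_dir>/run.log`` and,
    per dataset, ``<name>_metrics.json`` and ``<name>_model.npz``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"smafnet {__version__} experiment, seed={cfg.train.seed}"]
    t0 = time.perf_counter()

    if cfg.design is not None:
        data = generate_dataset(cfg.design)
        log_lines.append(f"simulate: N={data.n_samples} [{time.perf_counter() - t0:.2f}s]")
    else:
        data = read_spectra_csv(cfg.data_csv)
        log_lines.append(f"load: N={data.n_samples} [{time.perf_counter() - t0:.2f}s]")

    (out_dir / "config.json").write_text(
        json.dumps(_resolved_config(cfg), indent=2, sort_keys=True) + "\n"
    )

    results: dict[str, dict] = {}
    for name, tag in cfg.datasets:
        t1 = time.perf_counter()
        subset = data.filter_colorant(tag)
        if len(set(subset.labels.tolist())) < 2:
            raise ValueError(f"dataset {name!r} does not contain both classes")
        split = spxy_split(subset, cfg.split_ratio)
        cal = subset.subset(split.calibration_idx)
        val = subset.subset(split.validation_idx)
        model, _ = train_model(cfg.model, cfg.train, cal, val)
        cm, report = evaluate(model, val)
        write_metrics_json(cm, report, out_dir / f"{name}_metrics.json")
        save_checkpoint(model, out_dir / f"{name}_model.npz")
        results[name] = {
            "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
            "metrics": report.rounded().to_dict(),
            "n_calibration": len(split.calibration_idx),
            "n_validation": len(split.validation_idx),
        }
        log_lines.append(
            f"{name}: cal={len(split.calibration_idx)} val={len(split.validation_idx)} "
            f"acc={report.rounded().acc} [{time.perf_counter() - t1:.2f}s]"
        )

    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return results


def load_experiment_yaml(path: str | Path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file.

    Recognized top-level keys: ``design`` (SyntheticDesign fields),
    ``data_csv``, ``split_ratio``, ``model`` (SMAFNetConfig nesting),
    ``train`` (TrainConfig fields), ``datasets`` (list of [name, colorant]),
    ``out_dir``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "design" in raw:
        d = dict(raw["design"])
        for key in ("colorants", "concentrations", "band_centers", "band_widths", "band_amplitudes"):
            if key in d:
                d[key] = tuple(d[key])
        if "colorant_band" in d:
            d["colorant_band"] = {k: tuple(v) for k, v in d["colorant_band"].items()}
        kwargs["design"] = SyntheticDesign(**d)
    if "data_csv" in raw:
        kwargs["data_csv"] = raw["data_csv"]
    if "split_ratio" in raw:
        kwargs["split_ratio"] = float(raw["split_ratio"])
    if "model" in raw:
        kwargs["model"] = SMAFNetConfig.from_dict(raw["model"])
    if "train" in raw:
        kwargs["train"] = TrainConfig(**raw["train"])
    if "datasets" in raw:
        kwargs["datasets"] = tuple((str(a), str(b)) for a, b in raw["datasets"])
    if "out_dir" in raw:
        kwargs["out_dir"] = raw["out_dir"]
    return ExperimentConfig(**kwargs)
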