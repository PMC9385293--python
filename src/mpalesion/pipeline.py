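"""End-to-end orchestration: generate -> denoise/resize -> segment -> select -> classify -> evaluate.

A single :class:`PipelineConfig` holds every stage's settings plus one master
seed; each stage derives its own seed as a stable hash of (master seed, stage
name), so any stage can be re-run independently and deterministically.  Every
intermediate artifact (filtered stacks, predicted masks, selected wavelengths,
trained models, the evaluation report and a seed/version manifest) is written
to the run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import RnnConfig, predict, rnn_train, save_model, stack_to_sequence
from .evaluation import EvalReport, build_report, train_test_split
from .preprocess import BilateralParams, filter_stack, resize_bilinear
from .psaco import PsacoConfig, run_psaco_feature_selection
from .segmentation import (
    LedNetConfig,
    dice_coefficient,
    save_segmenter,
    segment,
    train_segmenter,
)
from .synthetic_data import (
    CANCER,
    LabeledStack,
    PhantomConfig,
    generate_dataset,
    make_spectral_profiles,
    save_labeled_stack,
)

__all__ = [
    "PipelineConfig",
    "SegmenterSettings",
    "ConfigError",
    "derive_seed",
    "load_config",
    "save_config",
    "run_pipeline",
]

log = logging.getLogger("mpalesion.pipeline")


class ConfigError(ValueError):
    """Invalid or unknown configuration entries (all offenses listed)."""


@dataclass(frozen=True)
class SegmenterSettings:
    """Segmentation-stage settings: network shape plus training budget."""

    in_channels: int = 8
    base_channels: int = 16
    n_ssnbt_per_stage: int = 2
    n_downsamples: int = 2
    n_steps: int = 300
    lr: float = 0.5

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        LedNetConfig(
            in_channels=self.in_channels,
            base_channels=self.base_channels,
            n_ssnbt_per_stage=self.n_ssnbt_per_stage,
            n_downsamples=self.n_downsamples,
        )

    def to_net_config(self, seed: int) -> LedNetConfig:
        return LedNetConfig(
            in_channels=self.in_channels,
            base_channels=self.base_channels,
            n_ssnbt_per_stage=self.n_ssnbt_per_stage,
            n_downsamples=self.n_downsamples,
            seed=seed,
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one reproducible end-to-end run."""

    n_specimens: int = 40
    class_balance: float = 0.5
    effect_size: float = 3.0
    train_fraction: float = 0.7
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    height_range: tuple[int, int] | None = None
    bilateral: BilateralParams = field(default_factory=BilateralParams)
    segmenter: SegmenterSettings = field(default_factory=SegmenterSettings)
    psaco: PsacoConfig = field(default_factory=lambda: PsacoConfig(k=8))
    rnn: RnnConfig = field(default_factory=RnnConfig)
    save_intermediates: bool = True

    def __post_init__(self) -> None:
        if self.n_specimens < 2:
            raise ValueError("n_specimens must be >= 2")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must lie in (0, 1)")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 from the master seed and stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


# ---------------------------------------------------------------------------
# Config file handling
# ---------------------------------------------------------------------------

_TUPLE_FIELDS = {
    "lesion_radius_range": float,
    "height_range": int,
}

_SECTIONS = {
    "phantom": PhantomConfig,
    "bilateral": BilateralParams,
    "segmenter": SegmenterSettings,
    "psaco": PsacoConfig,
    "rnn": RnnConfig,
}


def _build_section(cls, data: dict, section: str, errors: list[str]):
    allowed = set(cls.__dataclass_fields__)
    clean = {}
    for key, value in data.items():
        if key not in allowed:
            errors.append(f"{section}.{key}: unknown key")
            continue
        if key in _TUPLE_FIELDS and value is not None:
            value = tuple(_TUPLE_FIELDS[key](v) for v in value)
        clean[key] = value
    try:
        return cls(**clean)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return cls()


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; an empty file gives all defaults.

    All offending keys/values are reported together in a single
    :class:`ConfigError`.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    errors: list[str] = []
    top: dict = {}
    top_allowed = set(PipelineConfig.__dataclass_fields__) - set(_SECTIONS)
    for key, value in raw.items():
        if key in _SECTIONS:
            top[key] = _build_section(_SECTIONS[key], value or {}, key, errors)
        elif key in top_allowed:
            if key in _TUPLE_FIELDS and value is not None:
                value = tuple(_TUPLE_FIELDS[key](v) for v in value)
            top[key] = value
        else:
            errors.append(f"{key}: unknown key")
    config = None
    try:
        config = PipelineConfig(**top)
    except (TypeError, ValueError) as exc:
        errors.append(str(exc))
    if errors:
        raise ConfigError("; ".join(errors))
    log.info("loaded config: %s", asdict_config(config))
    return config


def asdict_config(config: PipelineConfig) -> dict:
    d = asdict(config)
    for prof in ("spectral_profile_cancer", "spectral_profile_normal"):
        if d["phantom"][prof] is not None:
            d["phantom"][prof] = np.asarray(d["phantom"][prof]).tolist()
    d["phantom"]["lesion_radius_range"] = list(d["phantom"]["lesion_radius_range"])
    if d["height_range"] is not None:
        d["height_range"] = list(d["height_range"])
    return d


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict_config(config), sort_keys=False))


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------

class _Stage:
    """Context wrapper attaching the stage name to any error and timing it."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"pipeline stage '{self.name}' failed: {exc}") from exc
        self.elapsed = time.perf_counter() - self.t0
        return False


def _label_int(label: str) -> int:
    return 1 if label == CANCER else 0


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> tuple[EvalReport, Path | None]:
    """Execute all stages on generated phantoms and return the evaluation report.

    Artifacts (every stage's outputs plus a manifest of seeds, shapes and the
    package version) are written under ``outdir`` when given and
    ``config.save_intermediates`` is true.
    """
    out = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
    seeds = {s: derive_seed(config.seed, s) for s in
             ("generate", "split", "segment", "select", "classify")}
    manifest: dict = {
        "version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "config": asdict_config(config),
    }

    # -- generate ----------------------------------------------------------
    with _Stage("generate") as st:
        phantom = config.phantom
        if phantom.spectral_profile_cancer is None:
            cancer_prof, normal_prof = make_spectral_profiles(
                phantom.n_wavelengths, config.effect_size, phantom.noise_sigma
            )
            phantom = replace(
                phantom,
                spectral_profile_cancer=cancer_prof,
                spectral_profile_normal=normal_prof,
            )
        data = generate_dataset(
            config.n_specimens, phantom, config.class_balance,
            seed=seeds["generate"], height_range=config.height_range,
        )
    labels = [d.label for d in data]
    log.info("generate: n=%d shapes=%s..%s [%.2fs]", len(data),
             data[0].shape, data[-1].shape, st.elapsed)

    # -- preprocess --------------------------------------------------------
    with _Stage("preprocess") as st:
        target = (phantom.height, phantom.width)
        processed: list[LabeledStack] = []
        for d in data:
            filtered = filter_stack(d.stack, config.bilateral)
            resized = resize_bilinear(filtered, target)
            mask = resize_bilinear(d.mask.astype(float), target) > 0.5
            processed.append(LabeledStack(resized, mask, d.label, d.seed))
    log.info("preprocess: %d stacks -> %s [%.2fs]", len(processed), target, st.elapsed)

    # -- split -------------------------------------------------------------
    with _Stage("split"):
        train_idx, test_idx = train_test_split(
            processed, labels, config.train_fraction, seed=seeds["split"]
        )
    log.info("split: %d train / %d test", len(train_idx), len(test_idx))

    # -- segment -----------------------------------------------------------
    with _Stage("segment") as st:
        net_cfg = config.segmenter.to_net_config(seeds["segment"])
        seg_model = train_segmenter(
            [processed[i] for i in train_idx], net_cfg,
            n_steps=config.segmenter.n_steps, lr=config.segmenter.lr,
        )
        pred_masks = []
        dices = []
        for d in processed:
            pm = segment(d, seg_model) > 0.5
            if pm.sum() == 0:  # degenerate prediction: fall back to whole image
                pm = np.ones_like(pm)
            pred_masks.append(pm)
            dices.append(dice_coefficient(pm, d.mask))
    manifest["train_dice_mean"] = float(np.mean([dices[i] for i in train_idx]))
    manifest["test_dice_mean"] = float(np.mean([dices[i] for i in test_idx]))
    log.info("segment: %d steps, final loss %.4f, mean dice %.3f [%.2fs]",
             config.segmenter.n_steps,
             seg_model.loss_history[-1] if seg_model.loss_history else float("nan"),
             float(np.mean(dices)), st.elapsed)

    # -- select ------------------------------------------------------------
    with _Stage("select") as st:
        features = np.stack([
            d.stack[pm].mean(axis=0) for d, pm in zip(processed, pred_masks)
        ])  # per-wavelength mean inside the predicted lesion mask
        y = np.array([_label_int(l) for l in labels])
        psaco_cfg = replace(config.psaco, seed=seeds["select"])
        selected, history = run_psaco_feature_selection(
            features[train_idx], y[train_idx], psaco_cfg
        )
    log.info("select: %d/%d wavelengths, best fitness %.3f [%.2fs]",
             selected.size, features.shape[1], history[-1], st.elapsed)

    # -- classify ----------------------------------------------------------
    with _Stage("classify") as st:
        sequences = [
            stack_to_sequence(d.stack, pm, selected)
            for d, pm in zip(processed, pred_masks)
        ]
        rnn_cfg = replace(config.rnn, input_size=2, seed=seeds["classify"])
        rnn_model = rnn_train(
            [(sequences[i], int(y[i])) for i in train_idx], rnn_cfg
        )
        pred_test, probs_test = predict([sequences[i] for i in test_idx], rnn_model)
    log.info("classify: %d epochs, final train acc %.3f [%.2fs]",
             rnn_cfg.epochs,
             rnn_model.accuracy_history[-1] if rnn_model.accuracy_history else float("nan"),
             st.elapsed)

    # -- evaluate ----------------------------------------------------------
    with _Stage("evaluate"):
        truths = np.array([labels[i] for i in test_idx])
        names = np.array([NORMAL_NAME, CANCER_NAME])
        preds = names[pred_test]
        scores = probs_test[:, 1]  # P(cancer)
        report = build_report(preds, truths, scores=scores, positive=CANCER_NAME)
    log.info("evaluate: accuracy %.1f%% auc %.3f", report.accuracy, report.auc)

    if out is not None and config.save_intermediates:
        stacks_dir = out / "stacks"
        for i, (d, pm) in enumerate(zip(processed, pred_masks)):
            save_labeled_stack(d, stacks_dir / f"specimen_{i:03d}")
            from PIL import Image

            Image.fromarray((pm * 255).astype(np.uint8)).save(
                stacks_dir / f"specimen_{i:03d}_predmask.png"
            )
        save_segmenter(seg_model, out / "segmenter.json")
        save_model(rnn_model, out / "rnn.json")
        json.dump(
            {"selected_wavelengths": selected.tolist()},
            (out / "selected.json").open("w"),
        )
        pd.DataFrame({"iteration": range(len(history)), "finalbest_fitness": history}).to_csv(
            out / "psaco_history.csv", index=False
        )
        pd.DataFrame({
            "epoch": range(len(rnn_model.loss_history)),
            "loss": rnn_model.loss_history,
            "train_accuracy": rnn_model.accuracy_history,
        }).to_csv(out / "rnn_history.csv", index=False)
        report.to_csv(out / "report.csv")
        report.to_json(out / "report.json")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report, out


CANCER_NAME = CANCER
NORMAL_NAME = "normal"
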