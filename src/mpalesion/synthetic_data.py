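"""Seeded synthetic multispectral photoacoustic phantoms and benchmark problems.

A phantom is an H x W x Lambda intensity stack: one 2-D image per excitation
wavelength, so each pixel carries an absorption spectrum.  A single elliptical
lesion is embedded in a spectrally flat background; lesion pixels carry a
class-specific smooth absorption profile (cancer vs. normal differ in a
secondary absorption bump), then multiplicative speckle and additive Gaussian
noise are applied — the standard first-order noise model for ultrasound-derived
images.  The generator is a pure function of (config, seed) so every
downstream stage of the pipeline is testable without any external data.

The module also generates abstract feature-selection problems (class-shifted
Gaussian columns with a known informative support) used to benchmark the
hybrid swarm/colony wavelength selector against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "PhantomConfig",
    "LabeledStack",
    "FeatureSelectionProblem",
    "make_spectral_profiles",
    "generate_phantom",
    "generate_dataset",
    "generate_feature_selection_problem",
    "save_labeled_stack",
    "load_labeled_stack",
    "save_feature_problem",
    "load_feature_problem",
]

CANCER = "cancer"
NORMAL = "normal"

#: Flat background absorption level (arbitrary units in [0, 1]).
BACKGROUND_LEVEL = 0.2


def make_spectral_profiles(
    n_wavelengths: int,
    effect_size: float = 3.0,
    noise_sigma: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Build default (cancer, normal) mean-absorption profiles.

    Both classes share a smooth Gaussian absorption bump (peak at 35% of the
    wavelength axis, amplitude 0.6 above background) that separates lesion
    from background.  The cancer class adds a second bump at 65% of the axis
    whose amplitude is ``effect_size * noise_sigma``, so the per-pixel,
    per-wavelength standardized mean difference between the classes at the
    discriminative wavelengths equals ``effect_size``.  ``effect_size=0``
    yields identical classes (a null dataset for sanity checks).

    Returns
    -------
    (cancer, normal) : pair of length-``n_wavelengths`` arrays in [0, 1].
    """
    lam = np.arange(n_wavelengths, dtype=float)
    center = 0.35 * max(n_wavelengths - 1, 1)
    width = max(n_wavelengths / 8.0, 1.0)
    base = BACKGROUND_LEVEL + 0.6 * np.exp(-0.5 * ((lam - center) / width) ** 2)

    center2 = 0.65 * max(n_wavelengths - 1, 1)
    delta = effect_size * noise_sigma * np.exp(-0.5 * ((lam - center2) / width) ** 2)

    normal = np.clip(base, 0.0, 1.0)
    cancer = np.clip(base + delta, 0.0, 1.0)
    return cancer, normal


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, optics and noise of a single synthetic specimen.

    Parameters
    ----------
    height, width : image extent in pixels.
    n_wavelengths : number of excitation wavelengths Lambda (default 200).
    lesion_radius_range : (min, max) semi-axis length of the elliptical
        lesion, pixels.
    spectral_profile_cancer, spectral_profile_normal : length-Lambda mean
        absorption profiles in [0, 1] for lesion pixels of each class.
        ``None`` selects the default bump profiles of
        :func:`make_spectral_profiles`.
    noise_sigma : std of additive Gaussian intensity noise (>= 0).
    speckle_strength : multiplicative speckle scale s in ``I*(1+s*u)``,
        u standard normal (dimensionless, >= 0).
    label : class of the lesion, ``"cancer"`` or ``"normal"``.
    seed : generator seed used when no explicit rng is supplied.
    """

    height: int = 64
    width: int = 64
    n_wavelengths: int = 200
    lesion_radius_range: tuple[float, float] = (6.0, 14.0)
    spectral_profile_cancer: np.ndarray | None = None
    spectral_profile_normal: np.ndarray | None = None
    noise_sigma: float = 0.05
    speckle_strength: float = 0.05
    label: str = CANCER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("phantom extent must be at least 2x2 pixels")
        if self.n_wavelengths < 1:
            raise ValueError("n_wavelengths must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.speckle_strength < 0:
            raise ValueError("speckle_strength must be >= 0")
        if self.label not in (CANCER, NORMAL):
            raise ValueError(f"label must be {CANCER!r} or {NORMAL!r}, got {self.label!r}")
        rmin, rmax = self.lesion_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("lesion_radius_range must satisfy 0 < min <= max")
        half_extent = min(self.height, self.width) / 2.0
        if rmax >= half_extent:
            raise ValueError(
                f"max lesion radius {rmax} exceeds image half-extent {half_extent}"
            )
        for name in ("spectral_profile_cancer", "spectral_profile_normal"):
            prof = getattr(self, name)
            if prof is not None and len(np.asarray(prof)) != self.n_wavelengths:
                raise ValueError(f"{name} must have length n_wavelengths")

    def profiles(self) -> tuple[np.ndarray, np.ndarray]:
        """Resolved (cancer, normal) profiles as float arrays."""
        if self.spectral_profile_cancer is None or self.spectral_profile_normal is None:
            return make_spectral_profiles(self.n_wavelengths, noise_sigma=self.noise_sigma)
        return (
            np.asarray(self.spectral_profile_cancer, dtype=float),
            np.asarray(self.spectral_profile_normal, dtype=float),
        )


@dataclass
class LabeledStack:
    """A specimen: H x W x Lambda stack, binary lesion mask, class label."""

    stack: np.ndarray
    mask: np.ndarray
    label: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.stack.ndim != 3:
            raise ValueError("stack must be H x W x Lambda")
        if self.mask.shape != self.stack.shape[:2]:
            raise ValueError("mask shape must match stack spatial shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.stack.shape  # type: ignore[return-value]


@dataclass
class FeatureSelectionProblem:
    """n x d feature matrix with binary labels and known informative support."""

    X: np.ndarray
    y: np.ndarray
    support_true: np.ndarray
    effect_size: float = float("nan")

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.support_true = np.asarray(sorted(self.support_true), dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on n")
        if self.support_true.size > self.X.shape[1]:
            raise ValueError("support larger than feature count")


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig, rng: np.random.Generator | None = None) -> LabeledStack:
    """Generate one labelled phantom stack.

    Lesion pixels carry the class mean-absorption profile, background pixels
    the flat baseline; speckle is applied multiplicatively and Gaussian noise
    additively, per voxel.  Deterministic given (config, rng state).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w, lam = config.height, config.width, config.n_wavelengths
    cancer_prof, normal_prof = config.profiles()
    lesion_profile = cancer_prof if config.label == CANCER else normal_prof

    rmin, rmax = config.lesion_radius_range
    a = rng.uniform(rmin, rmax)
    b = rng.uniform(rmin, rmax)
    margin_r = max(a, b)
    cy = rng.uniform(margin_r, h - 1 - margin_r)
    cx = rng.uniform(margin_r, w - 1 - margin_r)
    angle = rng.uniform(0.0, np.pi)
    mask = _ellipse_mask((h, w), (cy, cx), (a, b), angle)

    stack = np.full((h, w, lam), BACKGROUND_LEVEL, dtype=float)
    stack[mask] = lesion_profile

    if config.speckle_strength > 0:
        stack = stack * (1.0 + config.speckle_strength * rng.standard_normal(stack.shape))
    if config.noise_sigma > 0:
        stack = stack + config.noise_sigma * rng.standard_normal(stack.shape)

    return LabeledStack(stack=stack, mask=mask, label=config.label, seed=config.seed)


def generate_dataset(
    n: int,
    config: PhantomConfig,
    class_balance: float = 0.5,
    seed: int = 0,
    height_range: tuple[int, int] | None = None,
) -> list[LabeledStack]:
    """Generate ``n`` phantoms, ``round(n * class_balance)`` of them cancer.

    ``height_range`` (e.g. ``(20, 64)``) draws a per-specimen height uniformly
    from the closed integer range, emulating acquisition stacks of non-uniform
    extent that downstream resizing must normalise; lesion radii are clamped
    to fit the drawn extent.  Both classes must be represented, so
    ``class_balance`` may not round to 0 or n.
    """
    if n < 2:
        raise ValueError("need at least two specimens")
    if not (0.0 < class_balance < 1.0):
        raise ValueError("class_balance must lie strictly between 0 and 1")
    n_cancer = int(round(n * class_balance))
    if n_cancer < 1 or n_cancer > n - 1:
        raise ValueError("class_balance leaves one class empty")

    rng = np.random.default_rng(seed)
    labels = np.array([CANCER] * n_cancer + [NORMAL] * (n - n_cancer))
    rng.shuffle(labels)

    out: list[LabeledStack] = []
    for i, label in enumerate(labels):
        cfg = replace(config, label=str(label))
        if height_range is not None:
            lo, hi = height_range
            h = int(rng.integers(lo, hi + 1))
            rmin, rmax = cfg.lesion_radius_range
            limit = min(h, cfg.width) / 2.0 - 1.0
            cfg = replace(
                cfg,
                height=h,
                lesion_radius_range=(min(rmin, limit), min(rmax, limit)),
            )
        out.append(generate_phantom(cfg, rng))
    return out


def generate_feature_selection_problem(
    n: int,
    d: int,
    k_informative: int,
    effect_size: float,
    seed: int = 0,
) -> FeatureSelectionProblem:
    """Class-shifted Gaussian benchmark with a known informative support.

    All d columns are unit-variance Gaussian noise; for the ``k_informative``
    columns of the (recorded) true support, class-1 rows are shifted by
    ``effect_size``, i.e. the standardized mean difference equals the stated
    effect size.  Labels are balanced and shuffled.
    """
    if not (1 <= k_informative <= d):
        raise ValueError("need 1 <= k_informative <= d")
    if n < 4:
        raise ValueError("need n >= 4")
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    rng.shuffle(y)
    X = rng.standard_normal((n, d))
    support = np.sort(rng.choice(d, size=k_informative, replace=False))
    X[np.ix_(y == 1, support)] += effect_size
    return FeatureSelectionProblem(X=X, y=y, support_true=support, effect_size=effect_size)


# ---------------------------------------------------------------------------
# Disk formats: multi-page TIFF (one page per wavelength) + JSON sidecar;
# masks as PNG; feature problems as CSV with a label column.
# ---------------------------------------------------------------------------

def save_labeled_stack(item: LabeledStack, path: str | Path) -> None:
    """Write ``<path>.tiff`` (pages = wavelengths), ``<path>.json``, ``<path>_mask.png``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path.with_suffix(".tiff"),
        item.stack.transpose(2, 0, 1).astype(np.float32),
        photometric="minisblack",
    )
    sidecar = {"label": item.label, "seed": item.seed, "shape": list(item.shape)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    Image.fromarray((item.mask * 255).astype(np.uint8)).save(
        path.parent / f"{path.stem}_mask.png"
    )


def load_labeled_stack(path: str | Path) -> LabeledStack:
    path = Path(path)
    pages = tifffile.imread(path.with_suffix(".tiff"))
    if pages.ndim == 2:
        pages = pages[None]
    stack = np.asarray(pages, dtype=float).transpose(1, 2, 0)
    meta = json.loads(path.with_suffix(".json").read_text())
    mask = np.asarray(Image.open(path.parent / f"{path.stem}_mask.png")) > 0
    return LabeledStack(stack=stack, mask=mask, label=meta["label"], seed=meta.get("seed"))


def save_feature_problem(problem: FeatureSelectionProblem, path: str | Path) -> None:
    """CSV with header f0..f{d-1} and a trailing ``label`` column; support in a sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = problem.X.shape[1]
    df = pd.DataFrame(problem.X, columns=[f"f{j}" for j in range(d)])
    df["label"] = problem.y
    df.to_csv(path, index=False)
    sidecar = {"support_true": problem.support_true.tolist(), "effect_size": problem.effect_size}
    path.with_suffix(".support.json").write_text(json.dumps(sidecar))


def load_feature_problem(path: str | Path) -> FeatureSelectionProblem:
    path = Path(path)
    df = pd.read_csv(path)
    y = df.pop("label").to_numpy()
    support: list[int] = []
    effect = float("nan")
    sidecar = path.with_suffix(".support.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        support = meta.get("support_true", [])
        effect = meta.get("effect_size", float("nan"))
    return FeatureSelectionProblem(
        X=df.to_numpy(), y=y, support_true=np.asarray(support, dtype=int), effect_size=effect
    )
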