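"""Synthetic ER-IHC field generator with exact ground truth.

Emulates what a 20x high-power field of an estrogen-receptor IHC slide looks
like to the downstream pipeline: elliptical nuclei in two stain families —
hematoxylin-counterstained negatives (blue/purple hue, moderate brightness)
and DAB-stained positives (brown hue) at three darkness levels (weak pale,
moderate, strong dark) — on a warm bright background, with per-pixel color
jitter and additive Gaussian sensor noise. Colors are sampled in HSV on the
0-255 scale used by the positive/negative classifier and converted to RGB, so
the default palette is consistent with the wH/wV decision thresholds.

Coordinates are 0-based pixels, x = column, y = row. All randomness flows
from the seed in :class:`SceneSpec`; a fixed spec yields a byte-identical
image and ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import hsv2rgb
from skimage.draw import ellipse as draw_ellipse

CLASSES = ("N", "W", "M", "S")
POSITIVE_CLASSES = ("W", "M", "S")

DEFAULT_BACKGROUND = (243, 235, 224)  # warm bright field, hue ~24 on 0-255


class PackingError(RuntimeError):
    """Raised when the requested nuclei cannot be packed into the field."""


class AnnotationError(ValueError):
    """Raised for malformed annotation files; carries the offending line."""


@dataclass(frozen=True)
class ClassColorModel:
    """Per-class HSV color distribution, all channels on the 0-255 scale.

    Negatives sit in the blue band (hue ~155); the three positive classes
    share the brown band (hue ~18-22) and differ chiefly in value: weak is
    pale, strong is dark enough to trip the darkness rule of the
    positive/negative classifier.
    """

    mean_hsv: dict = field(default_factory=lambda: {
        "N": (155.0, 95.0, 150.0),
        "W": (22.0, 110.0, 170.0),
        "M": (20.0, 140.0, 110.0),
        "S": (18.0, 165.0, 45.0),
    })
    sd_hsv: dict = field(default_factory=lambda: {
        "N": (6.0, 12.0, 15.0),
        "W": (4.0, 12.0, 12.0),
        "M": (4.0, 12.0, 12.0),
        "S": (4.0, 15.0, 10.0),
    })
    pixel_jitter_hsv: tuple = (2.0, 6.0, 6.0)

    def sample_nucleus_hsv(self, label: str, rng: np.random.Generator) -> np.ndarray:
        mean = np.asarray(self.mean_hsv[label], dtype=float)
        sd = np.asarray(self.sd_hsv[label], dtype=float)
        return mean + sd * rng.standard_normal(3)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field.

    Counts are per stain class; ``radius_range`` bounds the major semi-axis
    of each elliptical nucleus; ``max_overlap_fraction`` caps pairwise
    center-distance overlap 1 - d/(r1+r2); ``noise_sd`` is additive Gaussian
    noise in 8-bit intensity units.
    """

    width: int = 512
    height: int = 512
    n_negative: int = 0
    n_weak: int = 0
    n_moderate: int = 0
    n_strong: int = 0
    radius_range: tuple = (12.0, 20.0)
    max_overlap_fraction: float = 0.1
    background: tuple = DEFAULT_BACKGROUND
    noise_sd: float = 3.0
    seed: int = 0
    color_model: ClassColorModel = field(default_factory=ClassColorModel)

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("field dimensions must be positive")
        for n in self.counts.values():
            if n < 0:
                raise ValueError("per-class counts must be >= 0")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError("radius range must be positive and ordered")
        if not 0 <= self.max_overlap_fraction <= 1:
            raise ValueError("max_overlap_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def counts(self) -> dict:
        return {"N": self.n_negative, "W": self.n_weak,
                "M": self.n_moderate, "S": self.n_strong}

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class Nucleus:
    """One rendered nucleus: integer-pixel centroid, class, ellipse params."""

    x: int
    y: int
    label: str
    r_major: float = 0.0
    r_minor: float = 0.0
    angle: float = 0.0


@dataclass
class SyntheticGroundTruth:
    """Ground-truth nuclei of one field; order matches rendering order."""

    nuclei: list

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) float array of (x, y)."""
        if not self.nuclei:
            return np.zeros((0, 2), dtype=float)
        return np.array([[n.x, n.y] for n in self.nuclei], dtype=float)

    @property
    def labels(self) -> list:
        return [n.label for n in self.nuclei]

    def __len__(self) -> int:
        return len(self.nuclei)


def _place_nuclei(spec: SceneSpec, rng: np.random.Generator) -> list:
    labels = [c for c in CLASSES for _ in range(spec.counts[c])]
    rng.shuffle(labels)
    lo, hi = spec.radius_range
    placed: list[Nucleus] = []
    radii: list[float] = []
    max_attempts = 200 * max(len(labels), 1)
    attempts = 0
    for label in labels:
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise PackingError(
                    f"could not place {len(labels)} nuclei in a "
                    f"{spec.width}x{spec.height} field at max_overlap_fraction="
                    f"{spec.max_overlap_fraction} after {max_attempts} attempts")
            r_major = rng.uniform(lo, hi)
            r_minor = r_major * rng.uniform(0.65, 1.0)
            angle = rng.uniform(0.0, np.pi)
            margin = int(np.ceil(r_major))
            if spec.width - 2 * margin <= 0 or spec.height - 2 * margin <= 0:
                raise PackingError("nucleus radius exceeds field size")
            x = int(rng.integers(margin, spec.width - margin))
            y = int(rng.integers(margin, spec.height - margin))
            r_eff = 0.5 * (r_major + r_minor)
            ok = True
            for other, r_other in zip(placed, radii):
                d = np.hypot(x - other.x, y - other.y)
                if 1.0 - d / (r_eff + r_other) > spec.max_overlap_fraction:
                    ok = False
                    break
            if ok:
                placed.append(Nucleus(x, y, label, r_major, r_minor, angle))
                radii.append(r_eff)
                break
    return placed


def _render_nucleus(img: np.ndarray, nuc: Nucleus, model: ClassColorModel,
                    rng: np.random.Generator) -> None:
    rr, cc = draw_ellipse(nuc.y, nuc.x, nuc.r_minor, nuc.r_major,
                          shape=img.shape[:2], rotation=nuc.angle)
    base = model.sample_nucleus_hsv(nuc.label, rng)
    jitter = np.asarray(model.pixel_jitter_hsv)
    hsv = base[None, :] + jitter[None, :] * rng.standard_normal((rr.size, 3))
    hsv = np.clip(hsv, 0.0, 255.0) / 255.0
    img[rr, cc] = hsv2rgb(hsv[None, :, :])[0] * 255.0


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render one synthetic field.

    Returns an (H, W, 3) uint8 RGB image and the ground truth listing every
    nucleus. Nuclei are placed by bounded rejection sampling; an infeasible
    packing raises :class:`PackingError`.
    """
    rng = np.random.default_rng(spec.seed)
    nuclei = _place_nuclei(spec, rng)
    img = np.empty((spec.height, spec.width, 3), dtype=float)
    img[:] = np.asarray(spec.background, dtype=float)
    for nuc in nuclei:
        _render_nucleus(img, nuc, spec.color_model, rng)
    if spec.noise_sd > 0:
        img += spec.noise_sd * rng.standard_normal(img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, SyntheticGroundTruth(nuclei)


def generate_patchset(n_per_class: int, patch_size: int = 32, seed: int = 0,
                      color_model: ClassColorModel | None = None,
                      radius_range: tuple = (12.0, 20.0),
                      background: tuple = DEFAULT_BACKGROUND,
                      noise_sd: float = 3.0,
                      classes: tuple = CLASSES) -> tuple[np.ndarray, np.ndarray]:
    """Balanced labeled patches, one nucleus centered per patch.

    Returns (patches, labels): a (n_per_class * len(classes), s, s, 3) uint8
    array and a matching array of class labels. Patch i of class c is
    rendered independently but from the single stream seeded by ``seed``, so
    a fixed seed reproduces identical bytes.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be > 0")
    model = color_model or ClassColorModel()
    rng = np.random.default_rng(seed)
    lo, hi = radius_range
    patches = []
    labels = []
    cy = cx = patch_size // 2
    for label in classes:
        for _ in range(n_per_class):
            img = np.empty((patch_size, patch_size, 3), dtype=float)
            img[:] = np.asarray(background, dtype=float)
            r_major = rng.uniform(lo, hi)
            nuc = Nucleus(cx, cy, label, r_major,
                          r_major * rng.uniform(0.65, 1.0),
                          rng.uniform(0.0, np.pi))
            _render_nucleus(img, nuc, model, rng)
            if noise_sd > 0:
                img += noise_sd * rng.standard_normal(img.shape)
            patches.append(np.clip(np.round(img), 0, 255).astype(np.uint8))
            labels.append(label)
    return np.stack(patches), np.array(labels)


def write_annotations(truth: SyntheticGroundTruth, path) -> None:
    """Write centroids + labels as the package's CSV dialect (header x,y,label)."""
    lines = ["x,y,label"]
    for nuc in truth.nuclei:
        lines.append(f"{int(nuc.x)},{int(nuc.y)},{nuc.label}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_annotations(path) -> SyntheticGroundTruth:
    """Read an annotation CSV; malformed rows raise with their line number.

    The label column may be empty (unclassified detections); ellipse
    parameters are not stored in the CSV and come back as zeros.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines()]
    if not lines or lines[0].strip().lower() not in ("x,y,label", "x,y"):
        raise AnnotationError(f"{path}: line 1: expected header 'x,y,label'")
    nuclei = []
    for i, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) not in (2, 3):
            raise AnnotationError(f"{path}: line {i}: expected 'x,y,label', got {ln!r}")
        try:
            x, y = int(parts[0]), int(parts[1])
        except ValueError:
            raise AnnotationError(
                f"{path}: line {i}: non-integer coordinate in {ln!r}") from None
        label = parts[2] if len(parts) == 3 and parts[2] else ""
        if label and label not in CLASSES:
            raise AnnotationError(
                f"{path}: line {i}: unknown label {label!r} (expected one of "
                f"{'/'.join(CLASSES)})")
        nuclei.append(Nucleus(x, y, label))
    return SyntheticGroundTruth(nuclei)


def scene_spec_from_dict(d: dict) -> SceneSpec:
    """Build a SceneSpec from a plain config mapping (CLI YAML/JSON)."""
    known = {f.name for f in dataclasses.fields(SceneSpec)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown SceneSpec keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("radius_range", "background"):
        if key in d:
            d[key] = tuple(d[key])
    return SceneSpec(**d)
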