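"""Synthetic hand-thermogram generator.

Rheumatoid arthritis produces synovial inflammation and therefore locally
elevated skin temperature over the small finger joints; on a false-colour
(rainbow-palette) thermogram the affected MCP/PIP/DIP joints show up as hot
spots.  This module emulates exactly that statistical structure: a warm
hand-shaped silhouette over a cooler background, with circular hot spots at a
fixed template of 14 joint loci whose peak intensity is raised by a
controllable ``effect_size`` for the RA class.  Every downstream stage of the
package (splitting, augmentation, the CNN, the quanvolution, the hybrid
pipeline) is exercised on these images.

The scalar "temperature" field is unitless in [0, 1]; no radiometric
calibration is attempted.  Rendering maps the scalar field through a fixed
piecewise-linear rainbow colormap (blue -> green -> yellow -> red) into three
bands.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "GeneratorConfig",
    "ThermogramImage",
    "HANDS",
    "VIEWS",
    "LABELS",
    "JOINT_CENTERS",
    "JOINT_RADIUS",
    "rainbow_colormap",
    "joint_mask",
    "hand_mask",
    "render_temperature_field",
    "render_hand_thermogram",
    "generate_arrays",
    "generate_dataset",
    "read_manifest",
    "write_manifest",
]

HANDS = ("left", "right")
VIEWS = ("dorsal", "ventral", "AP")
LABELS = ("normal", "RA")

MANIFEST_COLUMNS = ["path", "label", "subject_id", "hand", "view", "split"]

#: 14 joint loci in normalised (x, y) hand coordinates, y increasing downward:
#: MCP / PIP / DIP of digits 2-5 plus thumb MCP and IP.  Clinical thermography
#: protocols measure finger-joint temperature at these sites; the geometry here
#: is a stylised template, not an anatomical model.
JOINT_CENTERS: tuple[tuple[float, float], ...] = tuple(
    [(x, y) for x in (0.36, 0.46, 0.56, 0.66) for y in (0.44, 0.30, 0.18)]
    + [(0.225, 0.56), (0.165, 0.46)]
)

#: joint hot-spot disk radius, as a fraction of the image side.
JOINT_RADIUS = 0.035

# Scalar-field levels (unitless intensity).
_BG_LO, _BG_HI = 0.12, 0.30          # background vertical gradient
_HAND_BASE = 0.48                    # hand silhouette warmth
_HOTSPOT_BASE = 0.10                 # added inside joint disks (both classes)
_JITTER_SD = 0.015                   # per-subject warmth jitter (latent draw)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the clinical acquisition the generator stands in for:
    50 subjects per class, each imaged in 3 views x 2 hands at 256x256.
    """

    n_subjects_per_class: int = 50
    image_size: int = 256
    effect_size: float = 0.3
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 4:
            raise ValueError(f"image_size must be >= 4, got {self.image_size}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_subjects_per_class < 0:
            raise ValueError("n_subjects_per_class must be >= 0")

    @classmethod
    def from_json(cls, path: str) -> "GeneratorConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ThermogramImage:
    """An H x W x 3 false-colour thermogram with provenance metadata."""

    pixels: np.ndarray
    label: str
    subject_id: int
    hand: str = "left"
    view: str = "dorsal"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if min(self.pixels.shape[:2]) < 4:
            raise ValueError("image must be at least 4 x 4")


def rainbow_colormap(field: np.ndarray) -> np.ndarray:
    """Map a scalar field in [0, 1] through a fixed blue->green->yellow->red
    piecewise-linear rainbow palette; returns an array with a trailing 3-band
    axis."""
    t = np.clip(np.asarray(field, dtype=np.float64), 0.0, 1.0)
    stops = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
    reds = np.array([0.0, 0.0, 1.0, 1.0])
    greens = np.array([0.0, 1.0, 1.0, 0.0])
    blues = np.array([1.0, 0.0, 0.0, 0.0])
    out = np.stack(
        [np.interp(t, stops, c) for c in (reds, greens, blues)], axis=-1
    )
    return out


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(size) + 0.5) / size
    return np.meshgrid(c, c)  # xx, yy with y down rows


def _view_offset(hand: str, view: str) -> tuple[float, float]:
    # Small deterministic translation per view; left/right mirrors x.
    dx = {"dorsal": 0.0, "ventral": 0.015, "AP": -0.015}[view]
    dy = {"dorsal": 0.0, "ventral": 0.01, "AP": -0.01}[view]
    return dx, dy


def _hand_coords(size: int, hand: str, view: str) -> tuple[np.ndarray, np.ndarray]:
    xx, yy = _grid(size)
    if hand == "right":
        xx = 1.0 - xx
    dx, dy = _view_offset(hand, view)
    return xx - dx, yy - dy


_FINGER_X = (0.36, 0.46, 0.56, 0.66)


def _segment_distance(xx, yy, p0, p1):
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    L2 = vx * vx + vy * vy
    t = np.clip(((xx - p0[0]) * vx + (yy - p0[1]) * vy) / L2, 0.0, 1.0)
    return np.hypot(xx - (p0[0] + t * vx), yy - (p0[1] + t * vy))


def hand_mask(size: int, hand: str = "left", view: str = "dorsal") -> np.ndarray:
    """Boolean silhouette: palm ellipse plus five finger capsules."""
    xx, yy = _hand_coords(size, hand, view)
    palm = ((xx - 0.51) / 0.21) ** 2 + ((yy - 0.66) / 0.20) ** 2 <= 1.0
    mask = palm
    for x in _FINGER_X:
        mask = mask | (_segment_distance(xx, yy, (x, 0.50), (x, 0.12)) <= 0.042)
    # thumb
    mask = mask | (_segment_distance(xx, yy, (0.30, 0.62), (0.14, 0.42)) <= 0.045)
    return mask


def joint_mask(size: int, hand: str = "left", view: str = "dorsal") -> np.ndarray:
    """Boolean union of the 14 joint hot-spot disks."""
    xx, yy = _hand_coords(size, hand, view)
    mask = np.zeros((size, size), dtype=bool)
    for cx, cy in JOINT_CENTERS:
        mask |= np.hypot(xx - cx, yy - cy) <= JOINT_RADIUS
    return mask


def _subject_rng(subject_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(subject_seed) & 0x7FFFFFFF]))


def render_temperature_field(
    label: str,
    config: GeneratorConfig,
    subject_seed: int,
    hand: str = "left",
    view: str = "dorsal",
) -> np.ndarray:
    """Scalar (pre-colormap) temperature field in [0, 1].

    Construction order: background gradient + hand silhouette (+ per-subject
    latent warmth jitter, shared by all views of the subject and identical for
    either hypothetical label) + hot-spot disks; for the RA label the in-disk
    intensity is raised by exactly ``effect_size``; Gaussian pixel noise with
    sd ``noise_sd`` is then added and the field clipped to [0, 1].
    """
    config.validate()
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    if hand not in HANDS or view not in VIEWS:
        raise ValueError(f"unknown hand/view: {hand!r}/{view!r}")
    size = config.image_size
    _, yy = _grid(size)

    srng = _subject_rng(subject_seed)
    warmth_jitter = float(np.clip(srng.normal(0.0, _JITTER_SD), -0.03, 0.03))
    bg_jitter = float(np.clip(srng.normal(0.0, _JITTER_SD), -0.03, 0.03))

    fld = _BG_LO + (_BG_HI - _BG_LO) * yy + bg_jitter
    hmask = hand_mask(size, hand, view)
    fld = np.where(hmask, _HAND_BASE + warmth_jitter, fld)
    jmask = joint_mask(size, hand, view) & hmask
    fld = fld + jmask * _HOTSPOT_BASE
    if label == "RA":
        fld = fld + jmask * config.effect_size

    if config.noise_sd > 0:
        nrng = np.random.default_rng(
            np.random.SeedSequence(
                [int(subject_seed) & 0x7FFFFFFF, HANDS.index(hand), VIEWS.index(view), 7]
            )
        )
        fld = fld + nrng.normal(0.0, config.noise_sd, size=fld.shape)
    return np.clip(fld, 0.0, 1.0)


def render_hand_thermogram(
    label: str,
    config: GeneratorConfig,
    subject_seed: int,
    hand: str = "left",
    view: str = "dorsal",
    subject_id: int = 0,
) -> ThermogramImage:
    """Render one false-colour thermogram (scalar field -> rainbow RGB)."""
    fld = render_temperature_field(label, config, subject_seed, hand, view)
    rgb = rainbow_colormap(fld)
    return ThermogramImage(
        pixels=rgb, label=label, subject_id=subject_id, hand=hand, view=view
    )


def _subject_seed(config: GeneratorConfig, class_idx: int, subj_idx: int) -> int:
    ss = np.random.SeedSequence([int(config.seed), class_idx, subj_idx])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_arrays(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate the full cohort in memory.

    Returns a manifest-like DataFrame (`path` holds a synthetic stem) aligned
    row-for-row with an (n, size, size, 3) float64 pixel array.  Ordering is
    deterministic: class-major, then subject, hand, view.
    """
    config.validate()
    records = []
    images = []
    for class_idx, label in enumerate(LABELS):
        for subj_idx in range(config.n_subjects_per_class):
            subject_id = class_idx * max(config.n_subjects_per_class, 1) + subj_idx
            sseed = _subject_seed(config, class_idx, subj_idx)
            for hand in HANDS:
                for view in VIEWS:
                    img = render_hand_thermogram(
                        label, config, sseed, hand, view, subject_id
                    )
                    stem = f"{label}_s{subject_id:03d}_{hand}_{view}"
                    records.append(
                        {
                            "path": stem + ".png",
                            "label": label,
                            "subject_id": subject_id,
                            "hand": hand,
                            "view": view,
                            "split": "unassigned",
                        }
                    )
                    images.append(img.pixels)
    manifest = pd.DataFrame(records, columns=MANIFEST_COLUMNS)
    if images:
        X = np.stack(images)
    else:
        X = np.zeros((0, config.image_size, config.image_size, 3))
    return manifest, X


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(pixels * 255.0), 0, 255).astype(np.uint8)


def save_png(pixels: np.ndarray, path: str) -> None:
    Image.fromarray(to_uint8(pixels), mode="RGB").save(path, format="PNG")


def load_png(path: str) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0


def write_manifest(manifest: pd.DataFrame, path: str) -> None:
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != MANIFEST_COLUMNS:
        raise ValueError(f"manifest columns must be {MANIFEST_COLUMNS}")
    if df["path"].duplicated().any():
        raise ValueError("manifest contains duplicate paths")
    return df


def generate_dataset(config: GeneratorConfig, out_dir: str) -> pd.DataFrame:
    """Write one PNG per (class, subject, hand, view) plus ``manifest.csv``.

    Bit-reproducible for a fixed config/seed.  Returns the manifest.
    """
    manifest, X = generate_arrays(config)
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, row in manifest.iterrows():
        p = os.path.join(out_dir, row["path"])
        save_png(X[i], p)
        paths.append(p)
    manifest = manifest.assign(path=paths)
    write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return manifest
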