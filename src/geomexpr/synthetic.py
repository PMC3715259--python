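"""Synthetic labeled landmark sequences with the statistical structure the
pipeline assumes, plus an optional textured-image renderer for closed-loop
tracking tests.

Every generated sequence runs from a neutral first frame to an apex:
frame l places each landmark at

    template + subject_offset + ramp(warped_time_l) * apex_displacement + jitter

with a monotone ramp (ramp(0)=0, ramp(1)=1), a per-sequence monotone time
warp (so same-class sequences are out of phase, which is what DTW is
for), a per-sequence global position offset standing in for subject
placement, and i.i.d. per-frame Gaussian jitter. Class identity lives
entirely in the sparse apex-displacement pattern, so class-conditional
feature distributions are unimodal by construction.

The 52-landmark schematic face template (brows, eyes, nose, mouth,
contour) and its 7-region grouping ship as module data so region
summaries are meaningful; the six default class models are sparse
displacement patterns loosely organized around mouth-dominant vs
brow-dominant motion. They are fixtures for testing the pipeline, not
claims about real expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .sequences import LandmarkSequence

__all__ = [
    "ClassModel",
    "GenConfig",
    "TextureParams",
    "FACE_TEMPLATE",
    "default_regions",
    "default_class_models",
    "generate_dataset",
    "render_sequence",
]


# ---------------------------------------------------------------------------
# 52-landmark schematic face (x rightward, y downward, pixels)
# ---------------------------------------------------------------------------
# indices: 0-3 left brow, 4-7 right brow, 8-13 left eye, 14-19 right eye,
#          20-26 nose, 27-38 mouth (27-34 outer ring, 35-38 inner),
#          39-51 face contour (left temple -> chin -> right temple)

FACE_TEMPLATE = np.array(
    [
        # left brow
        (45, 55), (55, 50), (65, 50), (75, 53),
        # right brow
        (85, 53), (95, 50), (105, 50), (115, 55),
        # left eye (corner, upper x2, corner, lower x2)
        (50, 68), (58, 64), (66, 64), (72, 68), (66, 72), (58, 72),
        # right eye
        (88, 68), (94, 64), (102, 64), (110, 68), (102, 72), (94, 72),
        # nose: bridge x2, tip, left nostril, left base, right base, right nostril
        (80, 65), (80, 78), (80, 90), (70, 98), (75, 102), (85, 102), (90, 98),
        # mouth outer ring: L corner, upper x3, R corner, lower x3
        (58, 120), (68, 114), (80, 112), (92, 114), (102, 120),
        (92, 128), (80, 130), (68, 128),
        # mouth inner: left, top, right, bottom
        (70, 120), (80, 118), (90, 120), (80, 123),
        # contour: left temple down to chin and back up the right side
        (30, 55), (28, 80), (32, 105), (40, 128), (52, 146), (66, 158),
        (80, 162), (94, 158), (108, 146), (120, 128), (128, 105), (132, 80),
        (130, 55),
    ],
    dtype=float,
)

_BROWS = list(range(0, 8))
_EYES = list(range(8, 20))
_NOSE = list(range(20, 27))
_MOUTH = list(range(27, 39))
_CONTOUR = list(range(39, 52))


def default_regions() -> dict[int, str]:
    """Default 7-region grouping of the 52-landmark template.

    R1 upper contour/temples, R2 eyes+eyebrows, R3 nose, R4 left cheek
    contour, R5 right cheek contour, R6 mouth, R7 chin.
    """
    regions: dict[int, str] = {}
    for i in _BROWS + _EYES:
        regions[i] = "R2"
    for i in _NOSE:
        regions[i] = "R3"
    for i in _MOUTH:
        regions[i] = "R6"
    for i in (39, 40, 50, 51):
        regions[i] = "R1"
    for i in (41, 42, 43):
        regions[i] = "R4"
    for i in (44, 45, 46):
        regions[i] = "R7"
    for i in (47, 48, 49):
        regions[i] = "R5"
    return regions


@dataclass
class ClassModel:
    """Apex displacement pattern and temporal ramp of one expression class."""

    apex: np.ndarray  # (L, 2) pixels; zero rows = inactive landmarks
    ramp: str = "logistic"  # "logistic" | "linear"
    steepness: float = 8.0
    name: str = ""

    def __post_init__(self) -> None:
        self.apex = np.asarray(self.apex, dtype=float)
        if self.ramp not in ("logistic", "linear"):
            raise ValueError(f"unknown ramp family {self.ramp!r}")

    def ramp_values(self, t: np.ndarray) -> np.ndarray:
        """Monotone ramp with ramp(0)=0 and ramp(1)=1."""
        t = np.asarray(t, dtype=float)
        if self.ramp == "linear":
            return t
        k = self.steepness
        s = 1.0 / (1.0 + np.exp(-k * (t - 0.5)))
        s0 = 1.0 / (1.0 + np.exp(k * 0.5))
        s1 = 1.0 / (1.0 + np.exp(-k * 0.5))
        return (s - s0) / (s1 - s0)


def _apex(L: int, moves: dict[int, tuple[float, float]]) -> np.ndarray:
    a = np.zeros((L, 2))
    for i, (dx, dy) in moves.items():
        a[i] = (dx, dy)
    return a


def default_class_models(L: int = 52) -> list[ClassModel]:
    """Six sparse apex-displacement patterns (pixels) over the template.

    Patterns differ in which face regions carry the motion (brow-dominant
    vs mouth-dominant, compression vs opening) with per-landmark
    magnitudes of roughly 4-12 px.
    """
    if L != 52:
        raise ValueError("default class models are defined for the 52-landmark template")
    m1 = _apex(L, {  # brows pulled down and inward, mouth compressed
        1: (2, 5), 2: (3, 6), 3: (3, 7), 4: (-3, 7), 5: (-3, 6), 6: (-2, 5),
        27: (4, 0), 31: (-4, 0), 29: (0, 3), 33: (0, -4), 36: (0, 2), 38: (0, -2),
    })
    m2 = _apex(L, {  # nose wrinkle + upper-lip raise
        23: (0, -5), 26: (0, -5), 24: (0, -4), 25: (0, -4),
        28: (0, -6), 29: (0, -7), 30: (0, -6),
        2: (0, 3), 5: (0, 3), 22: (0, -3),
    })
    m3 = _apex(L, {  # brows raised flat, eyes widened, mouth corners stretched
        0: (0, -6), 1: (0, -6), 2: (0, -6), 5: (0, -6), 6: (0, -6), 7: (0, -6),
        9: (0, -3), 10: (0, -3), 15: (0, -3), 16: (0, -3),
        27: (-4, 2), 31: (4, 2), 33: (0, 6),
    })
    m4 = _apex(L, {  # mouth corners up and out, cheeks raised
        27: (-7, -5), 31: (7, -5), 28: (-3, -3), 30: (3, -3),
        32: (3, -2), 34: (-3, -2), 33: (0, 4), 38: (0, 3),
        12: (0, 2), 13: (0, 2), 18: (0, 2), 19: (0, 2),
    })
    m5 = _apex(L, {  # inner brows raised, mouth corners down
        3: (0, -5), 4: (0, -5), 2: (0, -3), 5: (0, -3),
        27: (0, 6), 31: (0, 6), 28: (0, 2), 30: (0, 2), 33: (0, 2),
    })
    m6 = _apex(L, {  # brows strongly raised, eyes wide, jaw dropped
        0: (0, -8), 1: (0, -9), 2: (0, -9), 3: (0, -8),
        4: (0, -8), 5: (0, -9), 6: (0, -9), 7: (0, -8),
        9: (0, -4), 10: (0, -4), 15: (0, -4), 16: (0, -4),
        11: (0, 3), 12: (0, 4), 13: (0, 3), 17: (0, 3), 18: (0, 4), 19: (0, 3),
        33: (0, 12), 32: (0, 9), 34: (0, 9), 38: (0, 8),
        27: (-2, 4), 31: (2, 4), 44: (0, 6), 45: (0, 8), 46: (0, 6),
    })
    names = ["class1", "class2", "class3", "class4", "class5", "class6"]
    steep = [7.0, 9.0, 8.0, 6.0, 8.0, 10.0]
    return [
        ClassModel(apex=a, ramp="logistic", steepness=s, name=n)
        for a, s, n in zip([m1, m2, m3, m4, m5, m6], steep, names)
    ]


@dataclass
class GenConfig:
    """Generator settings.

    Defaults emulate the structure of an expression-sequence corpus:
    6 classes, 52 landmarks, 40 sequences per class, 7-60 frames per
    sequence, a 3 px SD subject placement offset, 0.3 px SD per-frame
    landmark jitter, and a moderate monotone time warp.
    """

    K: int = 6
    L: int = 52
    n_per_class: int = 40
    frame_range: tuple[int, int] = (7, 60)
    subject_offset_sd: float = 3.0
    frame_noise_sd: float = 0.3
    time_warp_strength: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.frame_range
        if not (2 <= lo <= hi):
            raise ValueError(f"invalid frame range {self.frame_range}")
        if min(self.subject_offset_sd, self.frame_noise_sd, self.time_warp_strength) < 0:
            raise ValueError("noise and warp strengths must be nonnegative")


def generate_dataset(
    models: Sequence[ClassModel] | None = None,
    cfg: GenConfig | None = None,
    template: np.ndarray | None = None,
) -> list[LandmarkSequence]:
    """Generate a labeled dataset of landmark sequences.

    Class labels are 1..K in model order. Deterministic for a fixed
    ``cfg.seed``; all randomness flows through one seeded generator.
    """
    cfg = cfg or GenConfig()
    models = list(models) if models is not None else default_class_models(cfg.L)
    if len(models) != cfg.K:
        raise ValueError(f"need {cfg.K} class models, got {len(models)}")
    template = FACE_TEMPLATE if template is None else np.asarray(template, dtype=float)
    if template.shape != (cfg.L, 2):
        raise ValueError(f"template must have shape ({cfg.L}, 2)")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.frame_range
    out: list[LandmarkSequence] = []
    for c, model in enumerate(models, start=1):
        if model.apex.shape != (cfg.L, 2):
            raise ValueError(f"class model {c} apex must have shape ({cfg.L}, 2)")
        for s in range(cfg.n_per_class):
            F = int(rng.integers(lo, hi + 1))
            offset = rng.normal(0.0, cfg.subject_offset_sd, size=2)
            t = np.linspace(0.0, 1.0, F)
            # monotone per-sequence time warp: t -> t**g, endpoints fixed
            g = float(np.exp(cfg.time_warp_strength * rng.uniform(-1.0, 1.0)))
            r = model.ramp_values(t**g)  # (F,)
            coords = (
                template[:, None, :]
                + offset[None, None, :]
                + model.apex[:, None, :] * r[None, :, None]
                + rng.normal(0.0, cfg.frame_noise_sd, size=(cfg.L, F, 2))
            )
            out.append(
                LandmarkSequence(coords=coords, label=c, sequence_id=f"c{c}s{s:03d}")
            )
    return out


# ---------------------------------------------------------------------------
# Rendering: band-limited texture patches following the trajectories
# ---------------------------------------------------------------------------


@dataclass
class TextureParams:
    """Rendering settings for :func:`render_sequence`.

    Each landmark carries a unique Gaussian-windowed sinusoid (distinct
    orientation, spatial frequency, and phase derived from its index) on
    a static low-amplitude smooth-noise background, so Gabor jets see
    well-conditioned band-limited structure.
    """

    canvas_shape: tuple[int, int] | None = None  # (H, W); None = auto from bbox
    margin: int = 12
    patch_sigma: float = 3.0
    patch_radius: int = 10
    patch_amplitude: float = 0.35
    freq_lo: float = 0.7  # rad/px
    freq_hi: float = 1.4
    background_amplitude: float = 0.05
    background_smoothing: float = 3.0
    base_gray: float = 0.5
    seed: int = 0


def render_sequence(
    seq: LandmarkSequence, texture: TextureParams | None = None
) -> list[np.ndarray]:
    """Render a landmark sequence as grayscale frames in [0, 1].

    Patch centers follow the (sub-pixel) trajectories exactly; the
    background is identical across frames.
    """
    tx = texture or TextureParams()
    L, F, _ = seq.coords.shape
    if tx.canvas_shape is None:
        hi = seq.coords.max(axis=(0, 1))
        H = int(np.ceil(hi[1])) + tx.margin + 1
        W = int(np.ceil(hi[0])) + tx.margin + 1
    else:
        H, W = tx.canvas_shape
    lo = seq.coords.min(axis=(0, 1))
    hi = seq.coords.max(axis=(0, 1))
    if lo[0] < 0 or lo[1] < 0 or hi[0] > W - 1 or hi[1] > H - 1:
        raise ValueError("landmark trajectory leaves the canvas")

    rng = np.random.default_rng(tx.seed)
    background = tx.base_gray + tx.background_amplitude * gaussian_filter(
        rng.standard_normal((H, W)), tx.background_smoothing
    )

    # deterministic per-landmark texture identity
    golden = np.pi * (3.0 - np.sqrt(5.0))
    orients = golden * np.arange(L)
    freqs = tx.freq_lo + (tx.freq_hi - tx.freq_lo) * ((np.arange(L) * 7) % L) / max(L - 1, 1)
    phases = 2.0 * np.pi * ((np.arange(L) * 13) % L) / L

    frames = []
    R = tx.patch_radius
    for l in range(F):
        img = background.copy()
        for i in range(L):
            cx, cy = seq.coords[i, l]
            x0, x1 = int(np.floor(cx)) - R, int(np.floor(cx)) + R + 1
            y0, y1 = int(np.floor(cy)) - R, int(np.floor(cy)) + R + 1
            x0c, x1c = max(x0, 0), min(x1, W)
            y0c, y1c = max(y0, 0), min(y1, H)
            xs = np.arange(x0c, x1c) - cx
            ys = np.arange(y0c, y1c) - cy
            DX, DY = np.meshgrid(xs, ys)
            env = np.exp(-(DX**2 + DY**2) / (2.0 * tx.patch_sigma**2))
            carrier = np.cos(
                freqs[i] * (np.cos(orients[i]) * DX + np.sin(orients[i]) * DY)
                + phases[i]
            )
            img[y0c:y1c, x0c:x1c] += tx.patch_amplitude * env * carrier
        frames.append(np.clip(img, 0.0, 1.0))
    return frames
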