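"""Landmark trajectory data model: sequences, reference frame, normalization,
temporal resampling, and trajectory file I/O.

Coordinates are continuous pixel positions (origin top-left, x rightward,
y downward); frame 0 is the neutral frame. Sub-pixel values are allowed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSequence",
    "ReferenceFrame",
    "compute_reference",
    "normalize_sequence",
    "resample_sequence",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_trajectory_json",
    "write_trajectory_json",
]


@dataclass
class LandmarkSequence:
    """Trajectories of L landmarks over F frames.

    Parameters
    ----------
    coords
        Array of shape ``(L, F, 2)`` in pixel units; ``coords[i, l]`` is the
        (x, y) position of landmark ``i`` in frame ``l``. Frame 0 is the
        neutral frame.
    label
        Optional class id in ``1..K``.
    sequence_id
        Identifier used in trajectory files and fold bookkeeping.
    """

    coords: np.ndarray
    label: int | None = None
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError(
                f"coords must have shape (L, F, 2), got {self.coords.shape}"
            )
        if self.n_landmarks < 2:
            raise ValueError("a landmark sequence needs at least 2 landmarks")
        if self.n_frames < 2:
            raise ValueError("a landmark sequence needs at least 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[1]

    def with_coords(self, coords: np.ndarray) -> "LandmarkSequence":
        return replace(self, coords=coords)


@dataclass
class ReferenceFrame:
    """Per-landmark average neutral-frame position, shape ``(L, 2)``."""

    mu: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.ndim != 2 or self.mu.shape[1] != 2:
            raise ValueError(f"mu must have shape (L, 2), got {self.mu.shape}")
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("reference frame must be finite")

    @property
    def n_landmarks(self) -> int:
        return self.mu.shape[0]


def compute_reference(sequences: Iterable[LandmarkSequence]) -> ReferenceFrame:
    """Average neutral-frame landmark positions across sequences.

    The reference is the arithmetic mean of frame-0 positions per landmark,
    computed from the training sequences only; test sequences are normalized
    against the same reference.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("cannot compute a reference frame from zero sequences")
    L = seqs[0].n_landmarks
    for s in seqs:
        if s.n_landmarks != L:
            raise ValueError(
                f"landmark count mismatch: expected {L}, got {s.n_landmarks} "
                f"in sequence {s.sequence_id!r}"
            )
    neutral = np.stack([s.coords[:, 0, :] for s in seqs])  # (n, L, 2)
    return ReferenceFrame(mu=neutral.mean(axis=0))


def normalize_sequence(seq: LandmarkSequence, ref: ReferenceFrame) -> LandmarkSequence:
    """Translate each landmark trajectory so frame 0 coincides with the reference.

    For each landmark i the displacement ``delta = mu[i] - coords[i, 0]`` is
    added to every frame, so all normalized sequences start from identical
    neutral geometry while preserving all inter-frame motion exactly.
    """
    if seq.n_landmarks != ref.n_landmarks:
        raise ValueError(
            f"landmark count mismatch: sequence has {seq.n_landmarks}, "
            f"reference has {ref.n_landmarks}"
        )
    delta = ref.mu - seq.coords[:, 0, :]  # (L, 2)
    shifted = seq.coords + delta[:, None, :]
    shifted[:, 0, :] = ref.mu  # exact, immune to float cancellation
    return seq.with_coords(shifted)


def resample_sequence(seq: LandmarkSequence, n_target: int = 16) -> LandmarkSequence:
    """Resample a trajectory to ``n_target`` frames by linear interpolation.

    Frames are placed at uniformly spaced normalized times in [0, 1]; the
    first and last frames are preserved exactly. The default of 16 frames
    yields feature vectors with 15 non-neutral elements.
    """
    if n_target < 2:
        raise ValueError("n_target must be at least 2")
    F = seq.n_frames
    if F == n_target:
        return seq.with_coords(seq.coords.copy())
    t_src = np.linspace(0.0, 1.0, F)
    t_dst = np.linspace(0.0, 1.0, n_target)
    # coords is (L, F, 2); move F last for a clean per-channel reshape
    chans = np.moveaxis(seq.coords, 1, 2).reshape(-1, F)  # (L*2, F)
    out = np.empty((chans.shape[0], n_target))
    for r in range(chans.shape[0]):
        out[r] = np.interp(t_dst, t_src, chans[r])
    new = np.moveaxis(out.reshape(seq.n_landmarks, 2, n_target), 2, 1)
    # exact endpoint preservation against interp round-off
    new[:, 0, :] = seq.coords[:, 0, :]
    new[:, -1, :] = seq.coords[:, -1, :]
    return seq.with_coords(new)


# ---------------------------------------------------------------------------
# Trajectory file formats
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["sequence_id", "frame", "landmark", "x", "y", "label"]


def write_trajectory_csv(path, sequences: Sequence[LandmarkSequence]) -> None:
    """Write sequences to the long-format trajectory CSV
    (columns: sequence_id, frame, landmark, x, y, label)."""
    rows = []
    for s in sequences:
        L, F, _ = s.coords.shape
        frames = np.repeat(np.arange(F), L)
        landmarks = np.tile(np.arange(L), F)
        xy = np.moveaxis(s.coords, 1, 0).reshape(F * L, 2)
        rows.append(
            pd.DataFrame(
                {
                    "sequence_id": s.sequence_id,
                    "frame": frames,
                    "landmark": landmarks,
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                    "label": s.label if s.label is not None else -1,
                }
            )
        )
    pd.concat(rows, ignore_index=True)[_CSV_COLUMNS].to_csv(path, index=False)


def read_trajectory_csv(path) -> list[LandmarkSequence]:
    """Read the long-format trajectory CSV, validating rectangularity
    (every frame of a sequence must contain every landmark exactly once)."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    out = []
    for sid, g in df.groupby("sequence_id", sort=False):
        frames = np.sort(g["frame"].unique())
        landmarks = np.sort(g["landmark"].unique())
        F, L = len(frames), len(landmarks)
        if len(g) != F * L or not np.array_equal(frames, np.arange(F)) or not np.array_equal(
            landmarks, np.arange(L)
        ):
            raise ValueError(
                f"sequence {sid!r} is not rectangular: expected frames 0..{F-1} "
                f"x landmarks 0..{L-1} exactly once each"
            )
        g = g.sort_values(["frame", "landmark"])
        coords = g[["x", "y"]].to_numpy().reshape(F, L, 2).transpose(1, 0, 2)
        labels = g["label"].unique()
        if len(labels) != 1:
            raise ValueError(f"sequence {sid!r} has inconsistent labels {labels}")
        label = int(labels[0])
        out.append(
            LandmarkSequence(
                coords=coords,
                label=None if label < 0 else label,
                sequence_id=str(sid),
            )
        )
    return out


def write_trajectory_json(path, sequences: Sequence[LandmarkSequence]) -> None:
    """JSON dialect: one object per sequence with nested coordinate arrays."""
    payload = [
        {
            "sequence_id": s.sequence_id,
            "label": s.label,
            "coords": s.coords.tolist(),
        }
        for s in sequences
    ]
    with open(path, "w") as fh:
        json.dump({"format": "geomexpr-trajectories", "version": 1, "sequences": payload}, fh)


def read_trajectory_json(path) -> list[LandmarkSequence]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "geomexpr-trajectories":
        raise ValueError("not a geomexpr trajectory JSON file")
    return [
        LandmarkSequence(
            coords=np.asarray(rec["coords"], dtype=float),
            label=rec.get("label"),
            sequence_id=rec.get("sequence_id", ""),
        )
        for rec in payload["sequences"]
    ]
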