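"""Gabor-jet landmark tracking.

A Gabor jet is the vector of complex responses of a bank of Gabor
wavelets (several spatial frequencies x orientations) centered at one
image point. Landmarks are tracked frame to frame by comparing the jet
stored at the previous position with a jet extracted at the same
position in the new frame: for small motion the phase of each
coefficient rotates linearly with displacement (phase difference
approximately k . d for wave vector k), so the displacement is the
weighted least-squares solution over all coefficients, solved
coarse-to-fine over frequency levels with per-level phase unwrapping
("focused" estimation). Landmark initialization in frame 0 is supplied
by the caller; no face/eye detection or bunch-graph matching is
performed here.

Kernel family: k_nu = k_max / spacing**nu for nu = 0..n_freq-1 and
orientations mu*pi/n_orient, with the DC-free Gabor kernel

    psi(x) = (k^2/sigma^2) exp(-k^2 |x|^2 / (2 sigma^2))
             (exp(i k.x) - exp(-sigma^2/2)).

Discrete kernels are additionally projected to exact zero sum so a
constant image yields exactly zero magnitudes; near borders kernels are
truncated and renormalized by their in-window envelope mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sequences import LandmarkSequence

__all__ = [
    "JetParams",
    "GaborJet",
    "extract_jet",
    "estimate_displacement",
    "track_sequence",
]


@dataclass(frozen=True)
class JetParams:
    """Gabor family settings (classic EBGM defaults: 5 x 8 = 40 coefficients)."""

    n_freq: int = 5
    n_orient: int = 8
    max_frequency: float = np.pi / 2  # rad/px, highest-frequency level
    frequency_spacing: float = np.sqrt(2.0)
    gaussian_width: float = 2.0 * np.pi  # sigma, in units of 1/k
    radius_factor: float = 2.5  # kernel truncation radius = factor * sigma / k

    def __post_init__(self) -> None:
        if self.n_freq < 1 or self.n_orient < 1:
            raise ValueError("need at least one frequency and one orientation")
        if min(self.max_frequency, self.frequency_spacing, self.gaussian_width) <= 0:
            raise ValueError("frequency parameters must be positive")

    @property
    def n_coeff(self) -> int:
        return self.n_freq * self.n_orient

    def wave_vectors(self) -> np.ndarray:
        """Per-coefficient wave vectors, shape (n_coeff, 2), frequency-major
        (level 0 = highest frequency)."""
        ks = self.max_frequency / self.frequency_spacing ** np.arange(self.n_freq)
        phis = np.pi * np.arange(self.n_orient) / self.n_orient
        kv = np.empty((self.n_freq, self.n_orient, 2))
        kv[..., 0] = ks[:, None] * np.cos(phis)[None, :]
        kv[..., 1] = ks[:, None] * np.sin(phis)[None, :]
        return kv.reshape(-1, 2)

    def freq_levels(self) -> np.ndarray:
        """Frequency level index per coefficient (0 = highest frequency)."""
        return np.repeat(np.arange(self.n_freq), self.n_orient)

    def kernel_radius(self, level: int) -> int:
        k = self.max_frequency / self.frequency_spacing**level
        return int(np.ceil(self.radius_factor * self.gaussian_width / k))

    @property
    def max_radius(self) -> int:
        return self.kernel_radius(self.n_freq - 1)


@dataclass
class GaborJet:
    """Magnitude/phase decomposition of one jet."""

    magnitudes: np.ndarray  # (n_coeff,), >= 0
    phases: np.ndarray  # (n_coeff,), radians in (-pi, pi]
    wave_vectors: np.ndarray  # (n_coeff, 2)
    params: JetParams = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (
            len(self.magnitudes) == len(self.phases) == len(self.wave_vectors)
        ):
            raise ValueError("jet component lengths must agree")


def _as_float_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim != 2:
        raise ValueError("extract_jet expects a 2-D grayscale image")
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    return img.astype(float)


def extract_jet(image: np.ndarray, point, params: JetParams | None = None) -> GaborJet:
    """Extract the Gabor jet at a (sub-pixel) image point.

    Kernels are evaluated continuously at integer pixel offsets around the
    point, truncated at ``radius_factor * sigma / k``, renormalized by
    their in-window envelope mass, and projected to exact zero DC.
    """
    params = params or JetParams()
    img = _as_float_image(image)
    H, W = img.shape
    px, py = float(point[0]), float(point[1])
    if not (np.isfinite(px) and np.isfinite(py)):
        raise ValueError("jet extraction point must be finite")
    if not (0 <= px <= W - 1 and 0 <= py <= H - 1):
        raise ValueError(f"point ({px}, {py}) lies outside the image")

    sigma = params.gaussian_width
    kv = params.wave_vectors().reshape(params.n_freq, params.n_orient, 2)
    coeffs = np.empty(params.n_coeff, dtype=complex)
    idx = 0
    for nu in range(params.n_freq):
        k = float(np.hypot(*kv[nu, 0]))
        R = params.kernel_radius(nu)
        x0, x1 = int(np.floor(px)) - R, int(np.floor(px)) + R + 1
        y0, y1 = int(np.floor(py)) - R, int(np.floor(py)) + R + 1
        x0c, x1c = max(x0, 0), min(x1, W)
        y0c, y1c = max(y0, 0), min(y1, H)
        xs = np.arange(x0c, x1c) - px
        ys = np.arange(y0c, y1c) - py
        DX, DY = np.meshgrid(xs, ys)
        env = (k * k / (sigma * sigma)) * np.exp(
            -k * k * (DX * DX + DY * DY) / (2.0 * sigma * sigma)
        )
        env_sum = env.sum()
        patch = img[y0c:y1c, x0c:x1c]
        for mu in range(params.n_orient):
            kx, ky = kv[nu, mu]
            wave = np.exp(1j * (kx * DX + ky * DY))
            kern = env * (wave - np.exp(-sigma * sigma / 2.0))
            # exact zero-DC projection under truncation
            kern = kern - env * (kern.sum() / env_sum)
            kern = kern / env_sum  # border renormalization
            coeffs[idx] = np.sum(patch * np.conj(kern))
            idx += 1
    return GaborJet(
        magnitudes=np.abs(coeffs),
        phases=np.angle(coeffs),
        wave_vectors=params.wave_vectors(),
        params=params,
    )


def _wrap(phi: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * phi))


def estimate_displacement(
    jet_prev: GaborJet, jet_curr: GaborJet, n_iter: int = 3
) -> np.ndarray:
    """Estimate the image displacement between two jets at the same point.

    Solves the magnitude-weighted least squares

        min_d  sum_j w_j (dphi_j - k_j . d)^2,   w_j = a_prev,j * a_curr,j

    where ``dphi_j = wrap(phi_prev,j - phi_curr,j)``, focused coarse to
    fine: coefficients enter the solve one frequency level at a time
    (lowest frequency first), with phase differences re-unwrapped toward
    ``k . d`` of the current estimate at each step, followed by ``n_iter``
    full refinement passes. The result is clamped to half the largest
    kernel wavelength. Returns (dx, dy).
    """
    params = jet_prev.params or JetParams()
    if jet_curr.wave_vectors.shape != jet_prev.wave_vectors.shape:
        raise ValueError("jets must come from the same kernel family")
    w = jet_prev.magnitudes * jet_curr.magnitudes
    if w.sum() <= 1e-18:  # numerically zero texture energy
        warnings.warn("zero jet magnitudes; displacement undefined", RuntimeWarning)
        return np.zeros(2)
    kvec = jet_prev.wave_vectors
    dphi = _wrap(jet_prev.phases - jet_curr.phases)
    levels = params.freq_levels()
    kmin = np.hypot(kvec[:, 0], kvec[:, 1]).min()
    dmax = np.pi / kmin  # half of the largest wavelength 2*pi/kmin

    def solve(mask: np.ndarray, d: np.ndarray) -> np.ndarray:
        kd = kvec[mask] @ d
        phi_u = dphi[mask] + 2.0 * np.pi * np.round((kd - dphi[mask]) / (2.0 * np.pi))
        ws = w[mask]
        A = (kvec[mask] * ws[:, None]).T @ kvec[mask]
        b = (kvec[mask] * ws[:, None]).T @ phi_u
        try:
            return np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(A, b, rcond=None)[0]

    d = np.zeros(2)
    # focused pass: include levels from coarse (high level index) to fine
    for lo_level in range(params.n_freq - 1, -1, -1):
        d = solve(levels >= lo_level, d)
    for _ in range(n_iter):
        d = solve(np.ones(len(w), dtype=bool), d)
    norm = np.hypot(*d)
    if norm > dmax:
        d = d * (dmax / norm)
    return d


def track_sequence(
    images,
    init: np.ndarray,
    params: JetParams | None = None,
    refine_iters: int = 3,
) -> LandmarkSequence:
    """Track frame-0 landmarks through an ordered grayscale image sequence.

    Per frame and landmark: a jet is extracted at the previous-frame
    position in the new frame, the displacement against the stored
    previous jet is estimated and applied (iterated ``refine_iters``
    times, re-extracting at the refined position), then the jet is
    re-extracted at the final position and stored for the next frame.
    Positions that would leave the image are clamped to the border with a
    warning.
    """
    params = params or JetParams()
    imgs = [_as_float_image(im) for im in images]
    if len(imgs) < 2:
        raise ValueError("tracking needs at least 2 frames")
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs):
        raise ValueError("all frames must share the same shape")
    H, W = shape
    init = np.asarray(init, dtype=float)
    if init.ndim != 2 or init.shape[1] != 2:
        raise ValueError("init must have shape (L, 2)")
    L = init.shape[0]

    def clamp(p: np.ndarray) -> tuple[np.ndarray, bool]:
        q = np.clip(p, [0.0, 0.0], [W - 1.0, H - 1.0])
        return q, bool(np.any(q != p))

    positions = np.empty((L, len(imgs), 2))
    positions[:, 0] = init
    jets = [extract_jet(imgs[0], init[i], params) for i in range(L)]
    clamped_any = False
    for l in range(1, len(imgs)):
        for i in range(L):
            p_prev = positions[i, l - 1]
            p_new = p_prev.copy()
            for _ in range(max(1, refine_iters)):
                jet_b = extract_jet(imgs[l], p_new, params)
                # residual displacement of the texture under p_new relative
                # to the stored previous-frame jet
                d = estimate_displacement(jets[i], jet_b)
                p_new, hit = clamp(p_new + d)
                clamped_any = clamped_any or hit
                if np.hypot(*d) < 1e-3:
                    break
            positions[i, l] = p_new
            jets[i] = extract_jet(imgs[l], p_new, params)
    if clamped_any:
        warnings.warn("some landmarks were clamped to the image border", RuntimeWarning)
    return LandmarkSequence(coords=positions, sequence_id="tracked")
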