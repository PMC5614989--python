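"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the raw observables of the bead/node experiments:
2D bead-tracking trajectories with a known transport law, toy filament
contours with known tension, and protein sequences with planted proline
tracks.  They carry no imaging noise by default (an additive localization
noise knob exists but defaults to 0) and are bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

import numpy as np

from .datatypes import BeadTrajectory, FilamentShape, ProteinSequence

__all__ = [
    "gen_brownian_track",
    "gen_subdiffusive_track",
    "gen_arc_filament",
    "gen_pbt_sequence",
    "fgn_autocovariance",
]

#: Tracking frame interval used throughout, s.
DEFAULT_FRAME_INTERVAL = 5.0
#: Minimum number of frames for tracking-grade trajectories.
MIN_FRAMES = 20

_NON_PROLINE = np.array(list("ACDEFGHIKLMNQRSTVWY"))


def _finalize(bead_id, times, positions, noise_sd, rng):
    if noise_sd > 0:
        positions = positions + rng.normal(0.0, noise_sd, size=positions.shape)
    return BeadTrajectory(bead_id=bead_id, times=times, positions=positions)


def gen_brownian_track(
    diffusion_coeff: float,
    n_frames: int = 100,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    seed: int = 0,
    *,
    bead_id: str = "bead",
    noise_sd: float = 0.0,
) -> BeadTrajectory:
    """Free 2D Brownian track with MSD(t) = 4 D t.

    Parameters
    ----------
    diffusion_coeff
        D in nm²/s; each coordinate increment is Gaussian with variance
        2 D Δt.
    n_frames
        Number of frames (>= 20, the tracking minimum).
    frame_interval
        Δt in seconds (tracking default 5 s).
    noise_sd
        Optional additive localization noise per coordinate, nm (default 0).
    """
    if diffusion_coeff <= 0:
        raise ValueError("diffusion_coeff must be positive")
    if n_frames < MIN_FRAMES:
        raise ValueError(f"n_frames must be >= {MIN_FRAMES}")
    rng = np.random.default_rng(seed)
    step_sd = np.sqrt(2.0 * diffusion_coeff * frame_interval)
    increments = rng.normal(0.0, step_sd, size=(n_frames - 1, 2))
    positions = np.vstack([np.zeros((1, 2)), np.cumsum(increments, axis=0)])
    times = np.arange(n_frames) * frame_interval
    return _finalize(bead_id, times, positions, noise_sd, rng)


def fgn_autocovariance(alpha: float, n_lags: int, scale: float, dt: float) -> np.ndarray:
    """Autocovariance of fractional Gaussian noise increments at lags 0..n_lags-1.

    For per-coordinate fBm with variance scale·t^alpha (so the 2D MSD is
    2·scale·t^alpha per pair of coordinates), the increment process at
    spacing dt has gamma(k) = sigma²/2 (|k+1|^2H − 2|k|^2H + |k−1|^2H) with
    H = alpha/2 and sigma² = scale·dt^alpha.
    """
    h2 = alpha  # 2H
    sigma2 = scale * dt**alpha
    k = np.arange(n_lags, dtype=float)
    return 0.5 * sigma2 * (np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


def _fgn_davies_harte(alpha, n, scale, dt, rng):
    """Exact fGn sample via circulant embedding; falls back to Cholesky."""
    gamma = fgn_autocovariance(alpha, n, scale, dt)
    # circulant embedding of the covariance sequence
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(row).real
    if np.min(eig) < -1e-8 * np.max(eig):  # embedding failed: exact dense sampler
        cov = np.empty((n, n))
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        cov[:] = gamma[idx]
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
        return chol @ rng.standard_normal(n)
    eig = np.clip(eig, 0.0, None)
    m = row.size
    # synthesize a real stationary sequence with the prescribed spectrum
    z = rng.standard_normal(m // 2 + 1) + 1j * rng.standard_normal(m // 2 + 1)
    z[0] = z[0].real * np.sqrt(2)
    if m % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2)
    w = np.fft.irfft(np.sqrt(eig) * z, n=m) * np.sqrt(m / 2.0)
    return w[:n]


def gen_subdiffusive_track(
    alpha: float,
    scale: float,
    n_frames: int = 100,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    seed: int = 0,
    *,
    bead_id: str = "bead",
    noise_sd: float = 0.0,
) -> BeadTrajectory:
    """Fractional-Brownian-motion track with MSD(t) = 2·scale·t^alpha (2D).

    Each coordinate is fBm with Hurst exponent H = alpha/2, sampled exactly
    (circulant embedding of the fractional-Gaussian-noise covariance, with a
    dense Cholesky fallback).  ``alpha`` in (0, 1) gives sub-diffusion,
    alpha = 1 recovers Brownian motion with D = scale/2 per the 4Dt
    convention, alpha in (1, 2) super-diffusion.
    """
    if not 0 < alpha < 2:
        raise ValueError("alpha must lie in (0, 2)")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if n_frames < MIN_FRAMES:
        raise ValueError(f"n_frames must be >= {MIN_FRAMES}")
    rng = np.random.default_rng(seed)
    increments = np.column_stack(
        [_fgn_davies_harte(alpha, n_frames - 1, scale, frame_interval, rng) for _ in range(2)]
    )
    positions = np.vstack([np.zeros((1, 2)), np.cumsum(increments, axis=0)])
    times = np.arange(n_frames) * frame_interval
    return _finalize(bead_id, times, positions, noise_sd, rng)


def gen_arc_filament(radius: float, arc_angle: float, n_vertices: int = 100) -> FilamentShape:
    """Circular-arc filament contour of given radius subtending ``arc_angle``.

    The discrete contour length converges to radius·arc_angle as the vertex
    count grows; the chord gives the node-to-node separation, so the arc's
    filament tension T -> arc/chord analytically.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 < arc_angle <= 2 * np.pi * 0.99:
        raise ValueError("arc_angle must lie in (0, 0.99·2π]")
    if n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    phi = np.linspace(0.0, arc_angle, n_vertices)
    vertices = radius * np.column_stack([np.cos(phi), np.sin(phi)])
    return FilamentShape(vertices=vertices - vertices[0])


def gen_pbt_sequence(
    length: int,
    planted_runs: list[tuple[int, int]],
    seed: int = 0,
    *,
    seq_id: str = "synthetic",
) -> ProteinSequence:
    """Random non-proline background with proline runs planted at known spans.

    ``planted_runs`` is a list of (start, run_length) with 1-based starts.
    Runs must fit within the sequence, not overlap, and be separated by at
    least one non-proline residue so that each planted run is maximal.
    """
    if length < 1:
        raise ValueError("length must be positive")
    spans = []
    for start, run_length in planted_runs:
        if run_length < 1 or start < 1 or start + run_length - 1 > length:
            raise ValueError(f"run ({start}, {run_length}) out of bounds")
        spans.append((start, start + run_length - 1))
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1 + 1:
            raise ValueError("planted runs must be separated by >= 1 non-proline")
    rng = np.random.default_rng(seed)
    residues = rng.choice(_NON_PROLINE, size=length)
    for start, end in spans:
        residues[start - 1 : end] = "P"
    return ProteinSequence(id=seq_id, residues="".join(residues))
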