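"""Bead-trajectory microrheology: MSD, anomalous exponent, Stokes–Einstein.

The analysis chain mirrors standard single-particle tracking practice:
MSD(t) = <(x(t) − x(0))²> per trajectory, a log–log fit of MSD vs t^alpha to
classify the motion, a through-origin fit of MSD = 4 D t for diffusive
tracks, and the Stokes–Einstein conversions zeta = kBT/D and
eta = kBT/(6 pi D r).  Unit convention: 1 pN·s/nm² = 1e6 Pa·s.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import KBT_DEFAULT, BeadTrajectory, MotionFit, MsdCurve, RheologyEstimate

__all__ = [
    "compute_msd",
    "fit_anomalous_exponent",
    "classify_motion",
    "fit_diffusion_coeff",
    "drag_from_diffusion",
    "viscosity_from_drag",
    "viscosity_from_diffusion",
    "stokes_force",
    "rheology_from_diffusion",
    "ensemble_summary",
    "average_msd",
    "fit_table",
]

#: Pa·s per pN·s/nm².
PA_S_PER_PN_S_NM2 = 1.0e6

#: Motion-class boundaries on the anomalous exponent.
ALPHA_SUB_MAX = 0.8  # subdiffusive: alpha <= 0.8 (boundary closed downward)
ALPHA_DIFF_MAX = 1.05  # diffusive: 0.8 < alpha <= 1.05

DEFAULT_FIT_LAGS = 10


class InsufficientDataError(ValueError):
    """Trajectory or curve too short for the requested analysis."""


def compute_msd(
    traj: BeadTrajectory,
    max_lag_frames: int | None = None,
    averaging: str = "time_averaged",
) -> MsdCurve:
    """Mean-square displacement of one 2D track.

    ``time_averaged`` (default) averages |x(i+k) − x(i)|² over all start
    frames i for each lag k; ``origin_based`` uses only i = 0, matching the
    literal <(x(t) − x(0))²> definition.  Both coordinates are summed, so
    free diffusion gives MSD = 4 D t.
    """
    if averaging not in {"time_averaged", "origin_based"}:
        raise ValueError("averaging must be 'time_averaged' or 'origin_based'")
    n = traj.n_frames
    if max_lag_frames is None:
        max_lag_frames = n - 1
    if max_lag_frames < 1:
        raise ValueError("max_lag_frames must be >= 1")
    if n < max_lag_frames + 1:
        raise InsufficientDataError(
            f"trajectory has {n} frames, need >= {max_lag_frames + 1} for lag {max_lag_frames}"
        )
    pos = traj.positions
    dt = traj.frame_interval
    lags = np.arange(1, max_lag_frames + 1)
    msd = np.empty(lags.size)
    n_pairs = np.empty(lags.size, dtype=int)
    for j, k in enumerate(lags):
        disp = pos[k:] - pos[:-k]
        sq = np.sum(disp**2, axis=1)
        if averaging == "origin_based":
            sq = sq[:1]
        msd[j] = sq.mean()
        n_pairs[j] = sq.size
    return MsdCurve(lags=lags * dt, msd=msd, n_pairs=n_pairs)


def average_msd(curves: list[MsdCurve]) -> MsdCurve:
    """Ensemble-average MSD over curves sharing the same lag grid."""
    if not curves:
        raise InsufficientDataError("need at least one curve")
    n = min(c.lags.size for c in curves)
    lags = curves[0].lags[:n]
    for c in curves:
        if not np.allclose(c.lags[:n], lags, rtol=1e-9):
            raise ValueError("curves must share a common lag grid")
    stack = np.vstack([c.msd[:n] for c in curves])
    pairs = np.vstack([c.n_pairs[:n] for c in curves])
    return MsdCurve(lags=lags, msd=stack.mean(axis=0), n_pairs=pairs.sum(axis=0))


def classify_motion(alpha: float) -> str:
    """Motion class from the anomalous exponent.

    Sub-diffusive for alpha <= 0.8, diffusive for 0.8 < alpha <= 1.05,
    super-diffusive for alpha > 1.05.  The boundary at exactly 0.8 is closed
    downward (assigned sub-diffusive).
    """
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError("alpha must be finite and positive")
    if alpha <= ALPHA_SUB_MAX:
        return "subdiffusive"
    if alpha <= ALPHA_DIFF_MAX:
        return "diffusive"
    return "superdiffusive"


def _fit_window(curve: MsdCurve, fit_lags: int):
    lags = curve.lags[:fit_lags]
    msd = curve.msd[:fit_lags]
    if lags.size < 2:
        raise InsufficientDataError("need at least 2 lags in the fit window")
    return lags, msd


def fit_anomalous_exponent(curve: MsdCurve, fit_lags: int = DEFAULT_FIT_LAGS) -> MotionFit:
    """Least-squares slope of log MSD vs log lag over the first ``fit_lags`` lags."""
    lags, msd = _fit_window(curve, fit_lags)
    if lags.size < 3:
        raise InsufficientDataError("need at least 3 lags for the exponent fit")
    if np.any(msd <= 0):
        raise ValueError("MSD must be positive throughout the fit window")
    alpha, _ = np.polyfit(np.log(lags), np.log(msd), 1)
    alpha = float(alpha)
    diffusion = fit_diffusion_coeff(curve, fit_lags)
    return MotionFit(
        alpha=alpha,
        diffusion_coeff=diffusion,
        motion_class=classify_motion(alpha),
        fit_range=(float(lags[0]), float(lags[-1])),
    )


def fit_diffusion_coeff(curve: MsdCurve, fit_lags: int = DEFAULT_FIT_LAGS) -> float:
    """Through-origin fit of MSD = 4 D t over the first ``fit_lags`` lags (nm²/s)."""
    lags, msd = _fit_window(curve, fit_lags)
    slope = float(np.dot(msd, lags) / np.dot(lags, lags))
    return slope / 4.0


def drag_from_diffusion(D: float, kBT: float = KBT_DEFAULT) -> float:
    """Stokes–Einstein drag zeta = kBT/D in pN·s/nm."""
    if D <= 0:
        raise ValueError("D must be positive")
    return kBT / D


def viscosity_from_drag(zeta: float, r: float) -> float:
    """Viscosity eta = zeta/(6 pi r) converted to Pa·s for a bead of radius r nm."""
    if zeta <= 0 or r <= 0:
        raise ValueError("zeta and r must be positive")
    return zeta / (6.0 * np.pi * r) * PA_S_PER_PN_S_NM2


def viscosity_from_diffusion(D: float, r: float, kBT: float = KBT_DEFAULT) -> float:
    """Viscosity eta = kBT/(6 pi D r) in Pa·s."""
    if D <= 0 or r <= 0:
        raise ValueError("D and r must be positive")
    return kBT / (6.0 * np.pi * D * r) * PA_S_PER_PN_S_NM2


def stokes_force(v: float, r: float, eta: float) -> float:
    """Stokes drag force F = v · 6 pi r eta in pN (v in nm/s, r in nm, eta in Pa·s)."""
    if v < 0:
        raise ValueError("v is a speed and must be non-negative")
    if r <= 0 or eta <= 0:
        raise ValueError("r and eta must be positive")
    return v * 6.0 * np.pi * r * (eta / PA_S_PER_PN_S_NM2)


def rheology_from_diffusion(D: float, r: float, kBT: float = KBT_DEFAULT) -> RheologyEstimate:
    """Bundle zeta and eta derived from one diffusion coefficient."""
    return RheologyEstimate(
        drag_coeff=drag_from_diffusion(D, kBT),
        viscosity=viscosity_from_diffusion(D, r, kBT),
        bead_radius=r,
        kBT=kBT,
    )


def ensemble_summary(fits: list[MotionFit]) -> dict:
    """Counts per motion class plus per-class median and mean D.

    Mirrors the reporting style of tracked-bead ensembles: how many tracks
    fall in each class and the central diffusion coefficient per class.
    """
    if not fits:
        raise InsufficientDataError("need at least one fit")
    summary: dict = {"n_total": len(fits), "classes": {}}
    for cls in ("diffusive", "subdiffusive", "superdiffusive"):
        ds = np.array([f.diffusion_coeff for f in fits if f.motion_class == cls])
        entry = {"count": int(ds.size)}
        if ds.size:
            entry["median_D_nm2_per_s"] = float(np.median(ds))
            entry["mean_D_nm2_per_s"] = float(np.mean(ds))
        summary["classes"][cls] = entry
    summary["median_alpha"] = float(np.median([f.alpha for f in fits]))
    return summary


def fit_table(
    trajs: list[BeadTrajectory],
    fit_lags: int = DEFAULT_FIT_LAGS,
    bead_radius: float = 500.0,
    kBT: float = KBT_DEFAULT,
) -> pd.DataFrame:
    """Per-bead fit table: alpha, class, D, zeta and eta for each trajectory."""
    rows = []
    for traj in trajs:
        curve = compute_msd(traj, min(fit_lags, traj.n_frames - 1))
        fit = fit_anomalous_exponent(curve, fit_lags)
        rows.append(
            {
                "bead_id": traj.bead_id,
                "alpha": fit.alpha,
                "motion_class": fit.motion_class,
                "D_nm2_per_s": fit.diffusion_coeff,
                "zeta_pNs_per_nm": drag_from_diffusion(fit.diffusion_coeff, kBT),
                "eta_Pas": viscosity_from_diffusion(fit.diffusion_coeff, bead_radius, kBT),
            }
        )
    return pd.DataFrame(rows)
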