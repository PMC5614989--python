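"""Core data containers shared across the analysis stages.

Lengths are in nanometres, times in seconds, forces in piconewtons and
energies in pN·nm throughout the package; viscosities cross the SI boundary
(Pa·s) only at the user-facing surface of :mod:`scpsim.msd`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KBT_DEFAULT",
    "BeadTrajectory",
    "FilamentShape",
    "ProteinSequence",
    "MsdCurve",
    "MotionFit",
    "RheologyEstimate",
    "PBTrack",
    "TensionRecord",
    "RateTriple",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "read_filament_csv",
    "write_filament_csv",
    "read_fasta",
    "write_fasta",
]

#: Thermal energy at 298 K in pN·nm.
KBT_DEFAULT = 4.11

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class BeadTrajectory:
    """Time-stamped 2D positions of one tracked bead.

    Positions are in nm; frames must be uniformly spaced in time (the
    default tracking interval is 5 s).  Tracking-grade data carry at least
    20 frames — the synthetic generators enforce that — but the container
    also admits short hand-built tracks for worked examples.
    """

    bead_id: str
    times: np.ndarray
    positions: np.ndarray  # shape (n_frames, 2), nm

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", pos)
        if times.ndim != 1 or pos.shape != (times.size, 2):
            raise ValueError("times must be 1D and positions (n_frames, 2)")
        if times.size < 2:
            raise ValueError("trajectory must have at least 2 frames")
        dts = np.diff(times)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dts, dts[0], rtol=1e-9, atol=0.0):
            raise ValueError("times must be uniformly spaced")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class FilamentShape:
    """Ordered 2D contour of a filament from the formin end to the myosin end."""

    vertices: np.ndarray  # shape (n, 2), nm

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "vertices", v)
        if v.shape[0] < 2 or v.shape[1] != 2:
            raise ValueError("filament shape needs at least 2 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")

    @property
    def contour_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    @property
    def end_to_end(self) -> float:
        return float(np.hypot(*(self.vertices[-1] - self.vertices[0])))


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence in one-letter code (the 20 standard residues plus X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", str(self.residues).upper())
        bad = set(self.residues) - _AA_ALPHABET
        if bad:
            raise ValueError(f"non-standard residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MsdCurve:
    """Mean-square displacement vs lag time for one trajectory.

    ``msd`` sums both in-plane coordinates, so free diffusion follows
    MSD(t) = 4 D t.  ``n_pairs`` records how many displacement pairs entered
    each lag average.
    """

    lags: np.ndarray  # s
    msd: np.ndarray  # nm^2
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        msd = np.asarray(self.msd, dtype=float)
        n_pairs = np.asarray(self.n_pairs, dtype=int)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "msd", msd)
        object.__setattr__(self, "n_pairs", n_pairs)
        if not (lags.shape == msd.shape == n_pairs.shape):
            raise ValueError("lags, msd, n_pairs must have identical shape")
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(msd < 0):
            raise ValueError("msd must be non-negative")


@dataclass(frozen=True)
class MotionFit:
    """Anomalous-exponent fit of one MSD curve.

    ``motion_class`` follows the bead-tracking convention: sub-diffusive for
    alpha < 0.8, diffusive for 0.8 < alpha <= 1.05, super-diffusive above.
    """

    alpha: float
    diffusion_coeff: float  # nm^2/s
    motion_class: str
    fit_range: tuple[float, float]  # (min lag, max lag) in s

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError("alpha must be finite and positive")
        if self.motion_class not in {"diffusive", "subdiffusive", "superdiffusive"}:
            raise ValueError(f"unknown motion class {self.motion_class!r}")


@dataclass(frozen=True)
class RheologyEstimate:
    """Stokes–Einstein drag and viscosity derived from one diffusion coefficient."""

    drag_coeff: float  # pN·s/nm
    viscosity: float  # Pa·s
    bead_radius: float  # nm
    kBT: float  # pN·nm

    def __post_init__(self) -> None:
        for name in ("drag_coeff", "viscosity", "bead_radius", "kBT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PBTrack:
    """One poly-L-proline track (PBT): 1-based inclusive residue span.

    ``run_length`` keeps the length of the maximal proline run the track was
    carved from, so alternative conventions for splitting long runs can be
    recomputed.  Tracks produced by splitting a run longer than 12 may be
    shorter than the 4-residue detection threshold.
    """

    start: int
    end: int
    run_length: int
    distance_to_fh2: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError("need 1 <= start <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TensionRecord:
    """Filament tension T = contour length / node separation with its class."""

    contour_length: float  # nm
    separation: float  # nm
    T: float
    tension_class: str  # "high" (1 <= T <= 1.15, taut) or "low" (T > 1.15, slack)


@dataclass(frozen=True)
class RateTriple:
    """Elongation rates (subunits/s) before, during and after Capture-Pull."""

    before: float
    during: float
    after: float | None = None

    def __post_init__(self) -> None:
        for r in (self.before, self.during, self.after):
            if r is not None and r < 0:
                raise ValueError("rates must be non-negative")


# ---------------------------------------------------------------------------
# plain-text I/O


def write_trajectories_csv(trajectories: Iterable[BeadTrajectory], path: str | Path) -> None:
    """Write bead trajectories as ``bead_id,frame,time_s,x_nm,y_nm`` CSV."""
    frames = []
    for traj in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "bead_id": traj.bead_id,
                    "frame": np.arange(traj.n_frames),
                    "time_s": traj.times,
                    "x_nm": traj.positions[:, 0],
                    "y_nm": traj.positions[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories_csv(path: str | Path) -> list[BeadTrajectory]:
    """Read a ``bead_id,frame,time_s,x_nm,y_nm`` CSV into one trajectory per bead."""
    df = pd.read_csv(path)
    required = {"bead_id", "frame", "time_s", "x_nm", "y_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    out = []
    for bead_id, group in df.groupby("bead_id", sort=False):
        group = group.sort_values("frame")
        out.append(
            BeadTrajectory(
                bead_id=str(bead_id),
                times=group["time_s"].to_numpy(),
                positions=group[["x_nm", "y_nm"]].to_numpy(),
            )
        )
    return out


def write_filament_csv(shape: FilamentShape, path: str | Path) -> None:
    pd.DataFrame(
        {
            "vertex": np.arange(shape.vertices.shape[0]),
            "x_nm": shape.vertices[:, 0],
            "y_nm": shape.vertices[:, 1],
        }
    ).to_csv(path, index=False)


def read_filament_csv(path: str | Path) -> FilamentShape:
    df = pd.read_csv(path)
    missing = {"vertex", "x_nm", "y_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"filament CSV missing columns: {sorted(missing)}")
    df = df.sort_values("vertex")
    return FilamentShape(vertices=df[["x_nm", "y_nm"]].to_numpy())


def write_fasta(sequences: Sequence[ProteinSequence], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    from Bio.SeqIO import parse

    return [ProteinSequence(id=rec.id, residues=str(rec.seq)) for rec in parse(str(path), "fasta")]
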