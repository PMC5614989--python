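"""Scalar Capture-Pull metrics: filament tension, rate normalization, folds.

Filament tension T is the ratio of node-to-node contour length to the
straight-line node separation at the point of capture: T = 1 is a taut
filament ("high tension", 1 <= T <= 1.15), larger T means slack ("low
tension", T > 1.15).  Elongation rates before/during/after Capture-Pull are
normalized to the pre-capture baseline, and inhibition is summarized as the
fold reduction before/during.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import FilamentShape, RateTriple, TensionRecord

__all__ = [
    "filament_tension",
    "normalize_rates",
    "fold_change",
    "subs_to_nm",
    "fit_elongation_rates",
    "baseline_resumed",
    "TENSION_HIGH_MAX",
]

#: Boundary between "high" (taut, T <= 1.15) and "low" (slack, T > 1.15) tension.
TENSION_HIGH_MAX = 1.15

#: Axial length added per actin subunit at the barbed end, nm.
SUBUNIT_RISE_NM = 2.7

#: Relative tolerance for clamping T marginally below 1 (digitization noise).
_T_CLAMP_RTOL = 1e-3


def filament_tension(shape: FilamentShape) -> TensionRecord:
    """Tension T = contour length / end-to-end separation with its class.

    T marginally below 1 (within 0.1% relative, digitization noise) is
    clamped to 1; larger violations of the contour >= chord geometry are
    rejected as invalid.
    """
    contour = shape.contour_length
    sep = shape.end_to_end
    if sep <= 0 or not np.isfinite(sep):
        raise ValueError("node separation must be positive")
    T = contour / sep
    if T < 1.0:
        if T >= 1.0 - _T_CLAMP_RTOL:
            T = 1.0
        else:
            raise ValueError(f"contour length below separation (T = {T:.6f})")
    cls = "high" if T <= TENSION_HIGH_MAX else "low"
    return TensionRecord(contour_length=contour, separation=sep, T=T, tension_class=cls)


def normalize_rates(rates: RateTriple) -> tuple[float, float, float | None]:
    """Rates during/after Capture-Pull normalized to the pre-capture rate."""
    if rates.before <= 0:
        raise ValueError("pre-capture rate must be positive to normalize")
    after = None if rates.after is None else rates.after / rates.before
    return (1.0, rates.during / rates.before, after)


def fold_change(before: float, during: float) -> float:
    """Fold reduction of the elongation rate during Capture-Pull (before/during)."""
    if during < 0 or before < 0:
        raise ValueError("rates must be non-negative")
    if during == 0:
        return float("inf")  # complete inhibition
    return before / during


def subs_to_nm(rate: float, subunit_rise: float = SUBUNIT_RISE_NM) -> float:
    """Convert an elongation rate in subunits/s to filament-length growth in nm/s."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return rate * subunit_rise


def fit_elongation_rates(trace: pd.DataFrame) -> RateTriple:
    """Per-phase least-squares elongation rates from a length-vs-time trace.

    ``trace`` columns: ``time_s``, ``length_subunits``, ``phase`` with phase
    labels 'before', 'during' and optionally 'after'.  Each phase's rate is
    the OLS slope of length vs time within that phase.
    """
    required = {"time_s", "length_subunits", "phase"}
    missing = required - set(trace.columns)
    if missing:
        raise ValueError(f"trace missing columns: {sorted(missing)}")

    def slope(phase: str) -> float | None:
        sub = trace[trace["phase"] == phase]
        if len(sub) < 2:
            return None
        m, _ = np.polyfit(sub["time_s"].to_numpy(), sub["length_subunits"].to_numpy(), 1)
        return float(m)

    before = slope("before")
    during = slope("during")
    if before is None or during is None:
        raise ValueError("trace must contain >= 2 points in both 'before' and 'during'")
    return RateTriple(before=before, during=during, after=slope("after"))


def baseline_resumed(rates: RateTriple, rel_band: float = 0.5) -> bool:
    """Whether the post-capture rate returned to the pre-capture baseline.

    Events whose elongation does not resume near the baseline after the
    myosin releases are conventionally excluded from rate statistics.  The
    acceptance band (default +/-50% of the pre-capture rate) is a
    configurable convention, as no standard quantitative definition exists.
    """
    if rates.after is None:
        return False
    return abs(rates.after - rates.before) <= rel_band * rates.before
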