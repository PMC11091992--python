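"""Raw repetition traces -> normalized 1-degree extension moment curves.

The pipeline mirrors standard practice for qualitative moment-curve
reading: resample each repetition onto a 1-degree flexion grid by linear
interpolation, replace samples recorded off the isokinetic plateau
(\\|velocity\\| < 50 deg/s) or missing altogether by interpolation across
the gap, normalize to the repetition's own peak moment, and restrict the
analysis to the 2nd-4th repetitions to avoid movement-strategy changes
in the first and last efforts.

Curves are stored indexed by ascending flexion angle (10..90 deg) but
conceptually read in extension order (90 deg -> 10 deg): "before the
peak" always means a larger flexion angle than the peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CurveRejectionError, DegenerateCurveError, TrialRejectionError
from .synthetic import PLATEAU_THRESHOLD, TorqueCurve

#: The fixed flexion-angle grid, degrees (81 points).
GRID: np.ndarray = np.arange(10, 91, dtype=float)

#: Repetitions analyzed for pattern classification (1-based indices).
ANALYZED_REPETITIONS: tuple[int, ...] = (2, 3, 4)

_MIN_SPAN = (GRID[-1] - GRID[0]) / 2.0  # half the ROM


@dataclass
class NormalizedCurve:
    """A peak-normalized extension moment curve on the 1-degree grid.

    ``value`` is torque / peak torque at each grid angle (ascending
    flexion); its maximum is exactly 1.
    """

    value: np.ndarray
    peak_angle: float
    peak_torque: float
    repetition_index: int = 1

    @property
    def grid(self) -> np.ndarray:
        return GRID


def resample_to_grid(curve: TorqueCurve) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate torque and velocity onto the 1-degree grid.

    Grid angles outside the sampled span are returned as NaN (to be
    handled by :func:`fill_missing`).

    Returns
    -------
    (torque, velocity)
        Arrays aligned with :data:`GRID`.

    Raises
    ------
    CurveRejectionError
        Fewer than two valid samples, or the samples span less than half
        the range of motion.
    """
    valid = np.isfinite(curve.angle) & np.isfinite(curve.torque)
    if valid.sum() < 2:
        raise CurveRejectionError("need at least two valid samples to resample")
    ang = curve.angle[valid]
    if ang.max() - ang.min() < _MIN_SPAN:
        raise CurveRejectionError(
            f"samples span {ang.max() - ang.min():.1f} deg, "
            f"less than half the {GRID[-1] - GRID[0]:.0f} deg range of motion"
        )
    order = np.argsort(ang, kind="stable")
    ang_sorted = ang[order]
    torque = np.interp(GRID, ang_sorted, curve.torque[valid][order])
    vel_valid = np.isfinite(curve.velocity[valid])
    if vel_valid.any():
        velocity = np.interp(GRID, ang_sorted[vel_valid],
                             curve.velocity[valid][order][vel_valid])
    else:
        velocity = np.full_like(GRID, np.nan)
    outside = (GRID < ang_sorted[0]) | (GRID > ang_sorted[-1])
    torque[outside] = np.nan
    velocity[outside] = np.nan
    return torque, velocity


def fill_missing(
    torque: np.ndarray,
    velocity: np.ndarray,
    threshold: float = PLATEAU_THRESHOLD,
) -> np.ndarray:
    """Replace off-plateau and absent grid samples by linear interpolation.

    A grid point is invalid when its torque or velocity is missing or
    \\|velocity\\| < ``threshold`` (acceleration/deceleration phases,
    judged on the absolute velocity).  Interior invalid runs are bridged
    by the straight line between the flanking valid samples; invalid
    runs at the grid ends take the nearest valid value.

    Raises
    ------
    CurveRejectionError
        If no valid sample remains.
    """
    torque = np.asarray(torque, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if torque.shape != GRID.shape or velocity.shape != GRID.shape:
        raise ValueError("fill_missing expects arrays aligned with the 1-degree grid")
    invalid = ~np.isfinite(torque) | ~np.isfinite(velocity) | (np.abs(velocity) < threshold)
    if invalid.all():
        raise CurveRejectionError("no samples on the isokinetic plateau")
    if not invalid.any():
        return torque.copy()
    valid_idx = np.flatnonzero(~invalid)
    filled = torque.copy()
    filled[invalid] = np.interp(GRID[invalid], GRID[valid_idx], torque[valid_idx])
    return filled


def normalize_to_peak(torque: np.ndarray, repetition_index: int = 1) -> NormalizedCurve:
    """Divide a gridded curve by its own peak moment.

    The peak angle is the argmax; exact ties are broken toward the angle
    closest to the middle of the range of motion, then toward the larger
    flexion angle.

    Raises
    ------
    DegenerateCurveError
        If the curve contains no positive torque.
    """
    torque = np.asarray(torque, dtype=float)
    if torque.shape != GRID.shape:
        raise ValueError("normalize_to_peak expects an array aligned with the 1-degree grid")
    peak = float(np.max(torque))
    if not peak > 0:
        raise DegenerateCurveError("all-zero torque curve cannot be normalized")
    candidates = np.flatnonzero(torque >= peak - 1e-12 * max(peak, 1.0))
    mid = (GRID[0] + GRID[-1]) / 2.0
    best = min(candidates, key=lambda i: (abs(GRID[i] - mid), -GRID[i]))
    return NormalizedCurve(
        value=torque / peak,
        peak_angle=float(GRID[best]),
        peak_torque=peak,
        repetition_index=repetition_index,
    )


def select_repetitions(trial: Sequence[TorqueCurve]) -> list[TorqueCurve]:
    """Return the 2nd, 3rd and 4th repetitions, in order.

    Raises
    ------
    TrialRejectionError
        If fewer than four repetitions are present, or any of the
        analyzed repetitions is missing.
    """
    if len(trial) < 4:
        raise TrialRejectionError(
            f"trial has {len(trial)} repetitions; at least 4 are required"
        )
    by_index = {c.repetition_index: c for c in trial}
    missing = [i for i in ANALYZED_REPETITIONS if i not in by_index]
    if missing:
        raise TrialRejectionError(f"missing analyzed repetitions {missing}")
    return [by_index[i] for i in ANALYZED_REPETITIONS]


def preprocess_repetition(curve: TorqueCurve) -> NormalizedCurve:
    """Resample, fill, and peak-normalize a single repetition."""
    torque, velocity = resample_to_grid(curve)
    filled = fill_missing(torque, velocity)
    return normalize_to_peak(filled, repetition_index=curve.repetition_index)


def preprocess_trial(trial: Sequence[TorqueCurve]) -> list[NormalizedCurve]:
    """Select repetitions 2-4 and preprocess each."""
    return [preprocess_repetition(c) for c in select_repetitions(trial)]
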