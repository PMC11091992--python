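"""Rule-based classification of extension moment-curve morphology.

A healthy concentric knee-extension moment curve is smooth and roughly
parabolic with its peak near mid-range.  The classifier operationalizes
the qualitative taxonomy used by visual raters:

* ``Valley``  - one slight, recovering notch before or near the peak;
* ``Drop``    - a sharp fall right after the peak that never recovers;
* ``Shaking`` - repeated flutter excursions along the middle of the
  curve, spanning the peak;
* ``Normal``  - none of the above.

Breakpoints ("deviations from the prevailing pattern") are detected by
(1) local quadratic smoothing, (2) robustly fitting a concave quadratic
baseline that represents the prevailing parabolic shape — points far
below the running fit are iteratively trimmed so the artifact itself
does not distort the baseline — and (3) extracting contiguous excursions
of the curve below that baseline.  Each excursion carries its depth
(maximum shortfall from the baseline, in fractions of peak torque), its
sharpness (steepest per-degree decrease), whether the curve later
recovers to near its pre-break level, and its position relative to the
peak in extension order.

Decision rules are applied with precedence Shaking > Drop > Valley:
flutter descriptions subsume single disturbances, and fixed precedence
makes curves that raters find ambiguous deterministic.

A trial is labelled irregular only when all three analyzed repetitions
receive the *same* irregular label (the consistency rule); otherwise it
is Normal.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import ValidationError
from .preprocess import GRID, NormalizedCurve

_REGION_EPS_FRACTION = 0.5  # excursion extent threshold, fraction of min_depth


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the decision rules.

    The visual taxonomy defines shapes, not numbers; these defaults are
    calibration choices that recover the synthetic generator's canonical
    artifacts, documented here with their units.

    smoothing_window : deg, width of the local quadratic smoother.
    min_depth : fraction of peak; irregularity floor for any breakpoint.
    valley_max_depth : fraction of peak; a recovering notch deeper than
        this is no longer "slight".
    drop_min_depth / drop_min_sharpness : fraction of peak and fraction
        of peak per degree; a non-recovering fall must be this deep and
        this steep to count as a Drop.
    near_peak_window / post_peak_window : deg around the peak defining
        "near the peak" (at or preceding) and "right after the peak".
    flutter_min_oscillations / flutter_min_amplitude : how many
        excursions of what amplitude constitute Shaking.
    mid_region : fractional interval of the range of motion in which
        flutter excursions must lie.
    recovery_factor : a breakpoint "recovers" when the curve later
        re-attains this fraction of its pre-break level.
    baseline_trim / baseline_iterations : robust-baseline fitting; grid
        points deviating more than ``baseline_trim`` from the running
        quadratic fit are excluded and the fit repeated.
    baseline_fit_margin : deg; the baseline is fitted only to grid
        points at least this far from the ends of the range of motion,
        where acceleration/deceleration filling can flatten the trace,
        then evaluated on the full grid.
    """

    smoothing_window: float = 5.0
    min_depth: float = 0.03
    valley_max_depth: float = 0.15
    drop_min_depth: float = 0.20
    drop_min_sharpness: float = 0.05
    near_peak_window: float = 15.0
    post_peak_window: float = 10.0
    flutter_min_oscillations: int = 3
    flutter_min_amplitude: float = 0.05
    mid_region: tuple[float, float] = (0.25, 0.75)
    recovery_factor: float = 0.90
    baseline_trim: float = 0.02
    baseline_iterations: int = 4
    baseline_fit_margin: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.min_depth < self.valley_max_depth < self.drop_min_depth <= 1:
            raise ValidationError(
                "require 0 < min_depth < valley_max_depth < drop_min_depth <= 1"
            )
        for name in ("smoothing_window", "near_peak_window", "post_peak_window"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.flutter_min_oscillations < 1:
            raise ValidationError("flutter_min_oscillations must be >= 1")
        if not 0 < self.flutter_min_amplitude <= 1:
            raise ValidationError("flutter_min_amplitude must lie in (0, 1]")
        lo, hi = self.mid_region
        if not 0 <= lo < hi <= 1:
            raise ValidationError("mid_region must be an increasing sub-interval of [0, 1]")
        if not 0 < self.recovery_factor <= 1:
            raise ValidationError("recovery_factor must lie in (0, 1]")


def config_from_mapping(mapping: Mapping[str, object]) -> ClassifierConfig:
    """Build a config from a parsed YAML/JSON mapping, rejecting unknown keys."""
    known = {f.name for f in fields(ClassifierConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ValidationError(f"unknown classifier config keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    if "mid_region" in kwargs:
        kwargs["mid_region"] = tuple(kwargs["mid_region"])  # type: ignore[arg-type]
    return ClassifierConfig(**kwargs)  # type: ignore[arg-type]


@dataclass(frozen=True)
class Breakpoint:
    """One excursion of the curve below its prevailing parabolic baseline.

    ``angle`` is the flexion angle at which the curve leaves the
    baseline (the break onset); ``dip_angle`` that of its worst
    shortfall; ``position`` locates the onset relative to the peak of
    the prevailing shape in extension order (before_peak / near_peak at
    or preceding the peak, after_peak following it).
    """

    angle: float
    depth: float
    sharpness: float
    recovers: bool
    position: str
    dip_angle: float


def _smooth(values: np.ndarray, window_deg: float) -> np.ndarray:
    n = max(3, int(round(window_deg)))
    if n % 2 == 0:
        n += 1
    n = min(n, len(values) if len(values) % 2 else len(values) - 1)
    return savgol_filter(values, window_length=n, polyorder=2)


def _robust_baseline(
    y: np.ndarray,
    trim: float,
    n_iter: int,
    fit_mask: np.ndarray,
    start_mask: np.ndarray,
) -> np.ndarray:
    """Quadratic fit of the prevailing curve shape.

    Only points in ``fit_mask`` (the interior of the range of motion,
    away from the flat-extrapolated ramp ends) enter the fit.  The
    irregular morphologies are one-sided shortfalls, so the fit must
    settle on the prevailing *upper* branch of the curve.  A plain
    trimmed iteration can lock onto a compromise quadratic that hugs
    both branches of a non-recovering drop, so the iteration starts
    from the pre-peak limb (``start_mask``), which post-peak falls leave
    intact, and then repeatedly refits on every interior point within
    ``trim`` below the running fit.  The fit is evaluated on the full
    grid.
    """
    x = np.arange(len(y), dtype=float)
    keep = fit_mask & start_mask
    if keep.sum() < 10:
        keep = fit_mask.copy()
    coef = np.polyfit(x[keep], y[keep], 2)
    fit = np.polyval(coef, x)
    for _ in range(max(2, n_iter)):
        new_keep = fit_mask & (y - fit > -trim)
        if new_keep.sum() < 10 or bool(np.all(new_keep == keep)):
            break
        keep = new_keep
        coef = np.polyfit(x[keep], y[keep], 2)
        fit = np.polyval(coef, x)
    return fit, coef


def _prepare(curve: NormalizedCurve, config: ClassifierConfig):
    """Smoothed extension-order curve, baseline, residual, and the
    baseline's apex angle (the stable positional reference for "before"
    and "after the peak": the argmax of a noisy curve wanders several
    degrees along the flat apex of the parabola, the fitted vertex does
    not)."""
    if curve.value.shape != GRID.shape:
        raise ValidationError("expected an 81-point normalized curve")
    # Extension order: flexion 90 deg -> 10 deg.
    y = _smooth(curve.value[::-1], config.smoothing_window)
    angles = GRID[::-1]
    margin = config.baseline_fit_margin
    fit_mask = (angles >= GRID[0] + margin) & (angles <= GRID[-1] - margin)
    start_mask = angles >= curve.peak_angle
    baseline, coef = _robust_baseline(
        y, config.baseline_trim, config.baseline_iterations, fit_mask, start_mask
    )
    residual = baseline - y  # positive where the curve falls short
    ref_peak = curve.peak_angle
    if coef[0] < 0:
        vertex_idx = -coef[1] / (2.0 * coef[0])
        vertex_angle = float(np.clip(angles[0] - vertex_idx, GRID[0], GRID[-1]))
        # Heavy flutter can tilt the quadratic; trust the vertex only
        # when it lands near the observed peak.
        if abs(vertex_angle - curve.peak_angle) <= 15.0:
            ref_peak = vertex_angle
    return y, angles, baseline, residual, ref_peak


def detect_breakpoints(
    curve: NormalizedCurve, config: ClassifierConfig | None = None
) -> list[Breakpoint]:
    """Locate and characterize every breakpoint of a normalized curve.

    Returns the contiguous excursions of the smoothed curve below its
    robust parabolic baseline, in extension order, whose worst shortfall
    reaches the ``min_depth`` irregularity floor.  A clean parabola
    yields an empty list.
    """
    config = config or ClassifierConfig()
    y, angles, baseline, residual, ref_peak = _prepare(curve, config)
    floor = config.min_depth

    eps = _REGION_EPS_FRACTION * config.min_depth
    below = residual > eps
    # Per-degree decreases of the smoothed curve, extension order.
    drops = y[:-1] - y[1:]

    breakpoints: list[Breakpoint] = []
    n = len(y)
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        depth = float(residual[i : j + 1].max())
        if depth >= floor:
            dip = i + int(np.argmax(residual[i : j + 1]))
            lo_k = max(i - 1, 0)
            seg = drops[lo_k : min(j, n - 2) + 1]
            sharpness = float(seg.max()) if seg.size else 0.0
            # Break onset: the first steep descent within the excursion
            # when one exists (stable for long non-recovering falls whose
            # shallow leading edge wanders with noise), otherwise the
            # last point still on the baseline before the excursion.
            steep = np.flatnonzero(seg >= config.drop_min_sharpness)
            if steep.size:
                angle = float(angles[lo_k + int(steep[0])]) - 0.5
            else:
                angle = float(angles[lo_k])
            pre_break = float(y[i - 1]) if i > 0 else float(y[i])
            tail = y[dip:]
            recovers = bool(tail.size and tail.max() >= config.recovery_factor * pre_break)
            rel = angle - ref_peak  # >0: before the peak (extension order)
            if rel < 0:
                position = "after_peak"
            elif rel <= config.near_peak_window:
                position = "near_peak"
            else:
                position = "before_peak"
            breakpoints.append(
                Breakpoint(
                    angle=angle,
                    depth=depth,
                    sharpness=sharpness,
                    recovers=recovers,
                    position=position,
                    dip_angle=float(angles[dip]),
                )
            )
        i = j + 1
    return breakpoints


def classify_repetition(
    curve: NormalizedCurve, config: ClassifierConfig | None = None
) -> str:
    """Label one repetition: Shaking > Drop > Valley > Normal."""
    config = config or ClassifierConfig()
    y, angles, _baseline, residual, ref_peak = _prepare(curve, config)

    # Shaking: enough prominent flutter troughs along the middle of the
    # curve, spanning the peak.  Trough prominence is measured on the
    # baseline residual (scipy peak prominences on the detrended curve),
    # so the strong curvature of the parabolic envelope does not mask
    # oscillations on its descending limb.
    flutter_floor = config.flutter_min_amplitude
    lo = GRID[0] + config.mid_region[0] * (GRID[-1] - GRID[0])
    hi = GRID[0] + config.mid_region[1] * (GRID[-1] - GRID[0])
    troughs, _props = find_peaks(residual, prominence=flutter_floor)
    dips = [float(angles[t]) for t in troughs if lo <= angles[t] <= hi]
    if len(dips) >= config.flutter_min_oscillations:
        if min(dips) < curve.peak_angle < max(dips):
            return "Shaking"

    bps = detect_breakpoints(curve, config)

    for b in bps:
        gap = ref_peak - b.angle  # deg past the peak at which the fall starts
        if (
            not b.recovers
            and b.depth >= config.drop_min_depth
            and b.sharpness >= config.drop_min_sharpness
            and -2.0 <= gap <= config.post_peak_window
        ):
            return "Drop"

    for b in bps:
        if (
            b.recovers
            and config.min_depth <= b.depth <= config.valley_max_depth
            and b.position in ("before_peak", "near_peak")
        ):
            return "Valley"

    return "Normal"


def classify_trial(
    repetitions: Sequence[NormalizedCurve], config: ClassifierConfig | None = None
) -> str:
    """Apply the three-repetition consistency rule.

    The trial is labelled with an irregular pattern only when all three
    analyzed repetitions receive that same irregular label; any
    disagreement (including two different irregular labels) yields
    Normal.
    """
    if len(repetitions) != 3:
        raise ValidationError(
            f"consistency rule needs exactly 3 analyzed repetitions, got {len(repetitions)}"
        )
    labels = [classify_repetition(c, config) for c in repetitions]
    if labels[0] != "Normal" and labels.count(labels[0]) == 3:
        return labels[0]
    return "Normal"
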