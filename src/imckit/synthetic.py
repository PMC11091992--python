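"""Synthetic isokinetic knee-extension trials.

Emulates concentric knee-extensor testing on an isokinetic dynamometer:
five maximal repetitions at a nominal 60 deg/s over a 90 deg - 10 deg
flexion range of motion.  The extensor torque-angle curve of a healthy
repetition is modelled as a parabola peaking near mid-range; the three
irregular morphologies are injected as additive kernels on the
normalized curve:

* ``Valley`` - a slight, recovering Gaussian notch shortly before the peak;
* ``Drop``   - a sharp logistic fall just after the peak that never recovers;
* ``Shaking`` - a tapered sinusoidal flutter spanning the middle of the
  range of motion, including the peak.

Angular velocity follows a trapezoidal profile (linear ramps over the
first and last 8 deg), so each repetition contains acceleration and
deceleration samples with \\|velocity\\| below the 50 deg/s isokinetic
plateau that the preprocessing stage must replace.  Gaussian measurement
noise is added in proportion to the repetition's peak torque.

All randomness flows from a single root seed through
``numpy.random.SeedSequence`` spawning, so identical specifications
yield bitwise-identical traces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .labels import (
    CLASS_ORDER,
    PATTERN_ORDER,
    validate_class,
    validate_pattern,
)
from . import fixtures

#: Velocity magnitude (deg/s) below which a sample is off the isokinetic
#: plateau and treated as missing by the preprocessing stage.
PLATEAU_THRESHOLD = 50.0


@dataclass(frozen=True)
class CurveSpec:
    """Parameters of one synthetic trial (five repetitions of one leg).

    Torque amplitudes of the artifact kernels are expressed as fractions
    of the repetition's peak torque; angles are degrees of knee flexion.
    ``hq_ratio`` (flexor/extensor peak ratio) is carried as metadata only
    — flexor traces are not modelled.
    """

    pattern: str = "Normal"
    peak_torque: float = 180.0           # N·m
    peak_angle: float = 50.0             # deg flexion
    rom: tuple[float, float] = (90.0, 10.0)   # start, end flexion
    nominal_velocity: float = 60.0       # deg/s
    noise_sd: float = 0.0                # fraction of peak torque
    notch_depth: float = 0.08            # Valley: fraction of peak
    notch_offset: float = 8.0            # deg before the peak (extension order)
    notch_width: float = 4.0             # deg, full width at half maximum
    drop_depth: float = 0.30             # Drop: fraction of peak
    drop_offset: float = 5.0             # deg after the peak
    drop_scale: float = 1.0              # deg, logistic steepness
    flutter_cycles: int = 5              # Shaking: oscillation periods
    flutter_amplitude: float = 0.10      # fraction of peak
    flutter_span: tuple[float, float] = (0.25, 0.75)  # fraction of ROM
    hq_ratio: float = 0.65
    n_repetitions: int = 5
    seed: int = 0
    angle_step: float = 0.4              # deg between raw samples
    ramp_deg: float = 8.0                # deg of acceleration/deceleration

    def __post_init__(self) -> None:
        validate_pattern(self.pattern)
        start, end = self.rom
        if not start > end:
            raise ValidationError(f"rom must run from high to low flexion, got {self.rom}")
        if self.peak_torque <= 0:
            raise ValidationError("peak_torque must be positive")
        if not end < self.peak_angle < start:
            raise ValidationError(
                f"peak_angle {self.peak_angle} must lie strictly inside the ROM {self.rom}"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.flutter_cycles < 0:
            raise ValidationError("flutter_cycles must be >= 0")
        if self.n_repetitions < 1:
            raise ValidationError("n_repetitions must be >= 1")
        if self.hq_ratio <= 0:
            raise ValidationError("hq_ratio must be positive")


@dataclass
class TorqueCurve:
    """One repetition's raw dynamometer trace, ordered by acquisition time."""

    angle: np.ndarray       # deg knee flexion
    velocity: np.ndarray    # deg/s, signed (negative while extending)
    torque: np.ndarray      # N·m, >= 0
    repetition_index: int = 1
    subject_id: str = ""
    side: str = "R"

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        if not (len(self.angle) == len(self.velocity) == len(self.torque)):
            raise ValidationError("angle, velocity and torque must be equally long")
        finite = self.angle[np.isfinite(self.angle)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 100.0):
            raise ValidationError("flexion angles must lie within [0, 100] deg")


@dataclass(frozen=True)
class CohortSpec:
    """How to sample a cohort of trials with known injected patterns.

    ``pattern_distribution`` maps injury class -> pattern -> trial count
    and defaults to the packaged study table; ``class_counts`` is derived
    from it (and validated against it when given explicitly).
    """

    pattern_distribution: Mapping[str, Mapping[str, int]] | pd.DataFrame | None = None
    class_counts: Mapping[str, int] | None = None
    noise_sd: float = 0.02
    seed: int = 0

    def distribution(self) -> pd.DataFrame:
        """Resolve the distribution as a pattern x class count DataFrame."""
        dist = self.pattern_distribution
        if dist is None:
            table = fixtures.study_counts()
        elif isinstance(dist, pd.DataFrame):
            table = dist.reindex(index=list(PATTERN_ORDER), columns=list(CLASS_ORDER))
            table = table.fillna(0).astype(int)
        else:
            table = pd.DataFrame(0, index=list(PATTERN_ORDER), columns=list(CLASS_ORDER))
            for cls, row in dist.items():
                validate_class(cls)
                for pattern, count in row.items():
                    validate_pattern(pattern)
                    table.at[pattern, cls] = int(count)
        if (table.to_numpy() < 0).any():
            raise ValidationError("pattern_distribution counts must be non-negative")
        if self.class_counts is not None:
            for cls, n in self.class_counts.items():
                validate_class(cls)
                if int(table[cls].sum()) != int(n):
                    raise ValidationError(
                        f"class_counts[{cls!r}]={n} does not match the "
                        f"pattern_distribution column sum {int(table[cls].sum())}"
                    )
        return table


@dataclass(frozen=True)
class RaterSimSpec:
    """Row-stochastic mislabelling model for one simulated rater."""

    confusion_rates: Mapping[str, Mapping[str, float]]
    n_items: int | None = None
    seed: int = 0

    def matrix(self) -> pd.DataFrame:
        mat = pd.DataFrame(0.0, index=list(PATTERN_ORDER), columns=list(PATTERN_ORDER))
        for truth, row in self.confusion_rates.items():
            validate_pattern(truth)
            for assigned, p in row.items():
                validate_pattern(assigned)
                mat.at[truth, assigned] = float(p)
        arr = mat.to_numpy()
        if (arr < 0).any():
            raise ValidationError("confusion rates must be non-negative")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("each confusion row must sum to 1 within 1e-9")
        return mat


@dataclass
class CohortTrial:
    """One generated trial with its ground truth."""

    trial_id: str
    injury_class: str
    injected_pattern: str
    spec: CurveSpec
    repetitions: list[TorqueCurve]


def identity_confusion() -> dict[str, dict[str, float]]:
    """A perfect rater: every label reproduced exactly."""
    return {p: {p: 1.0} for p in PATTERN_ORDER}


def uniform_confusion() -> dict[str, dict[str, float]]:
    """A rater guessing uniformly at random, ignoring the true label."""
    k = len(PATTERN_ORDER)
    return {p: {q: 1.0 / k for q in PATTERN_ORDER} for p in PATTERN_ORDER}


def _speed_profile(angle: np.ndarray, spec: CurveSpec) -> np.ndarray:
    start, end = spec.rom
    up = (start - angle) / spec.ramp_deg
    down = (angle - end) / spec.ramp_deg
    frac = np.clip(np.minimum(up, down), 0.0, 1.0)
    return spec.nominal_velocity * frac


def _artifact(angle: np.ndarray, spec: CurveSpec) -> np.ndarray:
    """Pattern kernel in normalized torque units (fraction of peak)."""
    if spec.pattern == "Valley":
        center = spec.peak_angle + spec.notch_offset
        sigma = spec.notch_width / 2.3548  # FWHM -> standard deviation
        return -spec.notch_depth * np.exp(-0.5 * ((angle - center) / sigma) ** 2)
    if spec.pattern == "Drop":
        center = spec.peak_angle - spec.drop_offset
        return -spec.drop_depth * expit((center - angle) / spec.drop_scale)
    if spec.pattern == "Shaking":
        start, end = spec.rom
        lo = end + spec.flutter_span[0] * (start - end)
        hi = end + spec.flutter_span[1] * (start - end)
        t = (hi - angle) / (hi - lo)
        inside = (t >= 0.0) & (t <= 1.0)
        wave = np.zeros_like(angle)
        # Tukey-tapered sinusoid: cosine-smoothed entry/exit over the
        # outer 20% of the span each side, full flutter in between.
        alpha = 0.4
        ti = t[inside]
        taper = np.ones_like(ti)
        low = ti < alpha / 2.0
        high = ti > 1.0 - alpha / 2.0
        taper[low] = 0.5 * (1.0 + np.cos(np.pi * (2.0 * ti[low] / alpha - 1.0)))
        taper[high] = 0.5 * (1.0 + np.cos(np.pi * (2.0 * (1.0 - ti[high]) / alpha - 1.0)))
        wave[inside] = (
            spec.flutter_amplitude
            * np.sin(2.0 * np.pi * spec.flutter_cycles * ti)
            * taper
        )
        return wave
    return np.zeros_like(angle)


def generate_repetition(
    spec: CurveSpec,
    repetition_index: int = 1,
    seed: int | np.random.SeedSequence | None = None,
) -> TorqueCurve:
    """Sample one repetition's torque-angle trace.

    Parameters
    ----------
    spec : CurveSpec
        Trial parameters; exactly one morphology (``spec.pattern``) is
        injected, other artifact parameters are ignored.
    repetition_index : int
        1-based repetition number recorded on the trace.
    seed : int, SeedSequence, or None
        Noise stream for this repetition; defaults to ``spec.seed``.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    start, end = spec.rom
    n = int(round((start - end) / spec.angle_step)) + 1
    angle = np.linspace(start, end, n)
    speed = _speed_profile(angle, spec)
    velocity = -speed  # flexion angle decreases while extending

    width = max(start - spec.peak_angle, spec.peak_angle - end)
    base = 1.0 - ((angle - spec.peak_angle) / width) ** 2
    shape = np.clip(base, 0.0, None) + _artifact(angle, spec)
    if spec.noise_sd > 0:
        shape = shape + rng.normal(0.0, spec.noise_sd, size=n)
    torque = spec.peak_torque * np.clip(shape, 0.0, None)
    return TorqueCurve(angle=angle, velocity=velocity, torque=torque,
                       repetition_index=repetition_index)


def generate_trial(spec: CurveSpec) -> list[TorqueCurve]:
    """Generate ``spec.n_repetitions`` repetitions with seed-derived streams.

    The injected pattern is present in every repetition, so in particular
    in the analyzed 2nd-4th repetitions, allowing the three-repetition
    consistency rule to fire.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_repetitions)
    return [
        generate_repetition(spec, repetition_index=i + 1, seed=child)
        for i, child in enumerate(children)
    ]


def generate_cohort(spec: CohortSpec) -> list[CohortTrial]:
    """Generate one trial per count of the cohort's pattern distribution.

    Trial-level biology is jittered realistically: peak torque is drawn
    around 190 N·m for healthy legs and 160 N·m for injured legs (120 N·m
    with an H:Q ratio near 1 for Shaking trials, whose hallmark includes
    globally reduced extensor output), and the peak angle is jittered a
    few degrees around mid-range.  Aggregating the injected labels
    reproduces the requested distribution exactly.
    """
    table = spec.distribution()
    root = np.random.SeedSequence(spec.seed)
    n_trials = int(table.to_numpy().sum())
    children = iter(root.spawn(n_trials))
    trials: list[CohortTrial] = []
    idx = 0
    for cls in CLASS_ORDER:
        for pattern in PATTERN_ORDER:
            for _ in range(int(table.at[pattern, cls])):
                child = next(children)
                rng = np.random.default_rng(child)
                if pattern == "Shaking":
                    peak = rng.normal(120.0, 20.0)
                    hq = rng.normal(1.0, 0.08)
                elif cls == "Healthy":
                    peak = rng.normal(190.0, 25.0)
                    hq = rng.normal(0.65, 0.08)
                else:
                    peak = rng.normal(160.0, 25.0)
                    hq = rng.normal(0.65, 0.08)
                curve_spec = replace(
                    CurveSpec(),
                    pattern=pattern,
                    peak_torque=float(np.clip(peak, 60.0, None)),
                    peak_angle=float(np.clip(rng.normal(50.0, 2.5), 40.0, 60.0)),
                    noise_sd=spec.noise_sd,
                    hq_ratio=float(np.clip(hq, 0.3, None)),
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
                trials.append(
                    CohortTrial(
                        trial_id=f"T{idx:03d}",
                        injury_class=cls,
                        injected_pattern=pattern,
                        spec=curve_spec,
                        repetitions=generate_trial(curve_spec),
                    )
                )
                idx += 1
    return trials


def cohort_manifest(trials: Sequence[CohortTrial]) -> pd.DataFrame:
    """Manifest table: ``trial_id, injury_class, injected_pattern``."""
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "injury_class": [t.injury_class for t in trials],
            "injected_pattern": [t.injected_pattern for t in trials],
        }
    )


def simulate_raters(
    true_labels: Sequence[str],
    spec_a: RaterSimSpec,
    spec_b: RaterSimSpec,
) -> tuple[list[str], list[str]]:
    """Draw two raters' labels independently from their confusion rows."""
    for spec in (spec_a, spec_b):
        if spec.n_items is not None and spec.n_items != len(true_labels):
            raise ValidationError(
                f"n_items={spec.n_items} does not match {len(true_labels)} true labels"
            )
    out: list[list[str]] = []
    for spec in (spec_a, spec_b):
        mat = spec.matrix()
        rng = np.random.default_rng(spec.seed)
        labels = []
        for truth in true_labels:
            validate_pattern(truth)
            probs = mat.loc[truth].to_numpy()
            labels.append(str(rng.choice(list(PATTERN_ORDER), p=probs)))
        out.append(labels)
    return out[0], out[1]
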