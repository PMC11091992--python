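"""Cohen's kappa for paired categorical ratings.

Chance-corrected agreement between two raters assigning the four
moment-curve pattern labels:  kappa = (po - pe) / (1 - pe), where po is
the observed fraction of identical labels and pe the agreement expected
from the two raters' marginal label frequencies.  Values are mapped to
the conventional verbal bands (none-to-slight through almost perfect).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError

#: Verbal agreement bands with inclusive upper bounds on raw kappa.
_BANDS: tuple[tuple[float, str], ...] = (
    (0.0, "no agreement"),
    (0.20, "none to slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    band: str
    n: int


def interpret_kappa(kappa: float) -> str:
    """Map a raw kappa in [-1, 1] to its verbal agreement band.

    Bands use the published cut-points with inclusive upper bounds on
    the raw (unrounded) value: kappa <= 0 is "no agreement", then
    (0, 0.20] none to slight, (0.20, 0.40] fair, (0.40, 0.60] moderate,
    (0.60, 0.80] substantial, (0.80, 1] almost perfect.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValidationError(f"kappa must lie in [-1, 1], got {kappa}")
    for upper, band in _BANDS:
        if kappa <= upper:
            return band
    return _BANDS[-1][1]  # pragma: no cover


def cohen_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> KappaResult:
    """Unweighted Cohen's kappa between two raters' label sequences.

    Raises
    ------
    ValidationError
        On empty input or length mismatch.
    """
    if len(labels_a) != len(labels_b):
        raise ValidationError(
            f"label sequences differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    n = len(labels_a)
    if n == 0:
        raise ValidationError("cannot compute kappa on empty label sequences")

    po = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    categories = set(labels_a) | set(labels_b)
    pe = sum(
        (list(labels_a).count(c) / n) * (list(labels_b).count(c) / n)
        for c in categories
    )
    if pe >= 1.0 - 1e-15:
        # Both raters constant on the same label: perfect agreement.
        kappa = 1.0
        pe = 1.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    kappa = min(1.0, max(-1.0, kappa))
    return KappaResult(
        kappa=kappa,
        observed_agreement=po,
        expected_agreement=pe,
        band=interpret_kappa(kappa),
        n=n,
    )
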