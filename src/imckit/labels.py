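"""Canonical category orderings shared across the package.

The four moment-curve morphologies and five outcome classes are closed
enumerations; every table, model and report in the package uses these
fixed orders so that rows, columns and tie-breaks are reproducible.
"""

from __future__ import annotations

#: Moment-curve pattern labels, reference level first.
PATTERN_ORDER: tuple[str, ...] = ("Normal", "Valley", "Drop", "Shaking")

#: Injury classes; the healthy controls are the model's reference level
#: and deterministic tie-breaks follow this order.
CLASS_ORDER: tuple[str, ...] = ("ACL", "MS", "PFJ", "ACL+MS", "Healthy")

REFERENCE_PATTERN = "Normal"
REFERENCE_CLASS = "Healthy"

#: The irregular (non-reference) patterns, in model-term order.
IRREGULAR_PATTERNS: tuple[str, ...] = ("Valley", "Drop", "Shaking")


def validate_pattern(label: str) -> str:
    if label not in PATTERN_ORDER:
        raise ValueError(f"unknown pattern label {label!r}; expected one of {PATTERN_ORDER}")
    return label


def validate_class(label: str) -> str:
    if label not in CLASS_ORDER:
        raise ValueError(f"unknown injury class {label!r}; expected one of {CLASS_ORDER}")
    return label
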