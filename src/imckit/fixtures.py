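"""Packaged reference data: the pattern-by-injury contingency table.

The package ships the 4 x 5 count table of moment-curve patterns
(Normal, Valley, Drop, Shaking) against knee status for 114 legs:
10 isolated ACL ruptures, 17 grade-III meniscus tears, 24 patellofemoral
joint lesions, 23 combined ACL+meniscus injuries (involved leg each),
and 40 healthy control legs (both legs of 20 uninjured subjects).
Every downstream stage — the association model, the predictor and its
evaluation — is a deterministic function of these counts, so the whole
analysis is reproducible from this fixture alone.
"""

from __future__ import annotations

import pandas as pd

from .labels import CLASS_ORDER, PATTERN_ORDER

# Rows: pattern; columns: ACL, MS, PFJ, ACL+MS, Healthy.
_COUNTS: dict[str, tuple[int, ...]] = {
    "Normal": (2, 4, 4, 3, 35),
    "Valley": (2, 1, 10, 6, 2),
    "Drop": (3, 1, 1, 8, 1),
    "Shaking": (3, 11, 9, 6, 2),
}


def study_counts() -> pd.DataFrame:
    """Return the packaged pattern-by-injury contingency table.

    Returns
    -------
    pandas.DataFrame
        Integer counts, index ``PATTERN_ORDER`` (4 rows), columns
        ``CLASS_ORDER`` (5 columns); grand total 114.
    """
    return pd.DataFrame.from_dict(
        _COUNTS, orient="index", columns=list(CLASS_ORDER)
    ).reindex(list(PATTERN_ORDER)).astype(int)


def study_labels() -> list[tuple[str, str]]:
    """Expand the packaged counts into 114 ``(pattern, injury_class)`` pairs.

    The expansion iterates classes in ``CLASS_ORDER`` and patterns in
    ``PATTERN_ORDER``, so it is deterministic; cross-tabulating the result
    reproduces :func:`study_counts` exactly.
    """
    table = study_counts()
    pairs: list[tuple[str, str]] = []
    for cls in CLASS_ORDER:
        for pattern in PATTERN_ORDER:
            pairs.extend([(pattern, cls)] * int(table.at[pattern, cls]))
    return pairs
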