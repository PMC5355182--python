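"""The coefficient of rareness R_i and its five-class labelling.

For accession *i* with z-scores z_ij over M marker/allele columns,

    R_i = (1/M) * sum_j (z_ij - zbar_j)^2

where zbar_j is the column mean over the *whole* collection (including
accession *i*). Accessions whose allele content deviates most from the
collection-wide average — carriers of rare or private combinations — get
the largest R_i, which is why R_i seeds and tie-breaks the core-selection
greedy loop and drives in situ conservation priorities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .marker_matrix import AccessionMatrix

#: Ordered class labels, most common first.
RARENESS_CLASSES = ("very_common", "common", "average", "rare", "very_rare")

#: Default quantile levels cutting R into the five classes. Chosen so that a
#: collection mirroring the study's shares lands ~77% in the three common
#: classes, ~20% rare and ~3% very rare; fully configurable.
DEFAULT_BREAKS = (0.40, 0.60, 0.77, 0.97)


def rareness_coefficients(
    a: AccessionMatrix, include_self: bool = True
) -> pd.Series:
    """Compute R_i for every accession; returns a Series in input order.

    ``include_self=False`` recomputes each column mean without the focal
    accession (a leave-one-out variant, not the default definition).
    """
    z = a.data.to_numpy(dtype=float)
    n, m = z.shape
    if m == 0:
        raise ValueError("no marker/allele columns")
    if n < 2:
        raise ValueError("rareness needs at least 2 accessions")
    if include_self:
        zbar = z.mean(axis=0)
        r = ((z - zbar) ** 2).mean(axis=1)
    else:
        loo_mean = (z.sum(axis=0) - z) / (n - 1)
        r = ((z - loo_mean) ** 2).mean(axis=1)
    return pd.Series(r, index=a.data.index, name="R")


def classify_rareness(
    r: pd.Series, breaks: tuple[float, float, float, float] = DEFAULT_BREAKS
) -> pd.DataFrame:
    """Assign each accession one of the five rareness classes.

    The four ``breaks`` are quantile levels in (0,1); class boundaries are
    the empirical quantiles of R at those levels. A value tied with a
    boundary goes to the rarer class.

    Returns a DataFrame with columns ``R`` and ``rareness_class`` (ordered
    categorical); the cut points used are stored in ``.attrs["cutpoints"]``.
    """
    breaks = tuple(float(b) for b in breaks)
    if len(breaks) != 4 or any(not 0 < b < 1 for b in breaks):
        raise ValueError("breaks must be four quantile levels in (0, 1)")
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    values = r.to_numpy(dtype=float)
    cutpoints = np.quantile(values, breaks)
    # ties at a boundary fall to the rarer (higher) class
    idx = np.searchsorted(cutpoints, values, side="right")
    labels = pd.Categorical.from_codes(
        idx, categories=list(RARENESS_CLASSES), ordered=True
    )
    out = pd.DataFrame({"R": r, "rareness_class": labels}, index=r.index)
    out.attrs["cutpoints"] = cutpoints
    out.attrs["breaks"] = breaks
    return out
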