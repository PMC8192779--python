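"""Correlation of a target lncRNA with cell-marker genes.

The analysis asks whether a lncRNA of interest co-varies with a small panel
of epithelial/airway cell markers across disease samples.  For each marker
it reports the Pearson r with its t-transform p-value and a descriptive
least-squares line of the marker's expression on the target's.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import StagenetError
from .network import ZeroVarianceError, pearson_test

logger = logging.getLogger(__name__)

#: Default marker panel: basal (KRT5, NGFR), goblet/secretory (MUC5AC,
#: MUC5B, SCGB1A1, SPDEF) airway cell markers.
DEFAULT_MARKERS = ("KRT5", "MUC5AC", "MUC5B", "NGFR", "SCGB1A1", "SPDEF")


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: returns (slope, intercept, r2).

    ``r2`` is the squared Pearson correlation; a constant y gives slope 0
    and r2 = 0, a constant x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("constant x in linear fit")
    res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return float(res.slope), float(res.intercept), r2


def correlate_with_markers(
    em: pd.DataFrame,
    target: str,
    markers=DEFAULT_MARKERS,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Correlate marker genes with a target gene over a sample subset.

    Returns one row per marker found in the matrix (marker, r, p, n, slope,
    intercept, r2_fit).  Markers absent from the matrix or constant over the
    subset are skipped with a warning; a missing target is an error.
    """
    if target not in em.index:
        raise StagenetError(f"target gene {target!r} absent from matrix")
    samples = list(samples) if samples is not None else list(em.columns)
    if len(samples) < 3:
        raise StagenetError("need at least 3 samples")
    x = em.loc[target, samples].to_numpy(dtype=float)
    rows = []
    for marker in markers:
        if marker not in em.index:
            logger.warning("marker %s absent from matrix; skipped", marker)
            continue
        y = em.loc[marker, samples].to_numpy(dtype=float)
        try:
            cr = pearson_test(x, y)
        except ZeroVarianceError:
            logger.warning("marker %s constant over subset; skipped", marker)
            continue
        slope, intercept, r2 = linear_fit(x, y)
        rows.append(
            {"marker": marker, "r": cr.r, "p": cr.p, "n": cr.n,
             "slope": slope, "intercept": intercept, "r2_fit": r2}
        )
    return pd.DataFrame(
        rows, columns=["marker", "r", "p", "n", "slope", "intercept", "r2_fit"]
    )
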