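"""Morphological disparity as Procrustes variance, and its relation to
species richness.

The disparity (diversity index) of a group is its Procrustes variance:
the dispersion of the group's shapes around the group mean shape,
computed in the tangent space of the *global* alignment (groups are not
re-superimposed), with the sample-variance divisor (m - 1).  Groups with
a single member are excluded from tables and correlations.  The
association of disparity with species richness across groups is a
Pearson correlation with a two-sided t-test on n - 2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from beetlemorph.errors import ParameterError

__all__ = [
    "procrustes_variance",
    "disparity_table",
    "richness_correlation",
    "RichnessCorrelation",
]

log = logging.getLogger(__name__)


def procrustes_variance(group_tangent, ddof: int = 1) -> float:
    """Dispersion of a group's tangent rows around their mean.

    V = sum_i ||x_i - mean||^2 / (m - ddof).  ``ddof=1`` (default) is the
    sample-variance convention; ``ddof=0`` is available for cross-software
    comparison.
    """
    X = np.asarray(group_tangent, dtype=float)
    m = len(X)
    if m < 2:
        raise ParameterError(f"Procrustes variance undefined for group of size {m}")
    dev = X - X.mean(axis=0)
    return float((dev**2).sum() / (m - ddof))


def disparity_table(tangent, labels, richness: dict[str, int] | None = None, ddof: int = 1) -> pd.DataFrame:
    """Per-group Procrustes variance paired with species richness.

    ``richness`` maps group -> described species count; when omitted the
    sampled count is used.  Groups of size 1 are skipped with a log
    entry, mirroring the "genera with more than one species" inclusion
    rule.
    """
    X = np.asarray(tangent, dtype=float)
    labels = np.asarray(labels)
    rows = []
    for g in sorted(pd.unique(labels)):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            log.info("group %r has a single sampled member; skipped from disparity table", g)
            continue
        n_species = int(richness[g]) if richness is not None else len(idx)
        rows.append(
            {
                "group": g,
                "n_species": n_species,
                "n_sampled": len(idx),
                "procrustes_variance": procrustes_variance(X[idx], ddof=ddof),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RichnessCorrelation:
    r: float
    p: float
    n_groups: int


def richness_correlation(table: pd.DataFrame, log_richness: bool = False) -> RichnessCorrelation:
    """Pearson correlation of Procrustes variance with species richness.

    Two-sided p from t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees
    of freedom.  ``log_richness`` correlates against log10 counts.
    """
    if len(table) < 3:
        raise ParameterError(f"correlation needs >= 3 groups, got {len(table)}")
    x = table["n_species"].to_numpy(dtype=float)
    if log_richness:
        x = np.log10(x)
    y = table["procrustes_variance"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("zero variance in richness or disparity; correlation undefined")
    res = stats.pearsonr(x, y)
    return RichnessCorrelation(r=float(res.statistic), p=float(res.pvalue), n_groups=len(table))
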