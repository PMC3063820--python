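"""Technical-replicate quality control.

CT triplets are screened with a single-pass, two-sided Grubbs test
(alpha = 0.05 by default); at most one value is ever removed from a
triplet, and triplets with fewer than three values are passed through
untouched.  Surviving detected values are averaged to the mean CT.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ParameterError


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha).

    ``G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2))`` with t the
    upper ``alpha/(2n)`` quantile of Student's t on n-2 degrees of
    freedom.  For n = 3, alpha = 0.05 this is ~1.1543, just below the
    maximum attainable G of (n-1)/sqrt(n) ~ 1.1547.
    """
    if n < 3:
        raise ParameterError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_outlier(values, alpha: float = 0.05) -> int | None:
    """Index of the single Grubbs outlier in ``values``, or ``None``.

    Uses ``G = max|x_i - mean| / sd`` with the n-1 sample standard
    deviation.  Single pass: at most one index is ever reported.
    Fewer than three values or zero variance return ``None``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        warnings.warn("Grubbs test skipped: fewer than 3 values", stacklevel=2)
        return None
    if not np.all(np.isfinite(x)):
        raise ParameterError("Grubbs test requires finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    g = dev.max() / sd
    if g > grubbs_critical_value(x.size, alpha):
        return int(dev.argmax())
    return None


@dataclass
class TripletResult:
    """Aggregated CT for one gene x tissue x run triplet."""

    gene: str
    tissue: str
    bio_rep: int
    ct_mean: float
    n_used: int
    outlier_removed: bool
    detected: bool


def aggregate_triplet(
    values,
    detected=None,
    alpha: float = 0.05,
    gene: str = "",
    tissue: str = "",
    bio_rep: int = 1,
) -> TripletResult:
    """Screen one triplet with Grubbs and average the survivors.

    Not-detected replicates are excluded before testing; the Grubbs
    screen runs only when three or more detected values remain.  A
    triplet that started with two or more values must keep at least two
    detected values to yield a mean, otherwise it is reported as
    not-detected; a single-value group (e.g. a table of already-averaged
    CTs) passes through unchanged.
    """
    x = np.asarray(values, dtype=float)
    det = (
        np.ones(x.shape, dtype=bool)
        if detected is None
        else np.asarray(detected, dtype=bool)
    )
    det = det & np.isfinite(x)
    usable = x[det]
    removed = False
    if usable.size >= 3:
        idx = grubbs_outlier(usable, alpha)
        if idx is not None:
            usable = np.delete(usable, idx)
            removed = True
    min_needed = 2 if x.size >= 2 else 1
    if usable.size < min_needed:
        return TripletResult(gene, tissue, bio_rep, math.nan, int(usable.size), removed, False)
    return TripletResult(gene, tissue, bio_rep, float(usable.mean()), int(usable.size), removed, True)


class GrubbsAggregator(BaseEstimator, TransformerMixin):
    """Outlier-screen and aggregate a replicate-level CT table.

    A stateless transformer: ``transform`` maps the long layout
    (``gene, tissue, bio_rep, tech_rep, ct, detected``) to one row per
    (gene, tissue, bio_rep) with ``ct_mean, n_used, outlier_removed,
    detected``.  ``clean`` returns the long table with flagged outliers
    dropped instead, preserving technical replicates for randomization
    tests downstream.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y=None) -> "GrubbsAggregator":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for (gene, tissue, bio), grp in X.groupby(["gene", "tissue", "bio_rep"], sort=True):
            res = aggregate_triplet(
                grp["ct"].to_numpy(),
                grp["detected"].to_numpy() if "detected" in grp else None,
                alpha=self.alpha,
                gene=str(gene),
                tissue=str(tissue),
                bio_rep=int(bio),
            )
            rows.append(vars(res))
        return pd.DataFrame(rows)

    def clean(self, X: pd.DataFrame) -> pd.DataFrame:
        """Long table with Grubbs-flagged technical replicates removed."""
        keep = []
        for _, grp in X.groupby(["gene", "tissue", "bio_rep"], sort=False):
            det = grp["detected"].to_numpy() if "detected" in grp else np.ones(len(grp), bool)
            det = det & np.isfinite(grp["ct"].to_numpy(dtype=float))
            sub = grp[det]
            if len(sub) >= 3:
                idx = grubbs_outlier(sub["ct"].to_numpy(), self.alpha)
                if idx is not None:
                    sub = sub.drop(sub.index[idx])
            keep.append(sub)
        return pd.concat(keep, ignore_index=True) if keep else X.iloc[0:0]

    @staticmethod
    def to_matrix(aggregated: pd.DataFrame) -> pd.DataFrame:
        """Mean-CT matrix (gene x tissue), averaging biological runs."""
        det = aggregated[aggregated["detected"]]
        return det.pivot_table(index="gene", columns="tissue", values="ct_mean", aggfunc="mean")
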