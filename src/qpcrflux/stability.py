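"""Reference-gene stability screening.

Candidate housekeeping genes are ranked by the standard deviation of
their mean CT across samples, with the per-sample geometric mean of
candidate CTs serving as a composite stability index (the BestKeeper
construction).  Genes correlate with the index via Pearson r; selection
keeps genes with SD below one cycle whose r clears a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import InsufficientDataError, ParameterError


@dataclass
class StabilityReport:
    """Ranked stability table, per-sample index and the selected set."""

    table: pd.DataFrame
    index: pd.Series
    selected: list[str]


def stability_index(ct_matrix: pd.DataFrame, candidates: list[str]) -> pd.Series:
    """Per-sample geometric mean CT over the candidate genes.

    Samples where any candidate is missing are excluded with a warning.
    """
    missing = [g for g in candidates if g not in ct_matrix.index]
    if missing:
        raise ParameterError(f"candidates not in CT matrix: {missing}")
    sub = ct_matrix.loc[candidates]
    ok = sub.notna().all(axis=0)
    if not ok.all():
        dropped = list(sub.columns[~ok])
        warnings.warn(f"samples excluded from stability index (missing CT): {dropped}", stacklevel=2)
    sub = sub.loc[:, ok]
    index = pd.Series(stats.gmean(sub.to_numpy(), axis=0), index=sub.columns, name="index")
    return index


def rank_candidates(
    ct_matrix: pd.DataFrame,
    candidates: list[str] | None = None,
    sd_threshold: float = 1.0,
    r_threshold: float = 0.5,
    top_k: int | None = None,
) -> StabilityReport:
    """Rank candidate reference genes by CT stability.

    Per gene: sample SD and CV (%) of CT across samples, and Pearson r
    against the geometric-mean index.  Genes with any not-detected
    sample are ineligible for selection.  Selection keeps eligible genes
    with ``SD < sd_threshold`` whose r is at least ``r_threshold`` (a
    constant-CT gene has undefined r, reported as NaN and treated as
    stable), capped at ``top_k`` best by SD.
    """
    if candidates is None:
        candidates = list(ct_matrix.index)
    if len(candidates) < 1:
        raise ParameterError("at least one candidate required")
    if ct_matrix.shape[1] < 3:
        raise InsufficientDataError("need >= 3 samples to rank reference genes")

    complete = [g for g in candidates if ct_matrix.loc[g].notna().all()]
    if len(complete) >= 1:
        index = stability_index(ct_matrix, complete)
    else:
        raise InsufficientDataError("no candidate has complete CT data")

    rows = []
    for gene in candidates:
        cts = ct_matrix.loc[gene]
        obs = cts.dropna()
        eligible = len(obs) == len(cts)
        sd = float(obs.std(ddof=1)) if len(obs) >= 2 else np.nan
        cv = float(sd / obs.mean() * 100.0) if len(obs) >= 2 else np.nan
        common = obs.index.intersection(index.index)
        if len(common) >= 3 and obs[common].std() > 0 and index[common].std() > 0:
            r = float(stats.pearsonr(obs[common], index[common])[0])
        else:
            r = np.nan  # constant gene or too few shared samples
        rows.append({"gene": gene, "sd": sd, "cv": cv, "r_index": r, "eligible": eligible})
    table = pd.DataFrame(rows).set_index("gene").sort_values("sd")

    passing = table[
        table["eligible"]
        & (table["sd"] < sd_threshold)
        & (table["r_index"].isna() | (table["r_index"] >= r_threshold))
    ]
    selected = list(passing.index[:top_k]) if top_k is not None else list(passing.index)
    table["selected"] = table.index.isin(selected)
    return StabilityReport(table=table, index=index, selected=selected)


class ReferenceStabilityRanker(BaseEstimator):
    """Select stable reference genes from a mean-CT matrix.

    Attributes (after ``fit``): ``report_`` (full ranked table),
    ``index_`` (per-sample geometric-mean CT), ``selected_`` (gene
    list).
    """

    def __init__(
        self,
        candidates: list[str] | None = None,
        sd_threshold: float = 1.0,
        r_threshold: float = 0.5,
        top_k: int | None = 3,
    ):
        self.candidates = candidates
        self.sd_threshold = sd_threshold
        self.r_threshold = r_threshold
        self.top_k = top_k

    def fit(self, ct_matrix: pd.DataFrame, y=None) -> "ReferenceStabilityRanker":
        report = rank_candidates(
            ct_matrix,
            candidates=self.candidates,
            sd_threshold=self.sd_threshold,
            r_threshold=self.r_threshold,
            top_k=self.top_k,
        )
        self.report_ = report.table
        self.index_ = report.index
        self.selected_ = report.selected
        return self
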