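"""Efficiency-corrected relative expression with resampling inference.

The point estimate is the efficiency-corrected ratio

    ratio = E_t^(CT_t,control - CT_t,sample)
            / gmean_r [ E_r^(CT_r,control - CT_r,sample) ]

for target t normalized to one or more reference genes r.  Significance
comes from a fixed-reallocation randomization test on the log ratio
(replicate CT sets are swapped between sample and control groups,
jointly for target and references so within-replicate pairing is
preserved), and uncertainty from a percentile bootstrap over replicates.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import NormalizationError, ParameterError

_ABS_TOL = 1e-12


def _check_eff(e: float) -> float:
    e = float(e)
    if not (1.0 < e <= 2.0):
        raise ParameterError(f"efficiency must be in (1, 2], got {e}")
    return e


def pfaffl_ratio(
    ct_target_sample,
    ct_target_control,
    ct_refs_sample,
    ct_refs_control,
    e_target: float,
    e_refs,
) -> float:
    """Efficiency-corrected expression ratio (sample vs control).

    CT arguments may be scalars or replicate arrays (means are taken);
    ``ct_refs_*`` and ``e_refs`` are sequences over reference genes.
    """
    e_t = _check_eff(e_target)
    e_r = [_check_eff(e) for e in np.atleast_1d(e_refs)]
    if len(e_r) == 0:
        raise NormalizationError("at least one reference gene is required")
    refs_s = [np.mean(c) for c in ct_refs_sample]
    refs_c = [np.mean(c) for c in ct_refs_control]
    if not (len(refs_s) == len(refs_c) == len(e_r)):
        raise ParameterError("reference CT lists and efficiencies must align")
    dct_t = np.mean(ct_target_control) - np.mean(ct_target_sample)
    log_num = dct_t * math.log(e_t)
    log_den = np.mean(
        [(c - s) * math.log(e) for s, c, e in zip(refs_s, refs_c, e_r)]
    )
    return float(math.exp(log_num - log_den))


def _unit_matrices(ct_target_sample, ct_target_control, ct_refs_sample, ct_refs_control):
    """Stack target + reference CTs into (1+k, n) per-group matrices."""
    s = np.vstack([np.atleast_1d(np.asarray(ct_target_sample, float))]
                  + [np.atleast_1d(np.asarray(c, float)) for c in ct_refs_sample])
    c = np.vstack([np.atleast_1d(np.asarray(ct_target_control, float))]
                  + [np.atleast_1d(np.asarray(c_, float)) for c_ in ct_refs_control])
    return s, c


def _log_ratio(mean_sample, mean_control, log_e_t, log_e_refs):
    """Log ratio from per-row group means; rows are [target, ref1, ...]."""
    dct = mean_control - mean_sample
    return dct[..., 0] * log_e_t - np.mean(dct[..., 1:] * log_e_refs, axis=-1)


def randomization_test(
    ct_target_sample,
    ct_target_control,
    ct_refs_sample,
    ct_refs_control,
    e_target: float,
    e_refs,
    n_iter: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Fixed-reallocation randomization p-value for the log ratio.

    Replicate units (a target CT paired with its reference CTs) are
    pooled and randomly reallocated between the sample and control
    groups ``n_iter`` times; the two-sided p-value is
    ``(b + 1) / (n_iter + 1)`` with b the number of reallocations whose
    absolute log ratio reaches the observed one.  Returns NaN (with a
    warning) when either group has fewer than two replicates.
    """
    log_e_t = math.log(_check_eff(e_target))
    log_e_refs = np.array([math.log(_check_eff(e)) for e in np.atleast_1d(e_refs)])
    S, C = _unit_matrices(ct_target_sample, ct_target_control, ct_refs_sample, ct_refs_control)
    n_s, n_c = S.shape[1], C.shape[1]
    if n_s < 2 or n_c < 2:
        warnings.warn("randomization test skipped: need >= 2 replicates per group", stacklevel=2)
        return float("nan")
    if rng is None:
        rng = np.random.default_rng(seed)

    obs = _log_ratio(S.mean(axis=1), C.mean(axis=1), log_e_t, log_e_refs)
    pooled = np.hstack([S, C])  # (1+k, n)
    n = n_s + n_c
    # random group reassignments as one argsort per iteration
    order = np.argsort(rng.random((n_iter, n)), axis=1)
    take_s = order[:, :n_s]
    take_c = order[:, n_s:]
    mean_s = pooled.T[take_s].mean(axis=1)  # (n_iter, 1+k)
    mean_c = pooled.T[take_c].mean(axis=1)
    null = _log_ratio(mean_s, mean_c, log_e_t, log_e_refs)
    b = int(np.sum(np.abs(null) >= abs(obs) - _ABS_TOL))
    return (b + 1) / (n_iter + 1)


def bootstrap_interval(
    ct_target_sample,
    ct_target_control,
    ct_refs_sample,
    ct_refs_control,
    e_target: float,
    e_refs,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the expression ratio.

    Replicate units are resampled with replacement within each group;
    the interval is widened, if necessary, to contain the point ratio.
    """
    if not (0.0 < level < 1.0):
        raise ParameterError("level must be in (0, 1)")
    log_e_t = math.log(_check_eff(e_target))
    log_e_refs = np.array([math.log(_check_eff(e)) for e in np.atleast_1d(e_refs)])
    S, C = _unit_matrices(ct_target_sample, ct_target_control, ct_refs_sample, ct_refs_control)
    n_s, n_c = S.shape[1], C.shape[1]
    if n_s < 2 or n_c < 2:
        warnings.warn("bootstrap skipped: need >= 2 replicates per group", stacklevel=2)
        return (float("nan"), float("nan"))
    if rng is None:
        rng = np.random.default_rng(seed)
    point = math.exp(_log_ratio(S.mean(axis=1), C.mean(axis=1), log_e_t, log_e_refs))
    idx_s = rng.integers(0, n_s, size=(n_boot, n_s))
    idx_c = rng.integers(0, n_c, size=(n_boot, n_c))
    mean_s = S.T[idx_s].mean(axis=1)
    mean_c = C.T[idx_c].mean(axis=1)
    draws = _log_ratio(mean_s, mean_c, log_e_t, log_e_refs)
    draws = draws[np.isfinite(draws)]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.exp(np.quantile(draws, [alpha, 1.0 - alpha]))
    return (float(min(lo, point)), float(max(hi, point)))


class RelativeExpression(BaseEstimator):
    """Per-gene expression ratios vs a control tissue, with inference.

    Fits on a replicate-level CT table (long layout, outliers already
    removed).  Replicate units pair the target CT with the reference
    CTs measured in the same (bio_rep, tech_rep); units missing any of
    these are dropped.

    Parameters
    ----------
    reference_genes : list of str
        Normalizer genes (their geometric-mean correction divides the
        target ratio).
    control_tissue : str
        Tissue all ratios are computed against.
    efficiencies : mapping gene -> E, optional
        Amplicon efficiencies; genes absent from the mapping default to
        perfect doubling (E = 2).
    n_iter, n_boot, level, seed
        Randomization / bootstrap settings.
    bh_correct : bool, default False
        Apply Benjamini-Hochberg across all tested (gene, tissue) pairs
        into an extra ``p_adj`` column.

    Attributes
    ----------
    ratios_ : DataFrame with columns ``gene, tissue, control, ratio,
        ci_low, ci_high, p_value, n_sample, n_control``.
    """

    def __init__(
        self,
        reference_genes: list[str] | None = None,
        control_tissue: str = "old_leaves",
        efficiencies: dict[str, float] | None = None,
        n_iter: int = 2000,
        n_boot: int = 2000,
        level: float = 0.95,
        seed: int | None = None,
        bh_correct: bool = False,
    ):
        self.reference_genes = reference_genes
        self.control_tissue = control_tissue
        self.efficiencies = efficiencies
        self.n_iter = n_iter
        self.n_boot = n_boot
        self.level = level
        self.seed = seed
        self.bh_correct = bh_correct

    def _eff(self, gene: str) -> float:
        if self.efficiencies and gene in self.efficiencies:
            return float(self.efficiencies[gene])
        return 2.0

    def fit(self, ct_long: pd.DataFrame, y=None) -> "RelativeExpression":
        refs = list(self.reference_genes or [])
        if not refs:
            raise NormalizationError("reference_genes must name at least one gene")
        df = ct_long[ct_long.get("detected", True) & np.isfinite(ct_long["ct"])]
        if self.control_tissue not in set(df["tissue"]):
            raise ParameterError(f"control tissue {self.control_tissue!r} not in table")
        wide = df.pivot_table(
            index=["tissue", "bio_rep", "tech_rep"], columns="gene", values="ct"
        )
        rng = np.random.default_rng(self.seed)
        genes = sorted(g for g in wide.columns if g not in refs)
        tissues = sorted(t for t in wide.index.get_level_values("tissue").unique()
                         if t != self.control_tissue)
        e_refs = [self._eff(r) for r in refs]
        rows = []
        for gene in genes:
            cols = [gene] + refs
            if any(c not in wide.columns for c in cols):
                continue
            ctrl = wide.loc[self.control_tissue, cols].dropna()
            for tissue in tissues:
                if tissue not in wide.index.get_level_values("tissue"):
                    continue
                samp = wide.loc[tissue, cols].dropna()
                if len(samp) == 0 or len(ctrl) == 0:
                    continue
                args = (
                    samp[gene].to_numpy(),
                    ctrl[gene].to_numpy(),
                    [samp[r].to_numpy() for r in refs],
                    [ctrl[r].to_numpy() for r in refs],
                    self._eff(gene),
                    e_refs,
                )
                ratio = pfaffl_ratio(*args)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = randomization_test(*args, n_iter=self.n_iter, rng=rng)
                    lo, hi = bootstrap_interval(
                        *args, n_boot=self.n_boot, level=self.level, rng=rng
                    )
                rows.append(
                    {
                        "gene": gene,
                        "tissue": tissue,
                        "control": self.control_tissue,
                        "ratio": ratio,
                        "ci_low": lo,
                        "ci_high": hi,
                        "p_value": p,
                        "n_sample": len(samp),
                        "n_control": len(ctrl),
                    }
                )
        ratios = pd.DataFrame(rows)
        if self.bh_correct and len(ratios):
            mask = ratios["p_value"].notna()
            adj = np.full(len(ratios), np.nan)
            if mask.any():
                adj[mask.to_numpy()] = stats.false_discovery_control(
                    ratios.loc[mask, "p_value"].to_numpy()
                )
            ratios["p_adj"] = adj
        self.ratios_ = ratios
        return self
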