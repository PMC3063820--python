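"""Amplification-efficiency estimation from fluorescence curves.

Implements the window-of-linearity procedure: after baseline
subtraction, every contiguous stretch of 4-6 cycles with positive
corrected fluorescence is fitted by least squares on the log10 scale,
the window with the highest correlation wins, and the efficiency is
``E = 10^slope``.  Per-amplicon efficiency is the arithmetic mean of
per-reaction estimates passing a correlation filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import InsufficientDataError, ParameterError, QualityError


@dataclass
class AmplificationCurve:
    """One well's fluorescence trace over 1-based cycles."""

    well: str
    gene: str
    tissue: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycles.shape != self.fluorescence.shape:
            raise ParameterError("cycles and fluorescence must have equal length")
        if np.any(np.diff(self.cycles) <= 0):
            raise ParameterError("cycles must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ParameterError("fluorescence must be finite")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AmplificationCurve":
        df = df.sort_values("cycle")
        return cls(
            well=str(df["well"].iloc[0]),
            gene=str(df["gene"].iloc[0]),
            tissue=str(df["tissue"].iloc[0]),
            cycles=df["cycle"].to_numpy(),
            fluorescence=df["fluorescence"].to_numpy(),
        )


@dataclass
class EfficiencyEstimate:
    """Per-amplicon mean efficiency with fit diagnostics."""

    gene: str
    efficiencies: list[float]
    mean_efficiency: float
    window: tuple[int, int]
    correlation: float
    n_points: int
    n_excluded: int = 0


def baseline_correct(
    curve: AmplificationCurve,
    baseline_cycles: tuple[int, int] = (3, 15),
    signal_fraction: float = 0.05,
) -> AmplificationCurve:
    """Subtract the pre-amplification baseline from a trace.

    The baseline is the mean fluorescence over ``baseline_cycles``,
    restricted to cycles still in the flat region — those whose
    fluorescence lies within ``signal_fraction`` of the trace range
    above the trace minimum.  This guards the baseline mean against
    amplicons that leave the flat phase before the window ends.
    Corrected values may be non-positive; log fits exclude them.
    """
    lo, hi = baseline_cycles
    if lo >= hi:
        raise ParameterError("baseline window must satisfy lo < hi")
    in_window = (curve.cycles >= lo) & (curve.cycles <= hi)
    if not np.any(in_window):
        raise ParameterError(
            f"baseline window {baseline_cycles} outside measured cycles "
            f"[{curve.cycles[0]}, {curve.cycles[-1]}]"
        )
    f = curve.fluorescence
    fmin, fmax = f.min(), f.max()
    flat = in_window & (f - fmin <= signal_fraction * (fmax - fmin)) if fmax > fmin else in_window
    if not np.any(flat):
        flat = in_window
    baseline = f[flat].mean()
    return AmplificationCurve(
        well=curve.well,
        gene=curve.gene,
        tissue=curve.tissue,
        cycles=curve.cycles.copy(),
        fluorescence=f - baseline,
    )


def _weighted_slope(x: np.ndarray, f: np.ndarray) -> float:
    """Slope of log10(f) vs x by inverse-variance weighted least squares.

    Additive fluorescence noise has SD proportional to 1/f on the log
    scale, so weights proportional to f^2 restore efficiency of the fit.
    On noise-free exponential data the weighted and ordinary slopes
    coincide exactly.
    """
    y = np.log10(f)
    w = f * f
    w = w / w.sum()
    xb = (w * x).sum()
    yb = (w * y).sum()
    return float(((w * (x - xb) * (y - yb)).sum()) / ((w * (x - xb) ** 2).sum()))


def window_of_linearity(
    curve: AmplificationCurve,
    min_points: int = 4,
    max_points: int = 6,
    noise_floor_mult: float = 10.0,
    plateau_fraction: float = 0.9,
) -> tuple[tuple[int, int], float, float]:
    """Find the best log-linear window of a baseline-corrected curve.

    Candidate points must lie inside the window of linearity: corrected
    fluorescence positive, above ``noise_floor_mult`` times the noise SD
    estimated from the flat region, and below ``plateau_fraction`` of
    the trace maximum (saturated cycles carry no exponential signal).
    All contiguous windows of ``min_points`` to ``max_points`` such
    cycles are fitted by least squares on the log10 scale; the window
    with the highest correlation wins (ties prefer longer windows, then
    earlier starts).  Returns ``((first_cycle, last_cycle), slope, r)``
    with the slope from the inverse-variance weighted fit of the winning
    window.
    """
    f = curve.fluorescence
    cycles = curve.cycles
    fmin, fmax = f.min(), f.max()
    if fmax > fmin:
        # instrument noise from the quietest available estimate: the
        # flat region can contain deterministic growth, the first cycles
        # can contain early amplification, so take the smaller SD
        flat = f - fmin <= 0.05 * (fmax - fmin)
        candidates = [f[flat]] if flat.sum() >= 3 else []
        if len(f) >= 8:
            candidates.append(f[:8])
        noise_sd = min((c.std(ddof=1) for c in candidates), default=0.0)
    else:
        noise_sd = 0.0
    eligible = (f > 0) & (f > noise_floor_mult * noise_sd) & (f < plateau_fraction * fmax)
    if eligible.sum() < min_points:
        raise InsufficientDataError(
            f"only {int(eligible.sum())} usable points above the noise floor; "
            f"need >= {min_points}"
        )

    best: tuple[float, int, int] | None = None  # (r, n, -start)
    n_total = len(cycles)
    for n in range(min_points, max_points + 1):
        for start in range(0, n_total - n + 1):
            sl = slice(start, start + n)
            if not np.all(eligible[sl]):
                continue
            x = cycles[sl].astype(float)
            y = np.log10(f[sl])
            if np.ptp(y) == 0:  # flat segment: no defined correlation
                continue
            _, _, r, _, _ = stats.linregress(x, y)
            key = (r, n, -start)
            if best is None or key > best:
                best = key
    if best is None:
        raise InsufficientDataError("no contiguous usable window of sufficient length")
    r, n, neg_start = best
    start = -neg_start
    sl = slice(start, start + n)
    slope = _weighted_slope(cycles[sl].astype(float), f[sl])
    window = (int(cycles[start]), int(cycles[start + n - 1]))
    return window, slope, float(r)


def efficiency_from_slope(slope: float) -> float:
    """Efficiency E (fold/cycle) from a base-10 log-linear slope."""
    if not np.isfinite(slope):
        raise ParameterError("slope must be finite")
    return float(10.0 ** slope)


def estimate_reaction(
    curve: AmplificationCurve,
    baseline_cycles: tuple[int, int] = (3, 15),
    min_points: int = 4,
    max_points: int = 6,
) -> dict:
    """Baseline-correct one trace and estimate its efficiency."""
    corrected = baseline_correct(curve, baseline_cycles)
    window, slope, r = window_of_linearity(corrected, min_points, max_points)
    return {
        "well": curve.well,
        "gene": curve.gene,
        "efficiency": efficiency_from_slope(slope),
        "slope": slope,
        "r": r,
        "window_start": window[0],
        "window_end": window[1],
        "n_points": window[1] - window[0] + 1,
    }


def mean_amplicon_efficiency(
    reactions: pd.DataFrame,
    gene: str | None = None,
    min_r: float = 0.998,
) -> EfficiencyEstimate:
    """Average per-reaction efficiencies that pass the correlation filter.

    ``reactions`` is the frame produced by per-reaction estimation
    (columns ``gene, efficiency, r, window_start, window_end``).
    """
    if gene is not None:
        reactions = reactions[reactions["gene"] == gene]
    if len(reactions) == 0:
        raise InsufficientDataError("no reactions for amplicon")
    gene_label = str(reactions["gene"].iloc[0])
    accepted = reactions[reactions["r"] >= min_r]
    n_excluded = len(reactions) - len(accepted)
    if len(accepted) == 0:
        raise QualityError(
            f"all {len(reactions)} reactions for {gene_label!r} fall below r >= {min_r}"
        )
    best = accepted.loc[accepted["r"].idxmax()]
    return EfficiencyEstimate(
        gene=gene_label,
        efficiencies=[float(e) for e in accepted["efficiency"]],
        mean_efficiency=float(accepted["efficiency"].mean()),
        window=(int(best["window_start"]), int(best["window_end"])),
        correlation=float(accepted["r"].mean()),
        n_points=int(best["window_end"] - best["window_start"] + 1),
        n_excluded=n_excluded,
    )


class EfficiencyEstimator(BaseEstimator):
    """Per-amplicon efficiency from a plate of amplification curves.

    Parameters
    ----------
    baseline_cycles : (int, int), default (3, 15)
        Cycle window used to estimate the flat baseline.
    min_points, max_points : int
        Window-of-linearity lengths to scan (4-6 cycles).
    min_r : float, default 0.998
        Per-reaction acceptance threshold on the log-linear fit
        correlation.

    Attributes
    ----------
    reactions_ : DataFrame
        One row per well: efficiency, slope, r, fit window.
    efficiencies_ : DataFrame
        One row per gene: ``mean_efficiency, n_reactions, n_excluded,
        mean_r``.
    """

    def __init__(
        self,
        baseline_cycles: tuple[int, int] = (3, 15),
        min_points: int = 4,
        max_points: int = 6,
        min_r: float = 0.998,
    ):
        self.baseline_cycles = baseline_cycles
        self.min_points = min_points
        self.max_points = max_points
        self.min_r = min_r

    def fit(self, curves: pd.DataFrame, y=None) -> "EfficiencyEstimator":
        """Fit on a tidy curve table (``well, gene, tissue, cycle, fluorescence``)."""
        required = {"well", "gene", "tissue", "cycle", "fluorescence"}
        if not required.issubset(curves.columns):
            raise ParameterError(f"curve table must have columns {sorted(required)}")
        rows = []
        for _, grp in curves.groupby("well", sort=True):
            curve = AmplificationCurve.from_frame(grp)
            rows.append(
                estimate_reaction(
                    curve, self.baseline_cycles, self.min_points, self.max_points
                )
            )
        self.reactions_ = pd.DataFrame(rows)
        summaries = []
        for gene, grp in self.reactions_.groupby("gene", sort=True):
            est = mean_amplicon_efficiency(grp, min_r=self.min_r)
            summaries.append(
                {
                    "gene": gene,
                    "mean_efficiency": est.mean_efficiency,
                    "n_reactions": len(est.efficiencies),
                    "n_excluded": est.n_excluded,
                    "mean_r": est.correlation,
                }
            )
        self.efficiencies_ = pd.DataFrame(summaries).set_index("gene")
        return self

    def efficiency_dict(self) -> dict[str, float]:
        """Per-gene mean efficiency as a plain mapping."""
        return self.efficiencies_["mean_efficiency"].to_dict()
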