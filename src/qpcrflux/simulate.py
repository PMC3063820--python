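"""Synthetic qPCR data with known ground truth.

Two generators drive the test surface of the whole pipeline:

* :func:`simulate_curve` produces per-well fluorescence traces with an
  exact exponential phase (fold-increase *E* per cycle) clamped at a
  saturating plateau, plus additive Gaussian instrument noise.  The
  true efficiency is carried alongside the trace, so efficiency
  estimators can be checked against ground truth.

* :func:`simulate_ct_table` produces replicate-level CT tables for a
  designed expression experiment: per-gene baseline CTs in a control
  tissue, fold-changes mapped into CT shifts through the amplicon
  efficiency (``CT = CT_control - log_E(fold)``), technical triplicates
  with Gaussian scatter, occasional single-replicate outliers (displaced
  +5 to +10 cycles, large enough for a Grubbs test at n = 3), independent
  biological runs, and non-detects above a CT ceiling.

Defaults emulate the study conditions downstream stages were written
for: 6 tissues, triplicates, two biological runs, amplicon efficiencies
in 1.82-1.93 and CTs roughly in 19-40.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError


@dataclass
class CurveParams:
    """Ground-truth parameters of one simulated amplification curve.

    ``true_efficiency`` is the per-cycle fold increase E in (1, 2];
    fluorescence units are arbitrary.
    """

    true_efficiency: float = 1.88
    initial_amount: float = 1e-5
    baseline: float = 100.0
    plateau: float = 10100.0
    noise_sd: float = 0.0
    n_cycles: int = 40
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (1.0 < self.true_efficiency <= 2.0):
            raise ParameterError(f"true_efficiency must be in (1, 2], got {self.true_efficiency}")
        if self.initial_amount <= 0:
            raise ParameterError("initial_amount must be > 0")
        if self.plateau <= self.baseline:
            raise ParameterError("plateau must exceed baseline")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_cycles < 10:
            raise ParameterError("n_cycles must be >= 10")


def simulate_curve(
    params: CurveParams,
    well: str = "w1",
    gene: str = "gene",
    tissue: str = "tissue",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one amplification trace.

    The noise-free signal is ``baseline + min(A*E^c, span)`` with
    ``span = plateau - baseline``: exactly exponential below the
    plateau, clamped at it above.  The exact pre-plateau log-linearity
    is what downstream efficiency estimation is validated against.
    Deterministic under a fixed ``params.seed`` (ignored when an
    explicit ``rng`` is given).

    Returns a tidy frame with columns ``well, gene, tissue, cycle,
    fluorescence`` (cycles 1-based).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    cycles = np.arange(1, params.n_cycles + 1)
    span = params.plateau - params.baseline
    expo = params.initial_amount * params.true_efficiency ** cycles.astype(float)
    signal = params.baseline + np.minimum(expo, span)
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=signal.shape)
    return pd.DataFrame(
        {
            "well": well,
            "gene": gene,
            "tissue": tissue,
            "cycle": cycles,
            "fluorescence": signal,
        }
    )


def simulate_reactions(
    params: CurveParams,
    n_reactions: int,
    gene: str = "gene",
    tissue: str = "tissue",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate ``n_reactions`` replicate wells of the same amplicon."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    frames = [
        simulate_curve(params, well=f"{gene}_{i + 1}", gene=gene, tissue=tissue, rng=rng)
        for i in range(n_reactions)
    ]
    return pd.concat(frames, ignore_index=True)


@dataclass
class DesignSpec:
    """Design of a simulated expression experiment.

    ``true_fold_changes[gene][tissue]`` is expression relative to
    ``control_tissue`` (reference genes must be 1 everywhere; the control
    tissue itself is implicitly 1).  ``outlier_rate`` is the probability
    that a technical triplet contains exactly one displaced CT.
    """

    genes: list[str]
    tissues: list[str]
    control_tissue: str
    true_fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    reference_genes: list[str] = field(default_factory=list)
    base_ct: dict[str, float] | None = None
    n_technical: int = 3
    n_biological: int = 2
    noise_sd: float = 0.15
    outlier_rate: float = 0.05
    nondetect_ct: float = 40.0

    def __post_init__(self) -> None:
        if self.n_technical < 2:
            raise ParameterError("n_technical must be >= 2")
        if self.n_biological < 1:
            raise ParameterError("n_biological must be >= 1")
        if self.control_tissue not in self.tissues:
            raise ParameterError(f"control tissue {self.control_tissue!r} not among tissues")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ParameterError("outlier_rate must be a probability")
        for ref in self.reference_genes:
            if ref not in self.genes:
                raise ParameterError(f"reference gene {ref!r} not among genes")
            for tissue, fc in self.true_fold_changes.get(ref, {}).items():
                if fc != 1.0:
                    raise ParameterError(
                        f"reference gene {ref!r} must have fold-change 1 in all "
                        f"tissues (got {fc} in {tissue!r})"
                    )

    def fold_change(self, gene: str, tissue: str) -> float:
        if tissue == self.control_tissue or gene in self.reference_genes:
            return 1.0
        return float(self.true_fold_changes.get(gene, {}).get(tissue, 1.0))


def simulate_ct_table(
    design: DesignSpec,
    efficiencies: dict[str, float],
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a replicate-level CT table for a design.

    The noise-free CT obeys ``CT(g, t) = CT(g, control) - log_E(fold)``
    so that a fold-change f at amplicon efficiency E shifts the CT by
    ``-log(f)/log(E)`` cycles.  Returns the long layout
    ``gene, tissue, bio_rep, tech_rep, ct, detected``; CTs beyond
    ``design.nondetect_ct`` are flagged not-detected with missing CT.
    """
    missing = [g for g in design.genes if g not in efficiencies]
    if missing:
        raise ConfigError(f"no efficiency provided for genes: {missing}")
    rng = np.random.default_rng(seed)
    base = dict(design.base_ct) if design.base_ct else {}
    for gene in design.genes:
        if gene not in base:
            base[gene] = float(rng.uniform(20.0, 30.0))

    rows = []
    for bio in range(1, design.n_biological + 1):
        for gene in design.genes:
            eff = float(efficiencies[gene])
            if not (1.0 < eff <= 2.0):
                raise ConfigError(f"efficiency for {gene!r} must be in (1, 2], got {eff}")
            for tissue in design.tissues:
                fold = design.fold_change(gene, tissue)
                if fold <= 0:
                    raise ParameterError("fold-changes must be positive")
                true_ct = base[gene] - math.log(fold) / math.log(eff)
                cts = true_ct + rng.normal(0.0, design.noise_sd, size=design.n_technical)
                if rng.uniform() < design.outlier_rate:
                    cts[rng.integers(design.n_technical)] += rng.uniform(5.0, 10.0)
                for tech, ct in enumerate(cts, start=1):
                    detected = ct <= design.nondetect_ct
                    rows.append(
                        {
                            "gene": gene,
                            "tissue": tissue,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "ct": float(ct) if detected else np.nan,
                            "detected": bool(detected),
                        }
                    )
    return pd.DataFrame(rows)


def null_design(
    n_genes: int = 200,
    tissues: tuple[str, str] = ("treated", "control"),
    n_technical: int = 3,
    n_biological: int = 1,
    noise_sd: float = 0.15,
) -> DesignSpec:
    """A no-effect design (all fold-changes 1) for calibration studies."""
    genes = [f"g{i:03d}" for i in range(n_genes)] + ["ref1", "ref2"]
    return DesignSpec(
        genes=genes,
        tissues=list(tissues),
        control_tissue=tissues[1],
        reference_genes=["ref1", "ref2"],
        n_technical=n_technical,
        n_biological=n_biological,
        noise_sd=noise_sd,
        outlier_rate=0.0,
    )
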