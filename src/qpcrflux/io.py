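"""CSV I/O, label normalization, and the end-to-end pipeline driver.

All tables travel as plain CSV in documented dialects:

* curves:    ``well,gene,tissue,cycle,fluorescence`` (cycle 1-based)
* CT tables: ``gene,tissue,bio_rep,tech_rep,ct,detected`` — ``n.d.`` or
  an empty CT cell means not-detected
* efficiencies: ``gene,mean_efficiency,n_reactions,n_excluded,mean_r``
* kinetics:  ``enzyme,substrate,km_uM,kcat_per_s,stoichiometry``

Tissue labels are normalized case-insensitively into a snake_case
controlled vocabulary (``Flower buds`` -> ``flower_buds``).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import load_kinetics
from .ddct import DeltaDeltaCt, turnover_table
from .errors import ConfigError, TableFormatError
from .expression import RelativeExpression
from .qc import GrubbsAggregator
from .stability import ReferenceStabilityRanker

CT_COLUMNS = ["gene", "tissue", "bio_rep", "tech_rep", "ct", "detected"]
CURVE_COLUMNS = ["well", "gene", "tissue", "cycle", "fluorescence"]
_ND_TOKENS = {"n.d.", "nd", "n.d", "na", ""}


def normalize_tissue(label: str) -> str:
    """Canonical snake_case tissue label."""
    return str(label).strip().lower().replace(" ", "_").replace("-", "_")


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    """Read a replicate-level CT table, validating strictly.

    ``n.d.`` and empty CT cells map to not-detected; duplicate
    (gene, tissue, bio_rep, tech_rep) rows and malformed values raise
    :class:`TableFormatError` with 1-based line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CT_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise TableFormatError(f"{path}: no data rows")

    def _line(i: int) -> int:
        return int(i) + 2  # header is line 1

    cts, detected = [], []
    for i, raw in df["ct"].items():
        token = raw.strip().lower()
        if token in _ND_TOKENS:
            cts.append(np.nan)
            detected.append(False)
            continue
        try:
            val = float(raw)
        except ValueError:
            raise TableFormatError(f"{path}, line {_line(i)}: unparseable ct value {raw!r}")
        if val <= 0:
            raise TableFormatError(f"{path}, line {_line(i)}: ct must be positive, got {val}")
        cts.append(val)
        detected.append(True)
    out = pd.DataFrame(
        {
            "gene": df["gene"].str.strip(),
            "tissue": df["tissue"].map(normalize_tissue),
            "bio_rep": pd.to_numeric(df["bio_rep"], errors="coerce"),
            "tech_rep": pd.to_numeric(df["tech_rep"], errors="coerce"),
            "ct": cts,
            "detected": detected,
        }
    )
    if "detected" in df.columns:
        explicit = df["detected"].str.strip().str.lower()
        out["detected"] = out["detected"] & ~explicit.isin({"false", "0", "no"})
    bad = out.index[out["bio_rep"].isna() | out["tech_rep"].isna()]
    if len(bad):
        raise TableFormatError(f"{path}, line {_line(bad[0])}: non-integer replicate index")
    out["bio_rep"] = out["bio_rep"].astype(int)
    out["tech_rep"] = out["tech_rep"].astype(int)
    dup = out.duplicated(subset=["gene", "tissue", "bio_rep", "tech_rep"])
    if dup.any():
        raise TableFormatError(
            f"{path}, line {_line(out.index[dup][0])}: duplicate (gene, tissue, bio_rep, tech_rep) row"
        )
    return out


def write_ct_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CT table; not-detected rows print ``n.d.``."""
    out = df.copy()
    out["ct"] = [
        "n.d." if not d or not np.isfinite(c) else repr(float(c))
        for c, d in zip(out["ct"], out["detected"])
    ]
    out[CT_COLUMNS].to_csv(path, index=False)


def read_curves_csv(path: str | Path) -> pd.DataFrame:
    """Read an amplification-curve table (documented export dialect)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise TableFormatError(f"{path}: no data rows")
    df["tissue"] = df["tissue"].map(normalize_tissue)
    return df


def read_efficiency_csv(path: str | Path) -> dict[str, float]:
    """Read per-amplicon efficiencies into a gene -> E mapping."""
    df = pd.read_csv(path)
    for col in ("gene",):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    value_col = next(
        (c for c in ("mean_efficiency", "efficiency") if c in df.columns), None
    )
    if value_col is None:
        raise TableFormatError(f"{path}: missing an efficiency column")
    return dict(zip(df["gene"], df[value_col].astype(float)))


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible end-to-end run."""

    ct_path: str
    output_dir: str
    efficiency_path: str | None = None
    kinetics_path: str | None = None
    reference_genes: list[str] = field(default_factory=lambda: ["CPR", "beta-actin", "PAL"])
    control_tissue: str = "old_leaves"
    turnover_calibrator: tuple[str, str] = ("RED1", "flower_buds")
    amounts_calibrator: tuple[str, str] = ("GAS", "stems")
    turnover_reference: str = "beta-actin"
    turnover_tissue: str = "flower_buds"
    grubbs_alpha: float = 0.05
    n_iter: int = 2000
    n_boot: int = 2000
    seed: int = 0
    rounding: str = "none"
    stability_top_k: int = 3
    make_figure: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.turnover_calibrator = tuple(cfg.turnover_calibrator)
        cfg.amounts_calibrator = tuple(cfg.amounts_calibrator)
        return cfg


def _expression_figure(ratios: pd.DataFrame, path: Path) -> None:
    """Log-scale per-tissue summary of expression ratios."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tissues = sorted(ratios["tissue"].unique())
    fig, axes = plt.subplots(
        1, max(len(tissues), 1), figsize=(4 * max(len(tissues), 1), 4), squeeze=False
    )
    for ax, tissue in zip(axes[0], tissues):
        sub = ratios[ratios["tissue"] == tissue].sort_values("gene")
        x = np.arange(len(sub))
        ratio = sub["ratio"].to_numpy(dtype=float)
        ax.bar(x, ratio, color="#4878a8")
        err_lo = np.maximum(ratio - sub["ci_low"].to_numpy(dtype=float), 0)
        err_hi = np.maximum(sub["ci_high"].to_numpy(dtype=float) - ratio, 0)
        if np.isfinite(err_lo).all() and np.isfinite(err_hi).all():
            ax.errorbar(x, ratio, yerr=[err_lo, err_hi], fmt="none", ecolor="k", lw=1)
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_yscale("log")
        ax.set_xticks(x, sub["gene"], rotation=90, fontsize=7)
        ax.set_title(tissue)
        ax.set_ylabel("expression ratio vs control")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run QC -> stability -> expression -> ddCT/turnover, writing CSVs.

    Returns the result bundle as a dict of DataFrames; every output and
    a JSON manifest (parameters, seed, versions) land in
    ``config.output_dir``.  Stages that need replicate-level data are
    skipped (with a manifest note) when only single pseudo-replicates
    are available.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    notes: list[str] = []

    ct_long = read_ct_csv(config.ct_path)
    efficiencies = (
        read_efficiency_csv(config.efficiency_path) if config.efficiency_path else {}
    )
    kinetics = (
        pd.read_csv(config.kinetics_path) if config.kinetics_path else load_kinetics()
    )

    qc = GrubbsAggregator(alpha=config.grubbs_alpha)
    aggregated = qc.transform(ct_long)
    cleaned = qc.clean(ct_long)
    matrix = qc.to_matrix(aggregated)
    bundle["ct_clean"] = aggregated
    aggregated.to_csv(outdir / "ct_clean.csv", index=False)

    if matrix.shape[1] >= 3:
        ranker = ReferenceStabilityRanker(top_k=config.stability_top_k).fit(matrix)
        bundle["stability"] = ranker.report_
        ranker.report_.to_csv(outdir / "stability.csv")
    else:
        notes.append("stability stage skipped: fewer than 3 samples")

    n_units = cleaned.groupby(["gene", "tissue"]).size()
    if (n_units >= 2).any():
        expr = RelativeExpression(
            reference_genes=config.reference_genes,
            control_tissue=config.control_tissue,
            efficiencies=efficiencies,
            n_iter=config.n_iter,
            n_boot=config.n_boot,
            seed=config.seed,
        ).fit(cleaned)
        bundle["ratios"] = expr.ratios_
        expr.ratios_.to_csv(outdir / "ratios.csv", index=False)
        if config.make_figure and len(expr.ratios_):
            _expression_figure(expr.ratios_, outdir / "expression_ratios.svg")
    else:
        notes.append("expression stage skipped: no replicate-level data")

    def _cell_available(gene: str, tissue: str) -> bool:
        return gene in matrix.index and tissue in matrix.columns

    if config.turnover_reference in matrix.index and _cell_available(*config.amounts_calibrator):
        amounts = DeltaDeltaCt(
            reference_gene=config.turnover_reference,
            calibrator=config.amounts_calibrator,
            rounding=config.rounding,
        ).transform(matrix)
        bundle["amounts"] = amounts
        amounts.to_csv(outdir / "amounts.csv")
    else:
        notes.append("amounts stage skipped: calibrator or reference not in CT table")

    if config.turnover_reference in matrix.index and _cell_available(*config.turnover_calibrator):
        turnover = turnover_table(
            matrix,
            kinetics,
            tissue=config.turnover_tissue,
            reference_gene=config.turnover_reference,
            calibrator=config.turnover_calibrator,
            rounding=config.rounding,
        )
        bundle["turnover"] = turnover
        turnover.to_csv(outdir / "turnover.csv", index=False)
    else:
        notes.append("turnover stage skipped: calibrator or reference not in CT table")

    manifest = {
        "qpcrflux_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(config),
        "notes": notes,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    bundle["manifest"] = manifest
    return bundle
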