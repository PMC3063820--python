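"""2^-ddCT transcript amounts and enzyme turnover-potential scores.

The Livak ddCT method with the amplification factor fixed at 2:
a target (gene, tissue) is normalized to a reference gene measured in
the same tissue, then calibrated against a chosen (gene, tissue) cell
whose amount is 1 by construction.  Normalized amounts combine with
catalytic constants into a relative turnover potential
``amount x kcat x substrate_stoichiometry`` — a ranking of how much of
a shared precursor pool each enzyme could consume, assuming active
sites proportional to transcript level and substrate saturation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ParameterError

#: CT-table row used for each kinetics enzyme when the labels differ
#: (the FDS primer amplifies both FDS isoforms; DBR2 kinetics pair with
#: the DBR2-specific amplicon).
DEFAULT_GENE_MAP = {"FDS1": "FDS1/FDS2", "DBR2": "DBR2#"}

#: Kinetics rows whose printed source values are known not to be
#: reproducible from the packaged CT matrix (see docs/methods.md).
KNOWN_DISCREPANCIES = {"DBR2"}


@dataclass
class KineticConstants:
    """Michaelis-Menten constants for one enzyme/substrate pair."""

    enzyme: str
    substrate: str
    km_uM: float | None
    kcat_per_s: float | None
    substrate_stoichiometry: int = 1
    assumed: bool = False

    def __post_init__(self) -> None:
        if self.kcat_per_s is not None and self.kcat_per_s < 0:
            raise ParameterError("kcat must be >= 0")
        if self.km_uM is not None and self.km_uM <= 0:
            raise ParameterError("Km must be > 0")
        if self.substrate_stoichiometry not in (1, 2):
            raise ParameterError("substrate stoichiometry must be 1 or 2")


@dataclass
class TurnoverEstimate:
    """ddCT, normalized amount and turnover score for one enzyme/tissue."""

    enzyme: str
    substrate: str
    tissue: str
    ddct: float
    normalized_amount: float
    kcat_per_s: float | None
    substrate_stoichiometry: int
    relative_turnover: float
    flag: str = ""


def _round_amount(amount: float) -> float:
    """Reporting precision for normalized amounts: nearest integer
    (values below 1 keep two significant digits)."""
    if not np.isfinite(amount):
        return amount
    if amount >= 1.0:
        return float(round(amount))
    return float(f"{amount:.2g}")


def _round_turnover(value: float) -> float:
    """Reporting precision for turnover: integer when >= 10, one
    decimal below."""
    if not np.isfinite(value):
        return value
    return float(round(value)) if value >= 10 else float(round(value, 1))


def delta_delta_ct(
    ct_matrix: pd.DataFrame,
    target: tuple[str, str],
    reference_gene: str,
    calibrator: tuple[str, str],
) -> tuple[float, float]:
    """ddCT and 2^-ddCT amount for one target cell.

    ``dCT_target = CT(target gene, target tissue) - CT(reference, target
    tissue)``; likewise for the calibrator in its own tissue; the
    amplification factor is fixed at 2 (not the measured efficiencies).
    Any missing input CT yields ``(nan, nan)``.
    """
    tg, tt = target
    cg, ct_tissue = calibrator
    for g in (tg, cg, reference_gene):
        if g not in ct_matrix.index:
            raise ParameterError(f"gene {g!r} not in CT matrix")
    for t in (tt, ct_tissue):
        if t not in ct_matrix.columns:
            raise ParameterError(f"tissue {t!r} not in CT matrix")
    vals = (
        ct_matrix.loc[tg, tt],
        ct_matrix.loc[reference_gene, tt],
        ct_matrix.loc[cg, ct_tissue],
        ct_matrix.loc[reference_gene, ct_tissue],
    )
    if not all(np.isfinite(v) for v in vals):
        return (float("nan"), float("nan"))
    dct_target = vals[0] - vals[1]
    dct_cal = vals[2] - vals[3]
    ddct = float(dct_target - dct_cal)
    return ddct, float(2.0 ** (-ddct))


def amount_matrix(
    ct_matrix: pd.DataFrame,
    genes: list[str] | None = None,
    tissues: list[str] | None = None,
    reference_gene: str = "beta-actin",
    calibrator: tuple[str, str] = ("GAS", "stems"),
    rounding: str = "none",
) -> pd.DataFrame:
    """Normalized 2^-ddCT amounts for a block of genes x tissues.

    The reference gene is taken per tissue; the calibrator cell equals 1
    by construction.  ``rounding="paper"`` applies reporting precision
    (integer amounts); missing inputs propagate as NaN.
    """
    if rounding not in ("none", "paper"):
        raise ParameterError("rounding must be 'none' or 'paper'")
    genes = list(genes) if genes is not None else [g for g in ct_matrix.index if g != reference_gene]
    tissues = list(tissues) if tissues is not None else list(ct_matrix.columns)
    out = pd.DataFrame(index=pd.Index(genes, name="gene"),
                       columns=pd.Index(tissues, name="tissue"), dtype=float)
    for g in genes:
        for t in tissues:
            _, amount = delta_delta_ct(ct_matrix, (g, t), reference_gene, calibrator)
            out.loc[g, t] = _round_amount(amount) if rounding == "paper" else amount
    return out


def turnover_potential(
    amount: float,
    constants: KineticConstants,
    rounding: str = "none",
) -> float:
    """Relative turnover = amount x kcat x substrate stoichiometry.

    In ``rounding="paper"`` mode the amount is integer-rounded before
    multiplication and the product is reported at table precision.
    Raises when no kcat is available for the enzyme.
    """
    if constants.kcat_per_s is None or not np.isfinite(constants.kcat_per_s):
        raise ParameterError(f"no kcat available for {constants.enzyme!r}")
    if rounding == "paper":
        amount = _round_amount(amount)
    value = amount * constants.kcat_per_s * constants.substrate_stoichiometry
    return _round_turnover(value) if rounding == "paper" else float(value)


def turnover_table(
    ct_matrix: pd.DataFrame,
    kinetics: pd.DataFrame,
    tissue: str,
    reference_gene: str = "beta-actin",
    calibrator: tuple[str, str] | None = None,
    gene_map: dict[str, str] | None = None,
    rounding: str = "none",
) -> pd.DataFrame:
    """Turnover-potential scores for every kinetics row in one tissue.

    ``kinetics`` columns: ``enzyme, substrate, km_uM, kcat_per_s,
    stoichiometry`` (optional ``assumed``).  Enzymes lacking a kcat are
    kept with a ``no_kcat`` flag and missing score; enzymes absent from
    the CT matrix are flagged ``no_ct``.  Rows listed in
    :data:`KNOWN_DISCREPANCIES` carry a ``known_discrepancy`` flag.
    """
    gene_map = DEFAULT_GENE_MAP if gene_map is None else gene_map
    if calibrator is None:
        calibrator = ("RED1", tissue)
    rows = []
    for _, k in kinetics.iterrows():
        enzyme = str(k["enzyme"])
        gene = gene_map.get(enzyme, enzyme)
        kcat = k["kcat_per_s"]
        kcat = None if pd.isna(kcat) else float(kcat)
        const = KineticConstants(
            enzyme=enzyme,
            substrate=str(k["substrate"]),
            km_uM=None if pd.isna(k.get("km_uM")) else float(k["km_uM"]),
            kcat_per_s=kcat,
            substrate_stoichiometry=int(k.get("stoichiometry", 1)),
            assumed=bool(k.get("assumed", False)),
        )
        flags = []
        if enzyme in KNOWN_DISCREPANCIES:
            flags.append("known_discrepancy")
        if gene not in ct_matrix.index:
            flags.append("no_ct")
            ddct, amount = float("nan"), float("nan")
        else:
            ddct, amount = delta_delta_ct(ct_matrix, (gene, tissue), reference_gene, calibrator)
            if not np.isfinite(amount):
                flags.append("not_detected")
        if kcat is None:
            flags.append("no_kcat")
            turnover = float("nan")
        elif np.isfinite(amount):
            turnover = turnover_potential(amount, const, rounding=rounding)
        else:
            turnover = float("nan")
        rows.append(
            {
                "enzyme": enzyme,
                "substrate": const.substrate,
                "tissue": tissue,
                "km_uM": const.km_uM,
                "kcat_per_s": kcat,
                "stoichiometry": const.substrate_stoichiometry,
                "ddct": round(ddct, 1) if rounding == "paper" and np.isfinite(ddct) else ddct,
                "amount": _round_amount(amount) if rounding == "paper" else amount,
                "relative_turnover": turnover,
                "flag": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def competition_ratio(enzyme_a: TurnoverEstimate, enzyme_b: TurnoverEstimate) -> float:
    """Fold difference in turnover potential of enzyme a over enzyme b.

    Substrate stoichiometry is already inside each score (an enzyme
    consuming two precursor molecules per event counts double).  Both
    estimates must come from the same tissue; a zero or undefined
    denominator yields NaN.
    """
    if enzyme_a.tissue != enzyme_b.tissue:
        raise ParameterError("competition ratio requires the same tissue")
    num, den = enzyme_a.relative_turnover, enzyme_b.relative_turnover
    if not (np.isfinite(num) and np.isfinite(den)) or den == 0:
        return float("nan")
    return float(num / den)


def turnover_estimate(
    ct_matrix: pd.DataFrame,
    constants: KineticConstants,
    tissue: str,
    reference_gene: str = "beta-actin",
    calibrator: tuple[str, str] = ("GAS", "stems"),
    gene_map: dict[str, str] | None = None,
    rounding: str = "none",
) -> TurnoverEstimate:
    """Build a :class:`TurnoverEstimate` for one enzyme in one tissue."""
    gene_map = DEFAULT_GENE_MAP if gene_map is None else gene_map
    gene = gene_map.get(constants.enzyme, constants.enzyme)
    ddct, amount = delta_delta_ct(ct_matrix, (gene, tissue), reference_gene, calibrator)
    if rounding == "paper":
        amount = _round_amount(amount)
    turnover = (
        turnover_potential(amount, constants, rounding=rounding)
        if constants.kcat_per_s is not None and np.isfinite(amount)
        else float("nan")
    )
    return TurnoverEstimate(
        enzyme=constants.enzyme,
        substrate=constants.substrate,
        tissue=tissue,
        ddct=ddct,
        normalized_amount=amount,
        kcat_per_s=constants.kcat_per_s,
        substrate_stoichiometry=constants.substrate_stoichiometry,
        relative_turnover=turnover,
        flag="known_discrepancy" if constants.enzyme in KNOWN_DISCREPANCIES else "",
    )


class DeltaDeltaCt(BaseEstimator, TransformerMixin):
    """Transformer mapping a mean-CT matrix to 2^-ddCT amounts.

    Stateless: ``transform`` applies :func:`amount_matrix` with the
    configured reference gene, calibrator cell and rounding mode.
    """

    def __init__(
        self,
        reference_gene: str = "beta-actin",
        calibrator: tuple[str, str] = ("GAS", "stems"),
        genes: list[str] | None = None,
        tissues: list[str] | None = None,
        rounding: str = "none",
    ):
        self.reference_gene = reference_gene
        self.calibrator = calibrator
        self.genes = genes
        self.tissues = tissues
        self.rounding = rounding

    def fit(self, X: pd.DataFrame, y=None) -> "DeltaDeltaCt":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return amount_matrix(
            X,
            genes=self.genes,
            tissues=self.tissues,
            reference_gene=self.reference_gene,
            calibrator=tuple(self.calibrator),
            rounding=self.rounding,
        )
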