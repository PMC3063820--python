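"""Packaged reference tables.

Three small CSV fixtures ship with the package: per-amplicon primer
efficiencies, the published mean CT matrix for six *Artemisia annua*
tissues (flower buds, young leaves, old leaves, stems, roots, hairy
roots), and Michaelis-Menten constants (K_m, k_cat, substrate
stoichiometry) for the artemisinin-pathway enzymes.  ``n.d.`` cells
(reactions with no detectable amplification, e.g. ADS in roots) are
loaded as missing values, never as a CT of 40.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigError

_FILES = {
    "table1": "table1_efficiencies.csv",
    "table2": "table2_ct.csv",
    "table4_kinetics": "table4_kinetics.csv",
}

#: Controlled vocabulary for the six tissues, in publication order.
TISSUES = ["flower_buds", "young_leaves", "old_leaves", "stems", "roots", "hairy_roots"]


def _read(name: str) -> pd.DataFrame:
    path = resources.files("qpcrflux.data").joinpath(_FILES[name])
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def load_paper_fixture(name: str) -> pd.DataFrame:
    """Return one of the packaged tables verbatim.

    Parameters
    ----------
    name : {"table1", "table2", "table4_kinetics"}
        ``table1`` — per-amplicon efficiency (fold/cycle) and fragment size;
        ``table2`` — mean CT per gene x tissue, ``n.d.`` as NaN;
        ``table4_kinetics`` — K_m (uM), k_cat (1/s) and substrate
        stoichiometry per enzyme/substrate pair.
    """
    if name not in _FILES:
        raise ConfigError(f"unknown fixture {name!r}; choose from {sorted(_FILES)}")
    df = _read(name)
    if name == "table2":
        df = df.set_index("gene")
        df = df.apply(pd.to_numeric, errors="coerce")
        df.columns.name = "tissue"
    elif name == "table1":
        df = df.set_index("gene")
    elif name == "table4_kinetics":
        df["stoichiometry"] = df["stoichiometry"].astype(int)
    return df


def load_ct_matrix() -> pd.DataFrame:
    """Mean CT matrix (gene x tissue) with non-detects as NaN."""
    return load_paper_fixture("table2")


def load_efficiencies() -> dict[str, float]:
    """Per-amplicon amplification efficiency as a plain dict."""
    t1 = load_paper_fixture("table1")
    return t1["efficiency"].to_dict()


def load_kinetics() -> pd.DataFrame:
    """Enzyme kinetic constants with substrate stoichiometry."""
    return load_paper_fixture("table4_kinetics")


def ct_matrix_to_long(matrix: pd.DataFrame, bio_rep: int = 1) -> pd.DataFrame:
    """Expand a mean-CT matrix into the long CT-table layout.

    Each cell becomes a single pseudo-replicate row; missing cells become
    not-detected rows.  Useful for feeding published averages through code
    paths written for replicate-level tables.
    """
    rows = []
    for gene in matrix.index:
        for tissue in matrix.columns:
            ct = matrix.loc[gene, tissue]
            detected = bool(np.isfinite(ct))
            rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    "bio_rep": bio_rep,
                    "tech_rep": 1,
                    "ct": ct if detected else np.nan,
                    "detected": detected,
                }
            )
    return pd.DataFrame(rows)
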