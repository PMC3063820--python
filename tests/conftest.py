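import numpy as np
import pytest

import qpcrflux as qf

SPAN = 1.0e4


@pytest.fixture(scope="session")
def ct_matrix():
    return qf.load_ct_matrix()


@pytest.fixture(scope="session")
def efficiencies():
    return qf.load_efficiencies()


@pytest.fixture(scope="session")
def kinetics():
    return qf.load_kinetics()


def make_curve(E, noise_sd=0.0, seed=None, initial_frac=None, baseline=100.0,
               n_cycles=40):
    """One synthetic trace; by default the template crosses 10% of the
    plateau span at cycle 20 (a realistic CT)."""
    A = (initial_frac if initial_frac is not None else 0.1 * E ** -20) * SPAN
    params = qf.CurveParams(
        true_efficiency=E,
        initial_amount=A,
        baseline=baseline,
        plateau=baseline + SPAN,
        noise_sd=noise_sd * (baseline + SPAN),
        n_cycles=n_cycles,
        seed=seed,
    )
    return qf.AmplificationCurve.from_frame(qf.simulate_curve(params))


def estimate_efficiency(curve):
    corrected = qf.baseline_correct(curve)
    _, slope, r = qf.window_of_linearity(corrected)
    return qf.efficiency_from_slope(slope), r


def null_pvalues(n_genes=200, master_seed=0, n_iter=1000):
    """Randomization p-values from independent no-effect experiments.

    Each replication simulates its own target and reference wells
    (triplicates in two biological runs) so the p-values are mutually
    independent.
    """
    seeds = np.random.SeedSequence(master_seed).generate_state(2 * n_genes)
    design = qf.DesignSpec(
        genes=["tgt", "r1", "r2"],
        tissues=["treated", "control"],
        control_tissue="control",
        reference_genes=["r1", "r2"],
        n_technical=3,
        n_biological=2,
        noise_sd=0.15,
        outlier_rate=0.0,
    )
    eff = {"tgt": 1.9, "r1": 1.9, "r2": 1.9}
    pvals = []
    for i in range(n_genes):
        table = qf.simulate_ct_table(design, eff, seed=int(seeds[2 * i]) % 2**31)
        model = qf.RelativeExpression(
            reference_genes=["r1", "r2"],
            control_tissue="control",
            efficiencies=eff,
            n_iter=n_iter,
            n_boot=20,
            seed=int(seeds[2 * i + 1]) % 2**31,
        ).fit(table)
        pvals.append(model.ratios_["p_value"].iloc[0])
    return np.asarray(pvals)


@pytest.fixture(scope="session")
def null_pvalue_sample():
    return null_pvalues(n_genes=200, master_seed=0, n_iter=1000)
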