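import numpy as np
import pandas as pd
import pytest

from oxynet.containers import ExpressionMatrix
from oxynet import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix():
    """4 features x 6 samples log2 matrix with one constant feature."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.normal(8, 1, size=(4, 6)),
        index=["f1", "f2", "f3", "f4"],
        columns=[f"S{i}" for i in range(1, 7)],
    )
    values.loc["f4"] = 5.0
    return ExpressionMatrix(values, layer="miRNA", scale="log2")


@pytest.fixture
def tiny_config():
    """Small but fully structured simulation config used by CLI/IO tests."""
    return sim.SimConfig(
        n_mirna_samples=60, n_mrna_samples=40, n_shared_samples=30,
        n_mirna=40, n_mrna=30, n_batches=2, batch_shift_sd=0.3,
        cluster_specs=(sim.ClusterSpec(5, 0.85),),
        edge_specs=(sim.EdgeSpec("ESR1", "hsa-miR-100-5p", -1, 0.7),
                    sim.EdgeSpec("CH25H", "hsa-miR-143-3p", +1, 0.7)),
        mutation_specs=(sim.MutationSpec("CYP46A1", ("CYP46A1",), 0.2,
                                         {"EBP": 2.5, "DHCR7": 2.0}),),
        clinical_effect_specs=(sim.ClinicalEffectSpec("pN", "N1", {"STARD5": 3.0}),),
        survival_spec=sim.SurvivalSpec(coefficients={"hsa-miR-100-5p": np.log(2.0)},
                                       censoring_rate=0.4),
        seed=11,
    )


@pytest.fixture
def tiny_cohort(tiny_config):
    return sim.generate_cohort(tiny_config)
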