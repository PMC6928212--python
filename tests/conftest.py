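import numpy as np
import pytest

from protqtl import (
    QTLModel,
    QTLLocus,
    simulate_phenotypes,
    simulate_ril_population,
    uniform_map,
)


@pytest.fixture(scope="session")
def small_map():
    """5 chromosomes x 9 markers over 80 cM: fast but non-trivial."""
    return uniform_map(n_chrom=5, n_markers=9, length_cm=80.0)


@pytest.fixture(scope="session")
def ril_small(small_map):
    return simulate_ril_population(small_map, n_lines=100, derived_generation=5, seed=11)


@pytest.fixture(scope="session")
def major_qtl_model(small_map):
    """One locus at the middle marker of Gm01 explaining 60% of variance."""
    grp = small_map.chrom_table("Gm01")
    cm = float(grp["cm"].iloc[len(grp) // 2])
    return QTLModel(
        loci=[QTLLocus(chrom="Gm01", cm=cm)],
        target_variance_fractions=[0.60],
    )


@pytest.fixture(scope="session")
def major_qtl_phenotypes(ril_small, major_qtl_model):
    return simulate_phenotypes(ril_small, major_qtl_model, n_trials=3, seed=12)


@pytest.fixture(scope="session")
def null_phenotypes(ril_small):
    model = QTLModel(loci=[], residual_sd=1.5)
    return simulate_phenotypes(ril_small, model, n_trials=3, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
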