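import pytest
from hypothesis import HealthCheck, settings

import regcircuit as rc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study exercised by several modules."""
    cfg = rc.SimConfig(
        n_genes=400, n_mirnas=120, n_tumor=40, n_normal=12,
        n_true_edges=80, n_decoy_edges=60, seed=11,
    )
    return rc.simulate_study(cfg)


@pytest.fixture(scope="session")
def high_power_study():
    """Strong planted effects and fully concordant proteins: the regime in
    which the pipeline should recover essentially all planted RRC1 edges."""
    cfg = rc.SimConfig(
        n_genes=600, n_mirnas=150, n_tumor=30, n_normal=30,
        lfc_magnitude=3.0, dispersion=0.05, base_mean_range=(100, 2000),
        frac_protein_concordant=1.0, n_true_edges=200, n_decoy_edges=100,
        seed=1,
    )
    return rc.simulate_study(cfg)


def run_de(cm, kind):
    sf = rc.estimate_size_factors(cm)
    res = rc.nb_wald_test(cm, sf)
    return res, rc.call_differential(res, kind)
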