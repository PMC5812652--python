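import numpy as np
import pytest

from coreresponse import de_engine, normalization, synthetic_data
from coreresponse.data_io import CountMatrix, build_design


@pytest.fixture()
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        gene_ids=["gA", "gB"],
        sample_ids=["s1", "s2"],
        counts=np.array([[3, 0], [1, 7]]),
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced full-design simulation run through normalization and DE,
    shared by the set/kinetics/ordination tests."""
    cfg = synthetic_data.SimConfig(n_genes=400, seed=5)
    counts, samples, truth = synthetic_data.simulate_experiment(cfg)
    design = build_design(counts, samples)
    filtered = normalization.filter_low_counts(counts, 1.2, design.smallest_group_size())
    factors = normalization.tmm_factors(filtered)
    disp = de_engine.estimate_dispersion(filtered, design, factors)
    de = de_engine.run_all_contrasts(filtered, design, factors, disp)
    return {
        "config": cfg,
        "counts": counts,
        "filtered": filtered,
        "samples": samples,
        "truth": truth,
        "design": design,
        "factors": factors,
        "dispersions": disp,
        "de": de,
    }
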