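import numpy as np
import pandas as pd
import pytest

from gliosig.qc import QCThresholds, apply_qc, lognormalize
from gliosig.simulate import SimCohortSpec, simulate_sc_cohort


@pytest.fixture(scope="session")
def mouse_cohort():
    """Default mouse-style cohort plus QC'd/normalized views and truth."""
    spec = SimCohortSpec(seed=42, species="mouse")
    counts, truth, variants, arms = simulate_sc_cohort(spec)
    mito = [g.startswith("mt-") for g in counts.gene_ids]
    filtered, _ = apply_qc(counts, QCThresholds.for_species("mouse"), mito)
    lognorm = lognormalize(filtered)
    truth = truth.set_index("cell_id").reindex(filtered.obs_ids)
    return {
        "spec": spec,
        "counts": filtered,
        "lognorm": lognorm,
        "truth": truth,
        "variants": variants,
        "arms": arms,
    }


@pytest.fixture(scope="session")
def human_cohort():
    """Default human-style cohort for the three-evidence annotation path."""
    spec = SimCohortSpec(seed=42, species="human")
    counts, truth, variants, arms = simulate_sc_cohort(spec)
    mito = [g.startswith("MT-") for g in counts.gene_ids]
    filtered, _ = apply_qc(counts, QCThresholds.for_species("human"), mito)
    lognorm = lognormalize(filtered)
    truth = truth.set_index("cell_id").reindex(filtered.obs_ids)
    return {
        "spec": spec,
        "counts": filtered,
        "lognorm": lognorm,
        "truth": truth,
        "variants": variants,
        "arms": arms,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
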