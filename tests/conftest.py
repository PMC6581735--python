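import numpy as np
import pytest

from sdconnectome import (
    CohortSpec,
    ConnectomeStudy,
    SvmConfig,
    build_mask_family,
    build_networks,
    generate_cohort,
    uniform_parcellation,
)

# coarse grids keep test-scale grid searches fast while still exercising the
# search + tie-break machinery
FAST_SVM = SvmConfig(
    C_grid=(1.0, 2.0**7),
    gamma_grid=(2.0**-5, 2.0**-1),
    inner_cv_folds=3,
    seed=0,
)


@pytest.fixture(scope="session")
def planted_small():
    """A small cohort with a strong effect planted in region R1:
    12 nodes (3 regions of 4), 10+10 subjects, 120 timepoints."""
    spec = CohortSpec(
        n_sd=10, n_hc=10, n_nodes=12, n_timepoints=120,
        planted_regions=("R1",), effect_size=0.6, seed=11,
    )
    records, series = generate_cohort(spec)
    groups = [r.group for r in records]
    adjs = build_networks(series)
    return spec, records, series, adjs, groups


@pytest.fixture(scope="session")
def planted_small_masks(planted_small):
    _, _, _, adjs, groups = planted_small
    return build_mask_family(adjs, groups, alpha=0.05)


@pytest.fixture(scope="session")
def toy_parcellation():
    return uniform_parcellation(12, region_size=4)  # regions R1, R2, R3


@pytest.fixture(scope="session")
def planted_study(planted_small, toy_parcellation):
    _, records, series, adjs, groups = planted_small
    return ConnectomeStudy(adjs, groups, toy_parcellation, records)
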