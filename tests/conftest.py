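import numpy as np
import pandas as pd
import pytest

from gcniche import (
    AnalysisConfig,
    CellTable,
    ContaminationParams,
    TissueConfig,
    generate_tissue,
)


@pytest.fixture(scope="session")
def small_tissue():
    """Reduced tonsil (~4k cells, 2 follicles) with default contamination."""
    return generate_tissue(TissueConfig.small(seed=7))


@pytest.fixture(scope="session")
def clean_small_tissue():
    """Reduced tonsil with contamination switched off."""
    return generate_tissue(
        TissueConfig.small(seed=7, contamination=ContaminationParams.none())
    )


@pytest.fixture(scope="session")
def default_run():
    """Full default tissue (seed 1) with the complete pipeline applied."""
    from gcniche import run_pipeline

    tissue = generate_tissue(TissueConfig(seed=1))
    result = run_pipeline(AnalysisConfig(seed=1), tissue.cells, tissue.counts)
    return tissue, result


def make_cell_table(xy, types, sample="S1", samples=None):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return CellTable.from_frame(pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "x": xy[:, 0],
        "y": xy[:, 1],
        "sample_id": samples if samples is not None else [sample] * n,
        "type_l1": list(types),
    }))
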