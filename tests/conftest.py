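import numpy as np
import pandas as pd
import pytest

from scentnet.registry_io import (
    Compound,
    CompoundRegistry,
    IS_CODE,
    DEFAULT_IS_MASS_MG,
    PeakTable,
)


def make_peak_table(
    areas: dict[str, dict[str, float | None]],
    fresh_weight: float | dict = 1.0,
    is_mass: float = DEFAULT_IS_MASS_MG,
    is_area: float = 1e6,
) -> PeakTable:
    """Small peak-table builder; None cells mean not detected."""
    df = pd.DataFrame(areas, dtype=float)
    samples = list(df.columns)
    df.loc[IS_CODE] = is_area
    fw = (
        pd.Series(fresh_weight, index=samples)
        if np.isscalar(fresh_weight)
        else pd.Series(fresh_weight)
    )
    return PeakTable(
        areas=df,
        fresh_weight=fw,
        is_mass=pd.Series(is_mass, index=samples),
    )


@pytest.fixture
def tiny_registry() -> CompoundRegistry:
    return CompoundRegistry.from_compounds(
        [
            Compound("Methyl benzoate", "v06", "benzenoid_phenylpropanoid", 0.52),
            Compound("Linalool", "v01", "terpenoid", None),
            Compound("Leaf acetate", "v10", "fatty_acid_derivative", 12.10),
            Compound("Decane", "v08", "other", None),
        ]
    )


@pytest.fixture
def tiny_peaks() -> PeakTable:
    return make_peak_table(
        {
            "SF_ES_1": {"v06": 2.0e6, "v01": 1.0e6, "v10": None},
            "SF_ES_2": {"v06": 2.2e6, "v01": 0.8e6, "v10": None},
            "WF_ES_1": {"v06": 1.0e6, "v01": None, "v10": 0.5e6},
        }
    )
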