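import numpy as np
import pytest

from sancomplex.cells.modulation import CellParameterSet
from sancomplex.geometry import build_synthetic_complex
from sancomplex.protocols import geometry_preset
from sancomplex.regions import Region, default_scaling_table


@pytest.fixture(scope="session")
def scaling_table():
    return default_scaling_table()


def region_params(table, region: Region, ach_nm: float = 0.0) -> CellParameterSet:
    sc = table[region]
    return CellParameterSet(model_kind="SAN", scale_na=sc.i_na, scale_f=sc.i_f,
                            scale_k1=sc.i_k1, scale_kach=sc.i_kach, ach_nM=ach_nm)


@pytest.fixture(scope="session")
def desk_geometry():
    return build_synthetic_complex(geometry_preset("desk"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
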