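import numpy as np
import pandas as pd
import pytest

from fluidnet.model import (
    AssayMeta, Fluid, MeasurementMatrix, Platform, Scale, Status,
)
from fluidnet.synth import SimulationDesign, simulate_cohort


#: scaled-down design for tests that only need the structure, not the scale
SMALL_DESIGN = SimulationDesign(
    n_soma=200, n_olink=60, n_tmt=100, n_anchor=40,
    n_modules=4, module_size=12,
    module_effects=(1.5, -1.5, 1.0, 0.0),
    n_soma_duplicates=4, n_olink_duplicates=2,
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_DESIGN, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_matrix(values, samples=None, assays=None, scale=Scale.LINEAR,
                status=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"S{i}" for i in range(values.shape[0])]
    assays = assays or [f"A{j}" for j in range(values.shape[1])]
    vdf = pd.DataFrame(values, index=samples, columns=assays)
    sdf = None
    if status is not None:
        sdf = pd.DataFrame(np.asarray(status, dtype=np.int8),
                           index=samples, columns=assays)
    return MeasurementMatrix(vdf, sdf, scale)


def make_meta(assay_id, platform=Platform.SOMASCAN, uniprot="", symbol="",
              fluid=Fluid.CSF, **kw):
    return AssayMeta(assay_id=assay_id, platform=platform, uniprot=uniprot,
                     gene_symbol=symbol or (uniprot and f"G{uniprot}"),
                     fluid=fluid, **kw)
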