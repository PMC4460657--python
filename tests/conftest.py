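import numpy as np
import pytest

from gridqsar.chem_io import Atom, Molecule
from gridqsar.synthetic_data import make_planted_dataset, make_series

METHANE_SDF = """methane
  test

  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6290    0.6290    0.6290 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6290   -0.6290    0.6290 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6290    0.6290   -0.6290 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6290   -0.6290   -0.6290 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
M  END
$$$$
"""


@pytest.fixture
def methane_sdf(tmp_path):
    path = tmp_path / "methane.sdf"
    path.write_text(METHANE_SDF)
    return path


@pytest.fixture
def single_atom():
    return Molecule(
        id="one",
        atoms=[Atom(element="C", position=np.zeros(3), partial_charge=1.0,
                    vdw_rmin=1.70, vdw_epsilon=0.107)],
    )


@pytest.fixture
def small_series():
    return make_series(6, seed=42)


@pytest.fixture
def published_model():
    """The published 6-descriptor model equation loaded as a QsarModel."""
    from gridqsar.sw_mlr import QsarModel

    coefficients = {
        "E_337": 0.2989, "S_335": 3.2763, "E_832": 0.1785,
        "E_424": 0.4938, "S_151": -11.7460, "E_721": -0.6486,
    }
    coef_se = {
        "E_337": 0.0020, "S_335": 0.5560, "E_832": 0.0003,
        "E_424": 0.0033, "S_151": 0.3402, "E_721": 0.0019,
    }
    return QsarModel(
        selected=list(coefficients),
        coefficients=coefficients,
        coef_se=coef_se,
        intercept=5.0198,
        r2=0.9751, r2_se=0.0966,
        q2=0.9491, q2_se=0.1380,
        pred_r2=0.9525, pred_r2_se=0.1282,
        n_train=27,
    )


@pytest.fixture
def planted():
    return make_planted_dataset(
        n_compounds=30, n_descriptors=20, k_informative=3, noise_sd=0.1, seed=11
    )
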