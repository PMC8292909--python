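import os

# single-threaded BLAS: reproducible reductions and no thread thrashing on
# the small matrices this suite works with
for var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(var, "1")

import numpy as np
import pytest

from pocketscreen import synthetic
from pocketscreen.structure import flood_fill_site


@pytest.fixture(scope="session")
def pocket_and_site():
    spec = synthetic.PocketSpec()
    pocket = synthetic.make_pocket(seed=5, spec=spec)
    site = flood_fill_site(pocket, spec.cavity_center(), spec.flood_params())
    return spec, pocket, site


@pytest.fixture(scope="session")
def planted_library():
    planted = {
        "mw_below_min": 6, "mw_above_max": 6, "too_many_chiral": 6,
        "too_many_atoms": 5, "too_many_rotatable": 6,
        "element_not_allowed": 5, "pains": 3, "parse_error": 3,
    }
    records, truth = synthetic.make_ligand_library(100, seed=3, planted=planted, n_salts=5)
    return records, truth, planted


@pytest.fixture(scope="session")
def tmt_fixture():
    return synthetic.make_tmt_fixture(n_proteins=1000, n_planted=50,
                                      planted_lfc=-1.0, within_sd=0.1, seed=7)
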