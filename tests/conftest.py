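import numpy as np
import pytest

import xenoscale as xs
from xenoscale.io import default_pk_spec


@pytest.fixture(scope="session")
def mouse_pk():
    return default_pk_spec("mouse_ip")


@pytest.fixture(scope="session")
def mouse_regimen():
    """q3d x 4 i.p. dosing, 2.5 mg per dose (100 mg/kg at 25 g)."""
    return xs.DoseRegimen(
        tuple(xs.DoseEvent(3.0 * i, 2.5, route="ip") for i in range(4)), 43.0
    )


@pytest.fixture(scope="session")
def mouse_conc(mouse_pk, mouse_regimen):
    return xs.simulate_pk(mouse_pk, mouse_regimen, np.linspace(0.0, 43.0, 301))


@pytest.fixture(scope="session")
def gem_conc_month():
    """Standard gemcitabine exposure over 14 months, on the month axis."""
    spec = default_pk_spec("human_gemcitabine")
    regimen = xs.build_regimen("gemcitabine_standard", 14 * 30.0, bsa_m2=1.8)
    return xs.simulate_pk(spec, regimen).to_unit("month")


@pytest.fixture(scope="session")
def default_truth():
    return xs.PanelTruth()


@pytest.fixture(scope="session")
def small_panel(default_truth):
    """A 6-study synthetic panel plus its per-study true parameters."""
    truth = xs.PanelTruth(n_studies=6)
    return xs.generate_pdx_panel(truth, seed=101)


@pytest.fixture(scope="session")
def small_panel_fits(small_panel):
    panel, _ = small_panel
    return xs.fit_panel(panel, error="proportional", compute_se=False)
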