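import numpy as np
import pytest

from albind.spectra import Spectrum, SpectrumKind
from albind.synth import (
    AML_SERIES_M,
    Q_SERIES_M,
    TitrationScenario,
    simulate_titration,
)

#: Generative values of the four studied systems (molar) used across tests.
KD_Q_BINARY = 6.48e-6
KD_AML_BINARY = 183.77e-6
KD_Q_TERNARY = 2.39e-6
KD_AML_TERNARY = 192.81e-6


@pytest.fixture
def q_scenario_noise_free() -> TitrationScenario:
    """Quercetin-into-HSA quenching titration, no noise, inner filter on."""
    return TitrationScenario(
        l_totals=Q_SERIES_M,
        k_d=KD_Q_BINARY,
        ratio_at_saturation=0.1,
        absorbance_per_molar=(12000.0, 3000.0),
        noise_sd=0.0,
    )


@pytest.fixture
def aml_scenario_noise_free() -> TitrationScenario:
    """Amlodipine-into-HSA quenching titration, no noise."""
    return TitrationScenario(
        l_totals=AML_SERIES_M,
        k_d=KD_AML_BINARY,
        ratio_at_saturation=0.15,
        absorbance_per_molar=(1000.0, 200.0),
        noise_sd=0.0,
    )


@pytest.fixture
def q_series_noise_free(q_scenario_noise_free):
    return simulate_titration(q_scenario_noise_free)


def gaussian_emission(
    center: float, sigma: float = 20.0, lo: float = 300.0, hi: float = 450.0
) -> Spectrum:
    axis = np.arange(lo, hi + 0.5, 1.0)
    return Spectrum(
        axis=axis,
        signal=np.exp(-((axis - center) ** 2) / (2 * sigma**2)),
        kind=SpectrumKind.EMISSION,
    )
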