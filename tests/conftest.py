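import numpy as np
import pytest

import kaifluor as kf

#: Per-state intensities used throughout as ground truth, canonical order
#: (SpT, pSpT, pST, ST).
F_TRUE = (40.0, 8.0, 20.0, 38.0)


@pytest.fixture
def oscillation_model():
    return kf.OscillationModel(period=24.0, state_phases=(6.0, 12.0, 18.0, 0.0))


@pytest.fixture
def oscillation_abundances(oscillation_model):
    return kf.generate_oscillation_abundances(oscillation_model)


@pytest.fixture
def state_fluorescence():
    return kf.StateFluorescence(
        f_values=dict(zip(kf.STATES, F_TRUE)),
        construct="F419W",
        condition="KaiC-alone",
    )


@pytest.fixture
def kinetic_model():
    return kf.PhosphoKineticModel()


def gaussian_spectrum(center=340.0, sigma=15.0, amplitude=1.0,
                      wavelengths=None, meta=None):
    wl = np.arange(300.0, 401.0) if wavelengths is None else np.asarray(wavelengths)
    return kf.EmissionSpectrum(
        wavelengths=wl,
        intensities=amplitude * np.exp(-0.5 * ((wl - center) / sigma) ** 2),
        meta=meta or {},
    )
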