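"""Pinned physical constants: tissue optics, hemoglobin extinction, DPF.

All tables here are the single source of truth shared by the synthetic
generator (forward direction) and the unmixing/MBLL code (inverse direction),
so round trips are exact by construction.

Units
-----
* absorption / reduced scattering: mm^-1
* extinction coefficients: mm^-1 per uM of chromophore, natural-log
  convention (literature molar base-10 values times ln 10)
* wavelengths: nm
"""

from __future__ import annotations

import numpy as np

#: The two operating wavelengths of the dual-wavelength CW instrument.
WAVELENGTHS: tuple[float, float] = (690.0, 830.0)

#: Tissue label codes used in every voxelized head model.
TISSUE_OUTSIDE = 0
TISSUE_SCALP_SKULL = 1
TISSUE_CSF = 2
TISSUE_GRAY = 3
TISSUE_WHITE = 4

TISSUE_NAMES = {
    TISSUE_OUTSIDE: "outside",
    TISSUE_SCALP_SKULL: "scalp_skull",
    TISSUE_CSF: "csf",
    TISSUE_GRAY: "gray",
    TISSUE_WHITE: "white",
}

# Baseline optical properties per (tissue, wavelength), from a published
# compilation for adult head tissue in the NIR window.  CSF is given a small
# but nonzero reduced scattering so the diffusion approximation stays valid.
DEFAULT_MU_A = {  # mm^-1
    (TISSUE_SCALP_SKULL, 690.0): 0.0159,
    (TISSUE_SCALP_SKULL, 830.0): 0.0164,
    (TISSUE_CSF, 690.0): 0.0040,
    (TISSUE_CSF, 830.0): 0.0040,
    (TISSUE_GRAY, 690.0): 0.0178,
    (TISSUE_GRAY, 830.0): 0.0186,
    (TISSUE_WHITE, 690.0): 0.0167,
    (TISSUE_WHITE, 830.0): 0.0208,
}

DEFAULT_MU_S_PRIME = {  # mm^-1
    (TISSUE_SCALP_SKULL, 690.0): 0.80,
    (TISSUE_SCALP_SKULL, 830.0): 0.74,
    (TISSUE_CSF, 690.0): 0.30,
    (TISSUE_CSF, 830.0): 0.30,
    (TISSUE_GRAY, 690.0): 1.25,
    (TISSUE_GRAY, 830.0): 1.11,
    (TISSUE_WHITE, 690.0): 1.21,
    (TISSUE_WHITE, 830.0): 1.01,
}

#: Refractive index, identical for all head tissues.
DEFAULT_REFRACTIVE_INDEX = 1.4

_LN10 = float(np.log(10.0))

# Molar extinction (cm^-1 / M, base-10) at 690 / 830 nm from the standard
# hemoglobin compilation, converted to mm^-1 per uM, natural log:
# eps[mm^-1/uM] = eps[cm^-1/M] * 1e-6 [M/uM] * 0.1 [cm/mm] * ln(10).
_EXT_BASE10_CM_PER_M = {
    ("o2hb", 690.0): 276.0,
    ("hhb", 690.0): 2051.96,
    ("o2hb", 830.0): 974.0,
    ("hhb", 830.0): 693.04,
}

EXTINCTION = {
    key: value * 1e-7 * _LN10 for key, value in _EXT_BASE10_CM_PER_M.items()
}


def extinction_matrix(wavelengths=WAVELENGTHS) -> np.ndarray:
    """2x2 matrix E with E[i] = (eps_O2Hb, eps_HHb) at wavelengths[i].

    Maps concentration changes (uM) to absorption changes (mm^-1):
    ``delta_mu_a = E @ [dO2Hb, dHHb]``.
    """
    return np.array(
        [
            [EXTINCTION[("o2hb", w)], EXTINCTION[("hhb", w)]]
            for w in wavelengths
        ]
    )


#: Differential pathlength factors for adult head tissue.
DEFAULT_DPF = {690.0: 6.0, 830.0: 5.8}

#: Acquisition rate of the time-multiplexed CW instrument (Hz).
DEFAULT_SAMPLING_RATE = 39.7365
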