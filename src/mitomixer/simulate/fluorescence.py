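"""Per-cell two-channel fluorescence panel simulation.

Emulates imaging of recipient cells whose transferred (donor) mitochondria
carry an intrinsic Dendra2 label while total mitochondrial content is
stained with MitoTracker. Single-cell intensities are lognormal, as is
typical of fluorescence microscopy/cytometry data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..assays import FluorescencePanel
from ..errors import InvalidParameterError


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-median lognormal multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def simulate_fluorescence(
    n_cells: int,
    exo_fraction: float,
    noise_cv: float,
    seed: int = 0,
    n_calibration: int = 50,
    gain: float = 0.6,
    total_median: float = 1000.0,
    total_cv: float = 0.6,
) -> FluorescencePanel:
    """Simulate a fluorescence panel with known exogenous-mito fraction.

    Each cell's total mitochondrial signal is lognormal (median
    ``total_median`` a.u., CV ``total_cv``). The Dendra2 channel reads
    ``exo_fraction x total x gain`` and the MitoTracker channel reads
    ``total``, each corrupted by independent unit-median lognormal noise of
    coefficient of variation ``noise_cv``. ``n_calibration`` additional
    cells with entirely exogenous mitochondria (fraction 1.0) are appended
    and flagged ``is_calibration``; they model the donor-derived control
    population used to fix the channel gain.
    """
    if n_cells < 1 or n_calibration < 0:
        raise InvalidParameterError("cell counts must be positive")
    if not 0.0 <= exo_fraction <= 1.0:
        raise InvalidParameterError("exo_fraction must lie in [0, 1]")
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")

    rng = np.random.default_rng(seed)
    n_total = n_cells + n_calibration
    fractions = np.full(n_total, exo_fraction)
    fractions[n_cells:] = 1.0

    total = total_median * _lognormal_noise(rng, total_cv, n_total)
    dendra2 = (
        fractions * total * gain * _lognormal_noise(rng, noise_cv, n_total)
    )
    mitotracker = total * _lognormal_noise(rng, noise_cv, n_total)

    is_cal = np.zeros(n_total, dtype=bool)
    is_cal[n_cells:] = True
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(n_total)],
            "dendra2_intensity": dendra2,
            "mitotracker_intensity": mitotracker,
            # recipient cells are dTomato-negative; the fully-exogenous
            # controls are donor-type cells and carry the lineage marker
            "dtomato_positive": is_cal.copy(),
            "is_calibration": is_cal,
        }
    )
    return FluorescencePanel(cells=cells)
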