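"""Seeded simulator of Psi-labeled vegetation-like leaf reflectance spectra.

Real paired (reflectance, Psi_leaf) datasets for this task are scarce; this
module produces a phenomenological stand-in with the statistical structure a
dehydration experiment yields, so the whole pipeline is testable end to end:

* vegetation-shaped spectra: low visible reflectance, a chlorophyll
  absorption dip near 680 nm, a steep red-edge rise across 700-750 nm and a
  near-infrared plateau beyond ~900 nm;
* a monotone water-status effect: more negative Psi_leaf (drier leaves)
  raises NIR reflectance;
* a right-skewed, imbalanced Psi distribution (most samples mildly
  stressed, a thin tail toward -2.5 MPa), as slow-dehydration sampling
  produces;
* multiplicative (gain) then additive (sensor) Gaussian noise.

It is a template model, not a radiative-transfer simulation: parameters were
chosen once so that a linear baseline attains moderate but imperfect
accuracy, leaving headroom for the deep model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral_core import (
    PROVENANCE_MEASURED,
    SpectraSet,
    Spectrum,
    WavelengthGrid,
)

__all__ = ["SimulationConfig", "sample_psi_values", "psi_to_spectrum", "generate_dataset"]


@dataclass
class SimulationConfig:
    """Conditions of the simulated dehydration experiment.

    Defaults mirror the measurement campaign the simulator emulates:
    229 samples spanning Psi_leaf -2.5 to -0.1 MPa with mean near -1 MPa.

    Parameters
    ----------
    n_samples : sample count (default 229).
    psi_range_mpa : (lo, hi) support of Psi_leaf in MPa, both negative.
    beta_a, beta_b : shape of the Beta law (on the high-to-low Psi axis)
        producing the right-skewed imbalance; Beta(1.8, 3.0) over the
        default range gives mean -1.0 MPa with density thinning toward
        -2.5 MPa.
    noise_sd_multiplicative : SD of the per-spectrum gain noise (default 0.02).
    noise_sd_additive : SD of the per-band sensor noise (default 0.005).
    nir_sensitivity : rise of the NIR plateau reflectance per MPa of Psi
        decline (default 0.08, i.e. a -2.5 MPa leaf sits ~0.19 above a
        -0.1 MPa leaf at the plateau before noise).
    """

    n_samples: int = 229
    seed: int = 0
    psi_range_mpa: tuple[float, float] = (-2.5, -0.1)
    beta_a: float = 1.8
    beta_b: float = 3.0
    noise_sd_multiplicative: float = 0.02
    noise_sd_additive: float = 0.005
    nir_sensitivity: float = 0.08

    def __post_init__(self) -> None:
        lo, hi = self.psi_range_mpa
        if not (lo < hi <= 0):
            raise ValueError(f"psi_range_mpa must satisfy lo < hi <= 0, got {self.psi_range_mpa}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.noise_sd_additive < 0 or self.noise_sd_multiplicative < 0:
            raise ValueError("noise SDs must be >= 0")


def sample_psi_values(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw an imbalanced sample of Psi_leaf values (MPa).

    Psi = hi - (hi - lo) * Beta(a, b): mass concentrates near the mild-stress
    end (hi) and thins toward the most negative values, reproducing the
    scarcity of measurements on strongly dehydrated leaves.
    """
    lo, hi = cfg.psi_range_mpa
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    frac = rng.beta(cfg.beta_a, cfg.beta_b, size=cfg.n_samples)
    return hi - (hi - lo) * frac


# Template landmarks (nm): chlorophyll dip, red edge, NIR plateau onset.
_DIP_CENTER_NM = 680.0
_DIP_WIDTH_NM = 25.0
_RED_EDGE_CENTER_NM = 722.0
_RED_EDGE_WIDTH_NM = 9.0
_VIS_BASE = 0.09
_DIP_DEPTH = 0.045
_PLATEAU_BASE = 0.45
_PLATEAU_REF_PSI = -0.1  # plateau equals _PLATEAU_BASE at this Psi


def _noiseless_template(psi: float, grid: WavelengthGrid, nir_sensitivity: float) -> np.ndarray:
    w = grid.values
    vis = _VIS_BASE - _DIP_DEPTH * np.exp(-0.5 * ((w - _DIP_CENTER_NM) / _DIP_WIDTH_NM) ** 2)
    plateau = _PLATEAU_BASE + nir_sensitivity * (_PLATEAU_REF_PSI - psi)
    edge = 1.0 / (1.0 + np.exp(-(w - _RED_EDGE_CENTER_NM) / _RED_EDGE_WIDTH_NM))
    return vis + (plateau - vis) * edge


def psi_to_spectrum(
    psi: float,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    grid: WavelengthGrid | None = None,
) -> Spectrum:
    """Render one spectrum for a given Psi_leaf (MPa).

    The noiseless template is low in the visible (~0.05-0.12) with a
    Gaussian absorption dip at 680 nm, rises logistically across the red
    edge, and plateaus in the NIR; the plateau level increases linearly with
    water stress (nir_sensitivity per MPa of decline), making the noiseless
    Psi -> spectrum map injective. Gain and sensor noise are then applied
    and the result is clipped to [0, 1.2].
    """
    lo, hi = cfg.psi_range_mpa
    if not (lo <= psi <= hi):
        raise ValueError(f"psi={psi} outside configured range {cfg.psi_range_mpa}")
    if grid is None:
        grid = WavelengthGrid.default()
    r = _noiseless_template(psi, grid, cfg.nir_sensitivity)
    if rng is not None and (cfg.noise_sd_multiplicative > 0 or cfg.noise_sd_additive > 0):
        gain = 1.0 + cfg.noise_sd_multiplicative * rng.standard_normal()
        r = r * gain + cfg.noise_sd_additive * rng.standard_normal(grid.n_bands)
    return Spectrum(grid=grid, reflectance=np.clip(r, 0.0, 1.2))


def generate_dataset(cfg: SimulationConfig, grid: WavelengthGrid | None = None) -> SpectraSet:
    """Simulate a full labeled dataset; bitwise-deterministic given cfg."""
    if grid is None:
        grid = WavelengthGrid.default()
    rng = np.random.default_rng(cfg.seed)
    psi = sample_psi_values(cfg, rng)
    spectra = np.empty((cfg.n_samples, grid.n_bands))
    for i, p in enumerate(psi):
        spectra[i] = psi_to_spectrum(float(p), cfg, rng, grid).reflectance
    return SpectraSet(
        grid=grid,
        spectra=spectra,
        psi=psi,
        sample_ids=[f"sim{i:04d}" for i in range(cfg.n_samples)],
        provenance=[PROVENANCE_MEASURED] * cfg.n_samples,
    )
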