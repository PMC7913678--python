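"""Seeded synthetic-data generators for every technique the suite consumes.

These emulate the study conditions so that every processing module is
testable without instruments: two-state melting curves with sloped linear
baselines and Gaussian noise, CD band patterns for the three stacking-type
signatures, Gaussian MS peaks at the predicted K-adduct m/z over a uniform
noise floor, Lorentzian imino NMR peaks, and Gaussian arrival-time
distributions.  Identical parameters and seed yield identical output.

Noise is i.i.d. Gaussian per point — no instrument drift, no isotope fine
structure, no stray-light or saturation effects.
"""

from __future__ import annotations

import numpy as np

from .cd import CDSpectrum
from .melting import MeltingCurve, two_state_model
from .ms import MassSpectrum, neutral_mass, species_mz
from .nmr import NMRTrace

__all__ = [
    "make_melting_curve",
    "make_cd_spectrum",
    "make_mass_spectrum",
    "make_nmr_trace",
    "make_atd",
    "CD_BANDS",
]

#: Signature CD bands per stacking type: (center nm, signed weight).
#: Positive 265 / negative 245 for parallel type I homo-stacking; positive
#: 270 + 290 and negative 245 for hybrid type II; positive 290 / negative
#: 260 for antiparallel type III hetero-stacking.
CD_BANDS = {
    "parallel-typeI": [(265.0, 1.0), (245.0, -0.5)],
    "hybrid-typeII": [(270.0, 0.7), (290.0, 1.0), (245.0, -0.5)],
    "antiparallel-typeIII": [(290.0, 1.0), (260.0, -0.6)],
}


def make_melting_curve(
    Tm_K: float = 328.15,
    dH0_J_mol: float = 200e3,
    a_F: float = -1e-4,
    b_F: float = 1.05,
    a_U: float = -5e-5,
    b_U: float = 0.80,
    T_range_C: tuple[float, float] = (4.0, 90.0),
    step_C: float = 0.5,
    sigma: float = 0.0,
    seed: int = 0,
    **curve_kwargs,
) -> MeltingCurve:
    """Two-state baseline-model curve on a temperature grid, plus noise.

    Defaults mimic a 10 uM G4 monitored at 295 nm over a 4-90 C ramp.
    """
    rng = np.random.default_rng(seed)
    T_C = np.arange(T_range_C[0], T_range_C[1] + step_C / 2, step_C)
    T_K = T_C + 273.15
    y = two_state_model(T_K, Tm_K, dH0_J_mol, a_F, b_F, a_U, b_U)
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=y.size)
    return MeltingCurve(T_C, y, **curve_kwargs)


def make_cd_spectrum(
    stacking: str = "parallel-typeI",
    amplitude: float = 10.0,
    sigma: float = 0.0,
    seed: int = 0,
    band_width_nm: float = 8.0,
    wavelength_range: tuple[float, float] = (220.0, 320.0),
    step_nm: float = 0.5,
    concentration_M: float = 1e-5,
    pathlength_cm: float = 0.2,
    unit: str = "delta_epsilon",
) -> CDSpectrum:
    """Sum-of-Gaussian-bands spectrum for one stacking-type signature.

    ``amplitude`` scales the strongest band (Delta-epsilon units when
    ``unit="delta_epsilon"``); ``sigma`` is per-point Gaussian noise in the
    same units.  ``stacking=None`` or zero amplitude gives a flat spectrum.
    """
    rng = np.random.default_rng(seed)
    wl = np.arange(wavelength_range[0], wavelength_range[1] + step_nm / 2, step_nm)
    y = np.zeros_like(wl)
    if stacking is not None and amplitude != 0.0:
        try:
            bands = CD_BANDS[stacking]
        except KeyError:
            raise ValueError(
                f"unknown stacking label {stacking!r}; expected one of {list(CD_BANDS)}"
            ) from None
        for center, weight in bands:
            y = y + amplitude * weight * np.exp(
                -0.5 * ((wl - center) / band_width_nm) ** 2
            )
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=y.size)
    return CDSpectrum(
        wl,
        y,
        concentration_M=concentration_M,
        pathlength_cm=pathlength_cm,
        unit=unit,
    )


def make_mass_spectrum(
    sequence: str,
    charges: tuple[int, ...] = (5,),
    abundances: dict[tuple[int, int], float] | None = None,
    peak_sigma_Th: float = 0.15,
    noise_floor: float = 0.0,
    seed: int = 0,
    mz_range: tuple[float, float] | None = None,
    step_Th: float = 0.02,
    mass_type: str = "average",
) -> MassSpectrum:
    """Gaussian peaks at predicted [M+bK]^z- m/z, scaled to abundances.

    ``abundances`` maps (b, z) -> relative weight within that charge state
    (default: the fully folded 2-K+ species only).  ``noise_floor`` adds
    seeded uniform noise on [0, noise_floor] in units of the tallest peak.
    Peak areas within one charge state are proportional to the requested
    weights (all peaks share one width, so apex heights are too).
    """
    rng = np.random.default_rng(seed)
    if abundances is None:
        abundances = {(2, z): 100.0 for z in charges}
    M = neutral_mass(sequence, mass_type)
    centers = {
        (b, z): species_mz(M, b, z, mass_type) for (b, z) in abundances
    }
    if mz_range is None:
        lo = min(centers.values()) - 10.0
        hi = max(centers.values()) + 10.0
    else:
        lo, hi = mz_range
    mz = np.arange(lo, hi + step_Th / 2, step_Th)
    y = np.zeros_like(mz)
    for (b, z), weight in abundances.items():
        c = centers[(b, z)]
        y = y + weight * np.exp(-0.5 * ((mz - c) / peak_sigma_Th) ** 2)
    if y.max() > 0:
        y = y / y.max()
    if noise_floor > 0:
        y = y + rng.uniform(0.0, noise_floor, size=y.size)
    return MassSpectrum(mz, y, metadata={"synthetic": True, "sequence": sequence})


def make_nmr_trace(
    peaks: list[tuple[float, float, float]],
    sigma: float = 0.0,
    seed: int = 0,
    ppm_range: tuple[float, float] = (8.0, 13.0),
    step_ppm: float = 0.002,
) -> NMRTrace:
    """Sum of Lorentzian lines; ``peaks`` is (ppm, height, FWHM-ppm)."""
    rng = np.random.default_rng(seed)
    ppm = np.arange(ppm_range[0], ppm_range[1] + step_ppm / 2, step_ppm)
    y = np.zeros_like(ppm)
    for center, height, fwhm in peaks:
        hw = fwhm / 2.0
        y = y + height * hw**2 / ((ppm - center) ** 2 + hw**2)
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=y.size)
    return NMRTrace(ppm, y)


def make_atd(
    centroids_ms: list[float],
    widths_ms: list[float],
    weights: list[float],
    mz_center: float = 1400.0,
    mz_sigma_Th: float = 0.2,
    sigma: float = 0.0,
    seed: int = 0,
    time_range_ms: tuple[float, float] = (20.0, 60.0),
    time_step_ms: float = 0.1,
    n_mz_bins: int = 11,
) -> np.ndarray:
    """Long-format IMS triples (arrival_time_ms, mz, intensity).

    The arrival-time profile is a weighted sum of Gaussians; intensity is
    spread over ``n_mz_bins`` m/z bins with a Gaussian profile around
    ``mz_center``.  Suitable input for :func:`g4kit.ms.extract_atd`.
    """
    if not (len(centroids_ms) == len(widths_ms) == len(weights)):
        raise ValueError("centroids, widths and weights must have equal length")
    rng = np.random.default_rng(seed)
    t = np.arange(time_range_ms[0], time_range_ms[1] + time_step_ms / 2, time_step_ms)
    profile = np.zeros_like(t)
    for c, w, a in zip(centroids_ms, widths_ms, weights):
        profile = profile + a * np.exp(-0.5 * ((t - c) / w) ** 2)
    mz_bins = mz_center + np.linspace(-2 * mz_sigma_Th, 2 * mz_sigma_Th, n_mz_bins)
    mz_profile = np.exp(-0.5 * ((mz_bins - mz_center) / mz_sigma_Th) ** 2)
    rows = []
    for mzv, mzw in zip(mz_bins, mz_profile):
        for tv, pv in zip(t, profile):
            val = pv * mzw
            if sigma > 0:
                val = max(0.0, val + rng.normal(0.0, sigma))
            rows.append((tv, mzv, val))
    return np.asarray(rows)
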