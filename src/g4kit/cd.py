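"""Circular dichroism: blank subtraction, Delta-epsilon normalization and
stacking-type classification.

Raw CD traces come in millidegrees (theta).  Normalization to the molar
ellipticity coefficient uses

    Delta_eps = theta / (32980 * C * l)        [M^-1 cm^-1]

with C the strand concentration in mol/L and l the path length in cm, which
puts spectra acquired at different concentrations and path lengths on a
common scale.

G-quadruplex topologies carry characteristic guanine-stacking CD signatures:

* parallel (type I, homo-stacking): positive maximum near 265 nm, negative
  near 245 nm;
* hybrid (type II, mixed stacking): two positive bands at ~270 and ~290 nm
  and one negative minimum near 245 nm;
* antiparallel (type III, hetero-stacking): positive maximum near 290 nm,
  negative minimum near 260 nm.

``classify_stacking`` turns these qualitative signatures into a deterministic
rule over signed extrema in fixed wavelength windows; the windows and
thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np

__all__ = [
    "CDSpectrum",
    "ClassifierConfig",
    "subtract_blank",
    "mdeg_to_delta_epsilon",
    "classify_stacking",
    "read_xy",
    "write_tidy",
]

#: Eq. constant converting mdeg to Delta-epsilon (32980 = 100 * 3298/10;
#: the standard CD conversion factor for theta in millidegrees).
MDEG_TO_DELTA_EPSILON = 32980.0

PARALLEL = "parallel-typeI"
HYBRID = "hybrid-typeII"
ANTIPARALLEL = "antiparallel-typeIII"
AMBIGUOUS = "ambiguous"


@dataclass
class CDSpectrum:
    """A CD trace with the metadata needed for normalization.

    ``unit`` is ``"mdeg"`` for raw instrument output or ``"delta_epsilon"``
    after normalization.
    """

    wavelength_nm: np.ndarray
    signal: np.ndarray
    concentration_M: float | None = None
    pathlength_cm: float | None = None
    buffer: str = ""
    unit: str = "mdeg"

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.signal.ndim != 1:
            raise ValueError("wavelength and signal must be 1-D")
        if self.wavelength_nm.size != self.signal.size:
            raise ValueError("wavelength and signal must have equal length")
        d = np.diff(self.wavelength_nm)
        if self.wavelength_nm.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength must be strictly monotonic")
        # store ascending for interpolation convenience
        if self.wavelength_nm.size > 1 and d[0] < 0:
            self.wavelength_nm = self.wavelength_nm[::-1].copy()
            self.signal = self.signal[::-1].copy()
        if self.unit not in ("mdeg", "delta_epsilon"):
            raise ValueError(f"unknown unit {self.unit!r}")


def subtract_blank(sample: CDSpectrum, blank: CDSpectrum) -> CDSpectrum:
    """Pointwise sample - blank (both in mdeg) on the sample's grid.

    When the grids differ the blank is linearly interpolated onto the sample
    grid; no extrapolation — the result is restricted to the overlap.
    """
    if sample.unit != "mdeg" or blank.unit != "mdeg":
        raise ValueError("blank subtraction operates on raw mdeg spectra")
    lo = max(sample.wavelength_nm[0], blank.wavelength_nm[0])
    hi = min(sample.wavelength_nm[-1], blank.wavelength_nm[-1])
    if lo > hi:
        raise ValueError("sample and blank wavelength ranges do not overlap")
    keep = (sample.wavelength_nm >= lo) & (sample.wavelength_nm <= hi)
    wl = sample.wavelength_nm[keep]
    blank_on_grid = np.interp(wl, blank.wavelength_nm, blank.signal)
    return replace(sample, wavelength_nm=wl, signal=sample.signal[keep] - blank_on_grid)


def mdeg_to_delta_epsilon(spectrum: CDSpectrum) -> CDSpectrum:
    """Normalize a blank-corrected mdeg spectrum to Delta-epsilon."""
    if spectrum.unit != "mdeg":
        raise ValueError("spectrum is not in mdeg")
    C, l = spectrum.concentration_M, spectrum.pathlength_cm
    if C is None or l is None:
        raise ValueError("concentration and path length are required to normalize")
    if not (C > 0 and l > 0):
        raise ValueError("concentration and path length must be > 0")
    return replace(
        spectrum,
        signal=spectrum.signal / (MDEG_TO_DELTA_EPSILON * C * l),
        unit="delta_epsilon",
    )


@dataclass
class ClassifierConfig:
    """Windows (nm) and thresholds for the stacking-signature rule.

    ``secondary_fraction`` is the minimum height of each hybrid positive band
    relative to the global |max|; ``noise_floor`` (Delta-epsilon units) is the
    minimum global |max| below which everything is ambiguous.
    """

    pos_265: tuple[float, float] = (255.0, 275.0)
    pos_290: tuple[float, float] = (285.0, 295.0)
    neg_245: tuple[float, float] = (240.0, 250.0)
    neg_260: tuple[float, float] = (255.0, 265.0)
    secondary_fraction: float = 0.20
    noise_floor: float = 0.5
    required_range: tuple[float, float] = (230.0, 310.0)
    smoothing_nm: float = 2.0


def _smooth(spec: CDSpectrum, bandwidth_nm: float) -> CDSpectrum:
    """Gaussian smoothing in the wavelength domain.

    The bandwidth (default 2 nm) is small against G-quadruplex CD bands
    (~10 nm wide) but suppresses point-to-point noise before the window
    extrema are read off.
    """
    if bandwidth_nm <= 0.0:
        return spec
    from scipy.ndimage import gaussian_filter1d

    spacing = float(np.median(np.diff(spec.wavelength_nm)))
    sigma_pts = bandwidth_nm / spacing
    if sigma_pts < 0.5:
        return spec
    return CDSpectrum(
        spec.wavelength_nm,
        gaussian_filter1d(spec.signal, sigma_pts, mode="nearest"),
        unit=spec.unit,
    )


def _window_extremum(spec: CDSpectrum, window: tuple[float, float], sign: int) -> float:
    mask = (spec.wavelength_nm >= window[0]) & (spec.wavelength_nm <= window[1])
    if not mask.any():
        return 0.0
    vals = spec.signal[mask]
    return float(vals.max()) if sign > 0 else float(vals.min())


def classify_stacking(
    spectrum: CDSpectrum, config: ClassifierConfig | None = None
) -> str:
    """Label a Delta-epsilon spectrum by its stacking-type CD signature.

    Returns one of ``parallel-typeI``, ``hybrid-typeII``,
    ``antiparallel-typeIII`` or ``ambiguous``.  Deterministic for a given
    spectrum and configuration.
    """
    if spectrum.unit != "delta_epsilon":
        raise ValueError("classification expects a Delta-epsilon spectrum")
    cfg = config or ClassifierConfig()
    lo, hi = cfg.required_range
    if spectrum.wavelength_nm[0] > lo or spectrum.wavelength_nm[-1] < hi:
        raise ValueError(
            f"spectrum must cover {lo:.0f}-{hi:.0f} nm; got "
            f"{spectrum.wavelength_nm[0]:.1f}-{spectrum.wavelength_nm[-1]:.1f} nm"
        )
    smoothed = _smooth(spectrum, cfg.smoothing_nm)
    global_abs = float(np.max(np.abs(smoothed.signal)))
    if global_abs < cfg.noise_floor:
        return AMBIGUOUS

    pos265 = _window_extremum(smoothed, cfg.pos_265, +1)
    pos290 = _window_extremum(smoothed, cfg.pos_290, +1)
    neg245 = _window_extremum(smoothed, cfg.neg_245, -1)
    neg260 = _window_extremum(smoothed, cfg.neg_260, -1)
    cut = cfg.secondary_fraction * global_abs

    # Hybrid needs both positive bands; check first because its 270-band also
    # satisfies the parallel positive window.
    if pos265 > cut and pos290 > cut and neg245 < -cut:
        return HYBRID
    if pos290 > cut and neg260 < -cut:
        return ANTIPARALLEL
    if pos265 > cut and neg245 < -cut:
        return PARALLEL
    return AMBIGUOUS


def read_xy(path, **metadata) -> CDSpectrum:
    """Read a two-column (wavelength_nm, signal_mdeg) CSV/TSV file.

    Comment lines (``#``) and a single textual header line are tolerated.
    """
    x, y = load_xy_columns(path)
    return CDSpectrum(x, y, **metadata)


def load_xy_columns(path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a two-column numeric text file (comma, tab or space separated)."""
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").replace("\t", " ").split()
            try:
                x, y = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                continue  # header or malformed line
            xs.append(x)
            ys.append(y)
    if not xs:
        raise ValueError(f"no numeric (x, y) rows found in {path}")
    return np.asarray(xs), np.asarray(ys)


def write_tidy(path, spectra: dict[tuple[str, str], CDSpectrum]) -> None:
    """Write spectra as a tidy long table (oligo, buffer, wavelength, value)."""
    import pandas as pd

    frames = []
    for (oligo, buffer), spec in spectra.items():
        frames.append(
            pd.DataFrame(
                {
                    "oligo": oligo,
                    "buffer": buffer,
                    "wavelength_nm": spec.wavelength_nm,
                    spec.unit: spec.signal,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
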