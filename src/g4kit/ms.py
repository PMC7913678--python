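"""Native ESI-MS annotation of DNA-potassium complexes.

In the electrospray-compatible buffer (trimethylammonium acetate + a little
KCl) an intramolecular G-quadruplex is detected in negative mode as
[M + bK - (z+b)H]^z-: each specifically bound K+ substitutes one proton of
the polyanionic backbone, and z further protons are removed to give the net
charge.  The expected m/z of a species with b bound potassiums at charge z is

    m/z = (M + b*(m_K - m_H) - z*m_H) / z.

Because n stacked G-quartets sandwich n - 1 cations, the number of bound K+
reports on the quartet count of the detected sub-ensemble (b ions -> b + 1
quartets); a 0-K species is read as unfolded (no quartet core).

Species abundances are compared within one charge state (the 5- state by
default): the intensity matched in each species' m/z window divided by the
charge-state total, in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from pyteomics import mass as _pmass

from .seqcore import parse_sequence

__all__ = [
    "MassSpectrum",
    "SpeciesAssignment",
    "ATDTrace",
    "neutral_mass",
    "composition",
    "species_mz",
    "adduct_spacing",
    "intensity_filter",
    "annotate",
    "species_abundance",
    "infer_quartets",
    "extract_atd",
    "read_spectrum",
    "read_mzml",
    "UNFOLDED",
]

#: Sentinel returned by :func:`infer_quartets` for the 0-K+ species.
UNFOLDED = "unfolded/no core"

# 2'-deoxyribonucleoside elemental compositions (free nucleosides, 5'-OH/3'-OH)
_NUCLEOSIDES = {
    "A": {"C": 10, "H": 13, "N": 5, "O": 3},
    "C": {"C": 9, "H": 13, "N": 3, "O": 4},
    "G": {"C": 10, "H": 13, "N": 5, "O": 4},
    "T": {"C": 10, "H": 14, "N": 2, "O": 5},
}

# Element masses from the NIST table bundled with pyteomics.
MASS_H = {"average": _pmass.calculate_mass(formula="H", average=True),
          "monoisotopic": _pmass.calculate_mass(formula="H")}
MASS_K = {"average": _pmass.calculate_mass(formula="K", average=True),
          "monoisotopic": _pmass.calculate_mass(formula="K")}


def composition(sequence: str) -> dict[str, int]:
    """Elemental composition of a linear DNA oligo with 5'-OH/3'-OH termini.

    n nucleosides joined by n-1 phosphodiester bridges; each bridge adds
    HPO3 and removes H2O.
    """
    seq = parse_sequence(sequence)
    comp: dict[str, int] = {"C": 0, "H": 0, "N": 0, "O": 0, "P": 0}
    for base in seq:
        for el, k in _NUCLEOSIDES[base].items():
            comp[el] += k
    n_link = len(seq) - 1
    comp["P"] += n_link
    comp["O"] += 3 * n_link - n_link  # +O3 per HPO3, -O per lost H2O
    comp["H"] += n_link - 2 * n_link  # +H per HPO3, -H2 per lost H2O
    return comp


def neutral_mass(sequence: str, mass_type: str = "average") -> float:
    """Neutral (fully protonated) mass in Da of a DNA oligonucleotide."""
    if mass_type not in ("average", "monoisotopic"):
        raise ValueError("mass_type must be 'average' or 'monoisotopic'")
    comp = composition(sequence)
    formula = "".join(f"{el}{n}" for el, n in comp.items() if n)
    return float(
        _pmass.calculate_mass(formula=formula, average=(mass_type == "average"))
    )


def species_mz(M: float, b: int, z: int, mass_type: str = "average") -> float:
    """Expected m/z (Th) of [M + bK - (z+b)H]^z- in negative mode."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if b < 0:
        raise ValueError(f"K+ count must be >= 0, got {b}")
    mH = MASS_H[mass_type]
    mK = MASS_K[mass_type]
    return (M + b * (mK - mH) - z * mH) / z


def adduct_spacing(z: int, mass_type: str = "average") -> float:
    """m/z spacing between consecutive K-adduct peaks at charge z."""
    return (MASS_K[mass_type] - MASS_H[mass_type]) / z


@dataclass
class MassSpectrum:
    """An (m/z, intensity) trace, negative polarity by default."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "negative"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size != self.intensity.size:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0


@dataclass
class SpeciesAssignment:
    """One (strand count a, K+ count b) species at one charge state."""

    a: int
    b: int
    z: int
    expected_mz: float
    window: tuple[float, float]
    matched_intensity: float
    relative_abundance: float = float("nan")  # % within the charge state

    @property
    def label(self) -> str:
        m = "M" if self.a == 1 else f"{self.a}M"
        return f"[{m}+{self.b}K]{self.z}-"


@dataclass
class ATDTrace:
    """Arrival-time distribution for one selected species window."""

    arrival_time_ms: np.ndarray
    intensity: np.ndarray
    species: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.arrival_time_ms = np.asarray(self.arrival_time_ms, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.arrival_time_ms.size > 1 and not np.all(
            np.diff(self.arrival_time_ms) > 0
        ):
            raise ValueError("arrival times must be increasing")


def intensity_filter(spectrum: MassSpectrum, threshold_fraction: float) -> MassSpectrum:
    """Drop points below ``threshold_fraction`` of the base-peak intensity.

    Points exactly at the threshold are retained, so the base peak itself
    always survives.  The applied threshold and removal count are recorded in
    the output metadata.
    """
    if not 0 <= threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in [0, 1)")
    cut = threshold_fraction * spectrum.base_peak_intensity()
    keep = spectrum.intensity >= cut
    removed = int((~keep).sum())
    meta = dict(spectrum.metadata)
    meta.update(
        {"intensity_filter_fraction": threshold_fraction, "points_removed": removed}
    )
    return replace(
        spectrum, mz=spectrum.mz[keep], intensity=spectrum.intensity[keep], metadata=meta
    )


def annotate(
    spectrum: MassSpectrum,
    sequence: str,
    species: list[tuple[int, int]] | None = None,
    charges: tuple[int, ...] = (5,),
    tolerance_Th: float = 1.0,
    mass_type: str = "average",
) -> list[SpeciesAssignment]:
    """Label a spectrum with [aM + bK]^z- species and compute abundances.

    ``species`` is a list of (strand count a, K+ count b); default monomer
    with 0-2 K+.  For each species x charge, the expected m/z window is
    ``expected +/- tolerance_Th``; intensity is summed over the window.
    Overlapping windows raise a warning and each point is attributed to the
    nearer expected m/z.  Assignments with no matched intensity are retained
    with abundance 0; relative abundances are percentages within each charge
    state.
    """
    if spectrum.mz.size == 0:
        raise ValueError("empty spectrum")
    if species is None:
        species = [(1, 0), (1, 1), (1, 2)]
    strand_mass = {
        a: a * neutral_mass(sequence, mass_type) for a in {a for a, _ in species}
    }
    out: list[SpeciesAssignment] = []
    for z in charges:
        expected = sorted(
            ((a, b, species_mz(strand_mass[a], b, z, mass_type)) for a, b in species),
            key=lambda t: t[2],
        )
        centers = np.array([e[2] for e in expected])
        if len(centers) > 1 and np.min(np.diff(centers)) < 2 * tolerance_Th:
            warnings.warn(
                f"overlapping m/z windows at z={z}; intensity attributed to the "
                "nearer expected m/z",
                stacklevel=2,
            )
        # attribute each point to the nearest center, if within tolerance
        nearest = np.argmin(np.abs(spectrum.mz[:, None] - centers[None, :]), axis=1)
        in_window = np.abs(spectrum.mz - centers[nearest]) <= tolerance_Th
        matched = [
            float(spectrum.intensity[(nearest == j) & in_window].sum())
            for j in range(len(expected))
        ]
        assigns = [
            SpeciesAssignment(
                a=a,
                b=b,
                z=z,
                expected_mz=c,
                window=(c - tolerance_Th, c + tolerance_Th),
                matched_intensity=m,
            )
            for (a, b, c), m in zip(expected, matched)
        ]
        total = sum(s.matched_intensity for s in assigns)
        for s in assigns:
            s.relative_abundance = (
                100.0 * s.matched_intensity / total if total > 0 else 0.0
            )
        out.extend(assigns)
    return out


def species_abundance(
    assignments: list[SpeciesAssignment], z: int
) -> dict[tuple[int, int], float]:
    """Relative abundances (%) of the species at charge state z."""
    at_z = [s for s in assignments if s.z == z]
    if not at_z:
        raise ValueError(f"no assignments at charge state {z}")
    total = sum(s.matched_intensity for s in at_z)
    if total <= 0:
        raise ValueError(f"zero total matched intensity at charge state {z}")
    return {(s.a, s.b): 100.0 * s.matched_intensity / total for s in at_z}


def infer_quartets(b: int) -> int | str:
    """Quartet count of the sub-ensemble binding b K+ ions (b + 1 quartets);
    a 0-K species has no quartet core and reads as unfolded."""
    if b < 0:
        raise ValueError(f"K+ count must be >= 0, got {b}")
    if b == 0:
        return UNFOLDED
    return b + 1


def extract_atd(
    ims_data: np.ndarray,
    mz_window: tuple[float, float],
    species: str = "",
    normalize: bool = False,
) -> ATDTrace:
    """Sum IMS intensities over an m/z window, per arrival-time bin.

    ``ims_data`` is an (n, 3) array of (arrival_time_ms, mz, intensity)
    triples.  An m/z window containing no data is an error.
    """
    ims = np.asarray(ims_data, dtype=float)
    if ims.ndim != 2 or ims.shape[1] != 3 or ims.shape[0] == 0:
        raise ValueError("ims_data must be a non-empty (n, 3) array")
    lo, hi = mz_window
    if not lo < hi:
        raise ValueError("mz window must satisfy lo < hi")
    sel = ims[(ims[:, 1] >= lo) & (ims[:, 1] <= hi)]
    if sel.shape[0] == 0:
        raise ValueError(f"no IMS data in m/z window [{lo}, {hi}]")
    times = np.unique(sel[:, 0])
    intens = np.array([sel[sel[:, 0] == t, 2].sum() for t in times])
    if normalize:
        peak = intens.max()
        if peak > 0:
            intens = intens / peak
    return ATDTrace(times, intens, species=species, normalized=normalize)


def read_spectrum(path, **metadata) -> MassSpectrum:
    """Read a two-column (m/z, intensity) text file."""
    from .cd import load_xy_columns

    mz, inten = load_xy_columns(path)
    order = np.argsort(mz)
    return MassSpectrum(mz[order], inten[order], metadata=dict(metadata))


def read_mzml(path, scan: int = 0) -> MassSpectrum:
    """Read one spectrum from an mzML file (first scan by default)."""
    from pyteomics import mzml

    with mzml.read(str(path)) as reader:
        for i, spec in enumerate(reader):
            if i == scan:
                polarity = "negative" if "negative scan" in spec else "positive"
                mz = np.asarray(spec["m/z array"], dtype=float)
                inten = np.asarray(spec["intensity array"], dtype=float)
                order = np.argsort(mz)
                return MassSpectrum(
                    mz[order],
                    inten[order],
                    polarity=polarity,
                    metadata={"scan": scan, "source": str(path)},
                )
    raise ValueError(f"scan {scan} not found in {path}")
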