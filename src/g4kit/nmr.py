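"""Minimal handling of processed 1D 1H NMR traces.

Guanine imino protons engaged in quartet Hoogsteen hydrogen bonding resonate
in the 10-12 ppm window, so the imino-region peak pattern fingerprints a
G-quadruplex fold.  This module crops that region, picks peaks above a
noise floor, and matches them to a published per-base assignment list;
detected peaks with no assignment are reported as minor/unassigned (they
flag coexisting minor conformations).  Spectral processing (phasing,
baseline, water suppression) happens upstream in instrument software.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "NMRTrace",
    "Assignment",
    "MatchReport",
    "crop_region",
    "normalize_trace",
    "pick_peaks",
    "match_assignments",
    "read_trace",
    "read_assignments",
    "IMINO_WINDOW",
]

#: Default imino-region crop (ppm).
IMINO_WINDOW = (9.5, 12.5)


@dataclass
class NMRTrace:
    """A processed 1D trace; descending-ppm convention accepted on input."""

    ppm: np.ndarray
    intensity: np.ndarray
    field_MHz: float | None = None
    temperature_C: float | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.size != self.intensity.size:
            raise ValueError("ppm and intensity must have equal length")
        d = np.diff(self.ppm)
        if self.ppm.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be monotonic")
        if self.ppm.size > 1 and d[0] < 0:  # store ascending internally
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()


@dataclass
class Assignment:
    """A published imino-proton assignment: position and base label."""

    ppm: float
    label: str  # e.g. "G4"
    source: str = ""


@dataclass
class MatchReport:
    """Outcome of comparing detected peaks with an assignment list."""

    matched: list[tuple[Assignment, float]]  # (assignment, detected ppm)
    unmatched_assignments: list[Assignment]
    unassigned_peaks: list[float]  # detected but not in the list ("minor")
    no_peaks: bool = False

    @property
    def matched_fraction(self) -> float:
        total = len(self.matched) + len(self.unmatched_assignments)
        return len(self.matched) / total if total else 0.0


def crop_region(trace: NMRTrace, lo_ppm: float, hi_ppm: float) -> NMRTrace:
    """Restrict a trace to lo <= ppm <= hi."""
    if not lo_ppm < hi_ppm:
        raise ValueError("crop bounds must satisfy lo < hi")
    keep = (trace.ppm >= lo_ppm) & (trace.ppm <= hi_ppm)
    if not keep.any():
        raise ValueError(
            f"crop [{lo_ppm}, {hi_ppm}] ppm does not overlap the trace "
            f"({trace.ppm[0]:.2f}-{trace.ppm[-1]:.2f} ppm)"
        )
    return replace(trace, ppm=trace.ppm[keep], intensity=trace.intensity[keep])


def normalize_trace(trace: NMRTrace) -> NMRTrace:
    """Scale so the global maximum intensity is 1."""
    peak = float(np.max(trace.intensity))
    if peak <= 0:
        raise ValueError("trace has no positive intensity to normalize")
    return replace(trace, intensity=trace.intensity / peak)


def noise_floor(trace: NMRTrace, k_mad: float = 5.0) -> float:
    """Peak-picking floor: ``k_mad`` times the median absolute deviation."""
    mad = float(np.median(np.abs(trace.intensity - np.median(trace.intensity))))
    return k_mad * mad


def pick_peaks(trace: NMRTrace, floor: float | None = None) -> np.ndarray:
    """ppm positions of local maxima above the noise floor."""
    if floor is None:
        floor = noise_floor(trace)
    idx, _ = find_peaks(trace.intensity, height=floor)
    return trace.ppm[idx]


def match_assignments(
    trace: NMRTrace,
    assignments: list[Assignment],
    tolerance_ppm: float = 0.02,
    floor: float | None = None,
) -> MatchReport:
    """Match each published assignment to its nearest detected peak.

    A peak can satisfy at most one assignment (greedy nearest match, closest
    pairs first).  Detected peaks left over are reported as minor/unassigned.
    With no peaks above the floor everything is unmatched and the report is
    flagged.
    """
    peaks = pick_peaks(trace, floor=floor)
    if peaks.size == 0:
        return MatchReport(
            matched=[],
            unmatched_assignments=list(assignments),
            unassigned_peaks=[],
            no_peaks=True,
        )
    pairs = sorted(
        (
            (abs(a.ppm - p), i, j)
            for i, a in enumerate(assignments)
            for j, p in enumerate(peaks)
        ),
    )
    used_a: set[int] = set()
    used_p: set[int] = set()
    matched: list[tuple[Assignment, float]] = []
    for dist, i, j in pairs:
        if dist > tolerance_ppm:
            break
        if i in used_a or j in used_p:
            continue
        matched.append((assignments[i], float(peaks[j])))
        used_a.add(i)
        used_p.add(j)
    unmatched = [a for i, a in enumerate(assignments) if i not in used_a]
    unassigned = [float(p) for j, p in enumerate(peaks) if j not in used_p]
    return MatchReport(matched, unmatched, unassigned)


def read_trace(path, **metadata) -> NMRTrace:
    """Read a two-column (ppm, intensity) CSV/TSV file."""
    from .cd import load_xy_columns

    ppm, inten = load_xy_columns(path)
    return NMRTrace(ppm, inten, **metadata)


def read_assignments(path) -> list[Assignment]:
    """Read an assignment CSV with columns ppm, label[, ref]."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    out = []
    for _, row in df.iterrows():
        out.append(
            Assignment(
                ppm=float(row[cols["ppm"]]),
                label=str(row[cols["label"]]),
                source=str(row[cols["ref"]]) if "ref" in cols else "",
            )
        )
    return out
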