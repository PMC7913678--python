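"""Oligonucleotide sequences, extinction coefficients and concentrations.

The molar extinction coefficient at 260 nm is computed with the
nearest-neighbor model in its traditional form,

    eps260 = sum_{i=1..N-1} eps(i, i+1) - sum_{i=2..N-1} eps(i),

where ``eps(i, i+1)`` is the whole-dinucleotide coefficient for the ordered
pair at positions i, i+1 (5'->3') and ``eps(i)`` the monomer coefficient of
the internal nucleotide at position i.  The packaged coefficient table is the
Cantor-Warshaw-Shapiro set used by oligonucleotide vendors; a user-supplied
table can override it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "DNA_ALPHABET",
    "SequenceError",
    "Oligonucleotide",
    "Topology",
    "EpsilonTable",
    "load_epsilon_table",
    "default_epsilon_table",
    "parse_sequence",
    "epsilon260",
    "concentration_from_A260",
]

DNA_ALPHABET = frozenset("ACGT")

#: Allowed stacking-type annotations (guanine stacking classes).
STACKING_TYPES = ("I", "II", "III")

#: Oligonucleotide families used for database filtering.
FAMILIES = ("human-telomeric-and-variants", "parallel", "other")

#: Expert-judgment ratings, stored verbatim and never computed.
RATINGS = ("two-star", "one-star", "cross")


class SequenceError(ValueError):
    """Raised for text that does not parse as an all-natural DNA sequence."""


def parse_sequence(text: str) -> str:
    """Normalize raw text to an uppercase 5'->3' DNA sequence.

    Whitespace is stripped; lowercase is accepted.  Any other character
    (RNA bases, modified-base codes, digits...) raises :class:`SequenceError`
    naming the offending character and its 1-based position in the stripped
    input.
    """
    stripped = "".join(text.split())
    if not stripped:
        raise SequenceError("empty sequence")
    seq = stripped.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in DNA_ALPHABET:
            raise SequenceError(
                f"invalid character {stripped[pos - 1]!r} at position {pos}: "
                "only the natural DNA bases A, C, G, T are supported"
            )
    return seq


@dataclass
class Topology:
    """Structural annotations of a resolved G-quadruplex fold."""

    strand_orientation: str | None = None
    quartet_count: int | None = None
    stacking_type: str | None = None  # "I" | "II" | "III"
    loops: str | None = None
    grooves: str | None = None

    def __post_init__(self) -> None:
        if self.quartet_count is not None and self.quartet_count not in (2, 3):
            raise ValueError(f"quartet_count must be 2 or 3, got {self.quartet_count}")
        if self.stacking_type is not None and self.stacking_type not in STACKING_TYPES:
            raise ValueError(f"stacking_type must be one of {STACKING_TYPES}")


@dataclass
class Oligonucleotide:
    """One database oligonucleotide: identity, sequence and annotations.

    ``name`` is a PDB code where a deposited structure exists, otherwise an
    internal convention name (e.g. "21G", "22AG", "HIV-PRO1").
    """

    name: str
    sequence: str
    origin: str = ""
    family: str | None = None
    topology: Topology | None = None
    rating: str | None = None
    pdb_ids: str = ""
    references: str = ""

    def __post_init__(self) -> None:
        self.sequence = parse_sequence(self.sequence)
        if self.family is not None and self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.rating is not None and self.rating not in RATINGS:
            raise ValueError(f"rating must be one of {RATINGS}, got {self.rating!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class EpsilonTable:
    """Monomer and ordered-dinucleotide coefficients at 260 nm (M^-1 cm^-1)."""

    monomer: Mapping[str, float]
    doublet: Mapping[str, float]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        missing = DNA_ALPHABET - set(self.monomer)
        if missing:
            raise ValueError(f"monomer coefficients missing for {sorted(missing)}")
        pairs = {a + b for a in DNA_ALPHABET for b in DNA_ALPHABET}
        missing = pairs - set(self.doublet)
        if missing:
            raise ValueError(f"doublet coefficients missing for {sorted(missing)}")
        for k, v in [*self.monomer.items(), *self.doublet.items()]:
            if not v > 0:
                raise ValueError(f"coefficient for {k!r} must be > 0, got {v}")


def load_epsilon_table(path: str | Path) -> EpsilonTable:
    """Load a coefficient table from the packaged key-value TSV schema.

    Lines are ``kind<TAB>key<TAB>epsilon`` with ``kind`` in
    {monomer, doublet}; ``#`` starts a comment.
    """
    monomer: dict[str, float] = {}
    doublet: dict[str, float] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        kind, key, value = parts
        if kind == "monomer":
            monomer[key] = float(value)
        elif kind == "doublet":
            doublet[key] = float(value)
        else:
            raise ValueError(f"{path}:{lineno}: unknown kind {kind!r}")
    return EpsilonTable(monomer, doublet, source=path.name)


def default_epsilon_table() -> EpsilonTable:
    """The packaged Cantor-Warshaw-Shapiro nearest-neighbor table."""
    with resources.as_file(
        resources.files("g4kit.data").joinpath("epsilon_cws260.tsv")
    ) as p:
        table = load_epsilon_table(p)
    table.source = "Cantor-Warshaw-Shapiro 1970 (packaged, epsilon_cws260.tsv)"
    return table


def epsilon260(sequence: str, table: EpsilonTable | None = None) -> float:
    """Nearest-neighbor molar extinction coefficient at 260 nm (M^-1 cm^-1).

    For a single nucleotide the nearest-neighbor sum is undefined; the monomer
    coefficient is returned and a warning issued.
    """
    seq = parse_sequence(sequence)
    if table is None:
        table = default_epsilon_table()
    if len(seq) == 1:
        warnings.warn(
            "nearest-neighbor model undefined for a single nucleotide; "
            "returning the monomer coefficient",
            stacklevel=2,
        )
        return float(table.monomer[seq])
    doublet_sum = sum(table.doublet[seq[i : i + 2]] for i in range(len(seq) - 1))
    monomer_sum = sum(table.monomer[b] for b in seq[1:-1])
    return float(doublet_sum - monomer_sum)


def concentration_from_A260(A: float, epsilon: float, path_cm: float = 1.0) -> float:
    """Beer-Lambert concentration (mol/L) from absorbance at 260 nm."""
    if not epsilon > 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    if not path_cm > 0:
        raise ValueError(f"path length must be > 0, got {path_cm}")
    if A < 0:
        raise ValueError(f"absorbance must be >= 0, got {A}")
    return A / (epsilon * path_cm)
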