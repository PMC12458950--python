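"""Semi-random barcode library design.

Models the degenerate-oligo barcode library used for lentiviral clone
labeling and the two design constraints that make clonal interpretation
valid: library diversity large enough that two cells rarely draw the same
barcode, and a multiplicity of infection (MOI) low enough that cells
carrying more than one barcode are rare.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IUPAC_EXPANSION",
    "BarcodePattern",
    "LibrarySpec",
    "pattern_space_size",
    "sample_library",
    "multi_integration_fraction",
    "expected_barcode_collisions",
    "default_barcode_pattern",
]

# IUPAC nucleotide ambiguity codes -> the set of concrete bases each matches.
IUPAC_EXPANSION: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class BarcodePattern:
    """A degenerate nucleotide pattern over IUPAC codes.

    Lowercase input is accepted and upper-cased (oligo order sheets are
    inconsistent about case). Invalid characters are rejected with their
    position reported.
    """

    template: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "template", self.template.upper())
        if not self.template:
            raise ValueError("empty barcode pattern")
        for i, ch in enumerate(self.template):
            if ch not in IUPAC_EXPANSION:
                raise ValueError(
                    f"invalid IUPAC code {ch!r} at position {i} in pattern"
                )

    def __len__(self) -> int:
        return len(self.template)

    @property
    def degeneracies(self) -> list[int]:
        return [len(IUPAC_EXPANSION[c]) for c in self.template]

    def matches(self, sequence: str) -> bool:
        """True iff ``sequence`` is one concrete realization of the pattern."""
        if len(sequence) != len(self.template):
            return False
        return all(
            b in IUPAC_EXPANSION[c] for b, c in zip(sequence.upper(), self.template)
        )


def default_barcode_pattern(length: int = 265, unit: str = "NWSN") -> BarcodePattern:
    """Repeat ``unit`` and truncate/extend to ``length``.

    A configurable stand-in for the proprietary semi-random repeat design of
    the 265-nt transcribed barcode; the exact commercial oligo pattern is not
    modelled.
    """
    if length < 1:
        raise ValueError("length must be positive")
    reps = unit * (length // len(unit) + 1)
    return BarcodePattern(reps[:length])


@dataclass(frozen=True)
class LibrarySpec:
    """A barcode library: a pattern, a realized diversity, and the MOI."""

    pattern: BarcodePattern
    size: int
    moi: float

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("library size must be >= 1")
        if self.size > pattern_space_size(self.pattern):
            raise ValueError("library size exceeds pattern space")
        if self.moi <= 0:
            raise ValueError("moi must be > 0")


def pattern_space_size(pattern: BarcodePattern | str) -> int:
    """Number of distinct concrete sequences matching the pattern.

    Exact integer arithmetic (Python ints), so arbitrarily long patterns do
    not overflow.
    """
    if isinstance(pattern, str):
        pattern = BarcodePattern(pattern)
    size = 1
    for d in pattern.degeneracies:
        size *= d
    return size


def sample_library(
    pattern: BarcodePattern | str, n: int, seed: int
) -> list[str]:
    """Draw ``n`` distinct barcodes uniformly from the pattern space.

    Positional sampling (each degenerate position drawn independently) is
    exactly uniform over the space; uniqueness is enforced by a retry loop
    capped at 100*n attempts, which only matters when ``n`` approaches the
    space size. Returns a sorted list; same seed -> identical output.
    """
    if isinstance(pattern, str):
        pattern = BarcodePattern(pattern)
    space = pattern_space_size(pattern)
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > space:
        raise ValueError(f"requested {n} barcodes from a space of {space}")
    rng = np.random.default_rng(seed)
    choices = [IUPAC_EXPANSION[c] for c in pattern.template]
    # Exhaustive request: enumerate instead of rejection-sampling the tail.
    if n == space:
        seqs = [""]
        for opts in choices:
            seqs = [s + b for s in seqs for b in opts]
        return sorted(seqs)
    out: set[str] = set()
    attempts = 0
    max_attempts = 100 * max(n, 1)
    while len(out) < n:
        if attempts >= max_attempts:
            raise RuntimeError("uniqueness retry budget exhausted")
        attempts += 1
        out.add("".join(opts[rng.integers(len(opts))] for opts in choices))
    return sorted(out)


def multi_integration_fraction(moi: float) -> float:
    """P(a barcoded cell carries >= 2 integrations) at the given MOI.

    Integrations per cell are Poisson(moi); conditioning on the cell being
    barcoded at all (K >= 1):

        P(K >= 2 | K >= 1) = (1 - e^-m (1 + m)) / (1 - e^-m)

    Monotone increasing in ``moi`` and -> 0 as moi -> 0, which is why
    libraries are transduced at low MOI.
    """
    if moi <= 0:
        raise ValueError("moi must be > 0")
    em = math.exp(-moi)
    return (1.0 - em * (1.0 + moi)) / (1.0 - em)


def expected_barcode_collisions(library_size: int, n_cells: int) -> float:
    """Expected number of cells sharing their barcode with another cell.

    Cells draw barcodes uniformly with replacement from ``library_size``
    distinct sequences; a cell "collides" when at least one other cell drew
    the same barcode:

        E = n_cells * (1 - (1 - 1/library_size)^(n_cells - 1))
    """
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells <= 1:
        return 0.0
    return n_cells * (1.0 - (1.0 - 1.0 / library_size) ** (n_cells - 1))
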