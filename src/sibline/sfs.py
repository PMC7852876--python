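"""The unfolded site frequency spectrum (SFS) of two diploid full sibs.

Segregating sites in a line maintained at two individuals (A and B) fall into
seven joint-genotype configurations, named by the four allele "slots"
(A's pair then B's pair, ``R`` = reference, ``A`` = alternative)::

    RARR  one alt copy,   A heterozygous
    RRRA  one alt copy,   B heterozygous
    RARA  two alt copies, both heterozygous
    AARR  two alt copies, A homozygous alternative
    RRAA  two alt copies, B homozygous alternative
    AARA  three alt copies, B heterozygous
    RAAA  three alt copies, A heterozygous

The monomorphic configurations (0 or 4 alternative copies) are not SFS
elements.  :class:`SFSVector` holds one count per element, in the fixed
order above; counts are real-valued so the same container can carry
expected (fractional) spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

ELEMENTS: tuple[str, ...] = ("RARR", "RRRA", "RARA", "AARR", "RRAA", "AARA", "RAAA")

#: alt-copy counts (individual A, individual B) per element
ELEMENT_COPIES: dict[str, tuple[int, int]] = {
    "RARR": (1, 0),
    "RRRA": (0, 1),
    "RARA": (1, 1),
    "AARR": (2, 0),
    "RRAA": (0, 2),
    "AARA": (2, 1),
    "RAAA": (1, 2),
}

COPIES_TO_ELEMENT: dict[tuple[int, int], str] = {v: k for k, v in ELEMENT_COPIES.items()}

LOSS: tuple[int, int] = (0, 0)
FIXATION: tuple[int, int] = (2, 2)

#: elements in which individual A (resp. B) carries at least one alt copy
A_CARRIER_ELEMENTS = frozenset(e for e, (a, b) in ELEMENT_COPIES.items() if a >= 1)
B_CARRIER_ELEMENTS = frozenset(e for e, (a, b) in ELEMENT_COPIES.items() if b >= 1)


def classify_pair(alt_copies_a: int, alt_copies_b: int) -> str | None:
    """Map the pair of alt-copy counts to an SFS element label.

    Returns ``None`` for the monomorphic configurations (0,0) and (2,2).
    Raises :class:`ValueError` for counts outside 0..2.
    """
    key = (alt_copies_a, alt_copies_b)
    if key in (LOSS, FIXATION):
        return None
    try:
        return COPIES_TO_ELEMENT[key]
    except KeyError:
        raise ValueError(f"not a diploid-pair configuration: {key!r}") from None


@dataclass
class SFSVector:
    """Counts of segregating sites per SFS element (fixed element order)."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(len(ELEMENTS)))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(ELEMENTS),):
            raise ValueError(f"expected {len(ELEMENTS)} counts, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be non-negative")

    @classmethod
    def zeros(cls) -> "SFSVector":
        return cls(np.zeros(len(ELEMENTS)))

    @classmethod
    def from_dict(cls, counts: Mapping[str, float]) -> "SFSVector":
        unknown = set(counts) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"unknown SFS elements: {sorted(unknown)}")
        return cls(np.array([float(counts.get(e, 0.0)) for e in ELEMENTS]))

    @classmethod
    def from_elements(cls, elements: Iterable[str]) -> "SFSVector":
        """Tally an iterable of element labels into a spectrum."""
        arr = np.zeros(len(ELEMENTS))
        idx = {e: i for i, e in enumerate(ELEMENTS)}
        for e in elements:
            arr[idx[e]] += 1
        return cls(arr)

    def __getitem__(self, element: str) -> float:
        return float(self.counts[ELEMENTS.index(element)])

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def proportions(self) -> np.ndarray:
        """Counts normalised to sum one; all-NaN if the spectrum is empty."""
        tot = self.counts.sum()
        if tot == 0:
            return np.full(len(ELEMENTS), np.nan)
        return self.counts / tot

    def as_dict(self) -> dict[str, float]:
        return {e: float(c) for e, c in zip(ELEMENTS, self.counts)}

    def drop(self, excluded: Iterable[str]) -> tuple[np.ndarray, list[str]]:
        """Return (counts, labels) with the given elements removed."""
        excluded = set(excluded)
        unknown = excluded - set(ELEMENTS)
        if unknown:
            raise ValueError(f"unknown SFS elements: {sorted(unknown)}")
        kept = [e for e in ELEMENTS if e not in excluded]
        if not kept:
            raise ValueError("all SFS elements excluded")
        return np.array([self[e] for e in kept]), kept

    def __add__(self, other: "SFSVector") -> "SFSVector":
        return SFSVector(self.counts + other.counts)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("element\tcount\n")
            for e, c in zip(ELEMENTS, self.counts):
                fh.write(f"{e}\t{c:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SFSVector":
        counts: dict[str, float] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("element"):
                raise ValueError(f"{path}: expected an 'element<TAB>count' table")
            for line in fh:
                if not line.strip():
                    continue
                e, c = line.rstrip("\n").split("\t")[:2]
                counts[e] = float(c)
        return cls.from_dict(counts)
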