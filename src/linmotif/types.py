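"""Core domain types shared across the package.

The central objects are fixed-width aligned peptide windows
(:class:`SequenceWindow` / :class:`SequenceSet`), positional residue
candidates (:class:`PositionalPair`), and extracted motifs
(:class:`Motif`).  Window columns are addressed by *offset* relative to
the central (modified) position: ``-(w-1)/2 .. +(w-1)/2`` for an odd
window width ``w``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

#: The 20 standard amino acids, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity placeholder (normalized from X/U/B/Z/O/J/*).
UNKNOWN = "X"
#: Terminal padding character.
GAP = "-"

#: Integer codes: 0..19 standard residues, 20 = X, 21 = '-'.
_CODE_X = 20
_CODE_GAP = 21
_N_CODES = 22

_LUT = np.full(128, -1, dtype=np.int8)
for _i, _aa in enumerate(STANDARD_AA):
    _LUT[ord(_aa)] = _i
_LUT[ord(UNKNOWN)] = _CODE_X
_LUT[ord(GAP)] = _CODE_GAP

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


def encode_sequences(sequences: Sequence[str], width: int) -> np.ndarray:
    """Encode equal-width residue strings into an (n, width) int8 matrix."""
    if not sequences:
        return np.empty((0, width), dtype=np.int8)
    buf = "".join(sequences).encode("ascii")
    arr = np.frombuffer(buf, dtype=np.uint8).reshape(len(sequences), width)
    codes = _LUT[arr]
    # unmapped characters (nonstandard residue codes) count as ambiguous
    return np.where(codes < 0, np.int8(_CODE_X), codes)


@dataclass(slots=True)
class SequenceWindow:
    """One fixed-width aligned window around a (putatively) modified site.

    ``residues`` is a string over the 20 standard amino acids plus ``X``
    (ambiguous) and ``-`` (terminal padding, contiguous prefix/suffix only).
    """

    residues: str
    sample_label: Optional[str] = None
    source: Optional[tuple[str, int, str]] = None  # (accession, 1-based pos, modification)
    intensity: Optional[float] = None

    def reversed(self) -> "SequenceWindow":
        return SequenceWindow(
            residues=self.residues[::-1],
            sample_label=self.sample_label,
            source=self.source,
            intensity=self.intensity,
        )


class SequenceSet:
    """A collection of equal-width aligned windows.

    Parameters
    ----------
    windows:
        The member windows; all must share the same odd width.
    width:
        Window width; inferred from the first window when omitted.
    """

    def __init__(self, windows: Iterable[SequenceWindow], width: Optional[int] = None):
        self.windows: list[SequenceWindow] = list(windows)
        if width is None:
            if not self.windows:
                raise ValueError("width must be given for an empty SequenceSet")
            width = len(self.windows[0].residues)
        if width < 1 or width % 2 == 0:
            raise ValueError(f"window width must be odd and positive, got {width}")
        self.width = width
        for i, win in enumerate(self.windows):
            if len(win.residues) != width:
                raise ValueError(
                    f"window {i} has width {len(win.residues)}, expected {width}"
                )
        self._encoded: Optional[np.ndarray] = None

    @property
    def central_index(self) -> int:
        return (self.width - 1) // 2

    @property
    def offsets(self) -> range:
        h = self.central_index
        return range(-h, h + 1)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def sequences(self) -> list[str]:
        return [w.residues for w in self.windows]

    def encoded(self) -> np.ndarray:
        """Integer-coded (n, width) matrix; cached (the set is treated as immutable)."""
        if self._encoded is None:
            self._encoded = encode_sequences(self.sequences(), self.width)
        return self._encoded

    def subset(self, indices: Sequence[int]) -> "SequenceSet":
        sub = SequenceSet([self.windows[i] for i in indices], width=self.width)
        enc = self.encoded()
        sub._encoded = enc[np.asarray(indices, dtype=np.intp)]
        return sub

    def reversed(self) -> "SequenceSet":
        return SequenceSet([w.reversed() for w in self.windows], width=self.width)


@dataclass(frozen=True, slots=True)
class SiteRecord:
    """A modified site on a protein: accession, 1-based position, modification."""

    protein_accession: str
    position: int
    modification: str
    expected_residue: Optional[str] = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class CompoundGroup:
    """A named set of >= 2 residues sharing a physicochemical property."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError(f"compound group {self.name!r} needs >= 2 members")
        bad = set(self.members) - set(STANDARD_AA)
        if bad:
            raise ValueError(f"compound group {self.name!r} has non-standard members {bad}")
        if self.name in STANDARD_AA and len(self.name) == 1:
            raise ValueError("compound group name may not shadow a residue token")


@dataclass(frozen=True)
class PositionalPair:
    """A (position offset, residue-or-group) candidate for fixation.

    ``members`` carries the matched residue set: a singleton for a plain
    residue token, the full member set for a compound group.  This makes
    pairs self-contained for matching and serialization.
    """

    offset: int
    token: str
    members: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.members is None:
            object.__setattr__(self, "members", frozenset(self.token))

    @property
    def is_group(self) -> bool:
        return len(self.members) > 1

    def display(self) -> str:
        if self.is_group:
            return f"[{''.join(sorted(self.members))}]@{self.offset:+d}"
        return f"{self.token}@{self.offset:+d}"


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """Binomial statistics for one positional pair in one scan.

    ``k`` matches out of ``n`` foreground windows with a counted residue at
    that position, against background probability ``p0``; ``m`` is the
    number of tests in the scan (Bonferroni family size).
    """

    pair: PositionalPair
    k: int
    n: int
    p0: float
    p: float
    m: int
    significant: bool


@dataclass(frozen=True)
class Motif:
    """A set of fixed positional pairs with its supporting windows.

    ``support`` is the number of foreground windows exactly matching every
    fixed pair; ``complexity_class`` is ``"I"`` (central + flanking),
    ``"II"`` (central only) or ``"III"`` (flanking only).
    """

    pairs: tuple[PositionalPair, ...]
    support: int
    matched_ids: frozenset[int]
    pattern: str
    complexity_class: str
    trail: tuple[EnrichmentResult, ...] = ()

    @property
    def key(self) -> frozenset[PositionalPair]:
        """Identity of the motif: its fixed-pair set."""
        return frozenset(self.pairs)

    def offsets(self) -> set[int]:
        return {p.offset for p in self.pairs}


def render_pattern(pairs: Iterable[PositionalPair], width: int) -> str:
    """Dot-notation pattern string, e.g. ``D......S.......`` for width 15."""
    h = (width - 1) // 2
    cols = ["."] * width
    for pair in pairs:
        col = pair.offset + h
        if not 0 <= col < width:
            raise ValueError(f"offset {pair.offset} outside window of width {width}")
        cols[col] = f"[{''.join(sorted(pair.members))}]" if pair.is_group else pair.token
    return "".join(cols)
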