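"""Statistical background construction, querying and recursive reduction.

The background defines the null residue frequencies against which
foreground enrichment is tested.  It is built either from a proteome (one
window per residue position, terminal positions padded with ``-``,
optionally restricted to a given central residue) or directly from a set
of pre-aligned windows.  During motif recursion the background is
*recompiled*: restricted to the windows matching the already-fixed
positional pairs, so that the statistics of each subset are measured
against a commensurate null.

Padded ``-`` cells and ambiguous ``X`` cells are excluded from both the
numerator and the denominator of every frequency.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .types import (
    AA_INDEX,
    GAP,
    STANDARD_AA,
    PositionalPair,
    SequenceSet,
    encode_sequences,
)

_N_AA = len(STANDARD_AA)


class BackgroundExhausted(RuntimeError):
    """Raised when a reduced background contains no windows.

    The caller terminates that recursion branch.
    """


class BackgroundModel:
    """Position-specific and pooled residue counts over background windows.

    Attributes
    ----------
    width:
        Window width ``w`` (odd).
    counts:
        ``(w, 20)`` integer matrix of per-position residue counts
        (standard residues only).
    totals:
        Per-position number of counted residues (``counts.sum(axis=1)``).
    pooled_counts / pooled_total:
        Counts summed over positions.
    central_residue_filter:
        The central-residue restriction used at construction, if any.
    fixed_prefix:
        The positional pairs this background has been reduced on.
    """

    def __init__(
        self,
        windows: Sequence[str],
        width: int,
        central_residue_filter: Optional[str] = None,
        fixed_prefix: tuple[PositionalPair, ...] = (),
    ):
        if width < 1 or width % 2 == 0:
            raise ValueError(f"width must be odd and positive, got {width}")
        if len(windows) == 0:
            raise BackgroundExhausted("background contains no windows")
        self.width = width
        self.windows = list(windows)
        self.central_residue_filter = central_residue_filter
        self.fixed_prefix = tuple(fixed_prefix)
        self._encoded = encode_sequences(self.windows, width)
        self.n_sequences = len(self.windows)
        counts = np.zeros((width, _N_AA), dtype=np.int64)
        for col in range(width):
            binc = np.bincount(self._encoded[:, col], minlength=22)
            counts[col] = binc[:_N_AA]
        self.counts = counts
        self.totals = counts.sum(axis=1)
        self.pooled_counts = counts.sum(axis=0)
        self.pooled_total = int(self.pooled_counts.sum())

    # -- construction -------------------------------------------------

    @classmethod
    def from_windows(
        cls,
        windows: Union[SequenceSet, Iterable[str]],
        central_residue: Optional[str] = None,
    ) -> "BackgroundModel":
        if isinstance(windows, SequenceSet):
            width = windows.width
            seqs = windows.sequences()
        else:
            seqs = list(windows)
            if not seqs:
                raise BackgroundExhausted("background contains no windows")
            width = len(seqs[0])
        if central_residue is not None:
            c = (width - 1) // 2
            seqs = [s for s in seqs if s[c] == central_residue]
            if not seqs:
                raise BackgroundExhausted(
                    f"no background window has central residue {central_residue!r}"
                )
        return cls(seqs, width, central_residue_filter=central_residue)

    @classmethod
    def from_proteome(
        cls,
        proteome: Union[dict[str, str], Iterable[str]],
        width: int,
        central_residue: Optional[str] = None,
    ) -> "BackgroundModel":
        """Enumerate one window per residue position of every protein.

        Terminal positions are ``-``-padded so that each residue is a
        potential window center; with ``central_residue`` set, enumeration
        is restricted to centers equal to that residue.
        """
        seqs = (
            list(proteome.values()) if isinstance(proteome, dict) else list(proteome)
        )
        windows = enumerate_windows(seqs, width, central_residue)
        if not windows:
            raise BackgroundExhausted(
                f"no background window found (central residue {central_residue!r})"
            )
        return cls(windows, width, central_residue_filter=central_residue)

    # -- queries ------------------------------------------------------

    def frequency(
        self,
        offset: int,
        token: Union[str, PositionalPair, frozenset, set],
        position_specific: bool = True,
    ) -> float:
        """Background probability of the token (residue or group) at an offset.

        For a compound group the frequency is the sum over its (disjoint)
        member residues.  A token absent from the background has frequency 0.
        """
        members = _token_members(token)
        h = (self.width - 1) // 2
        if not -h <= offset <= h:
            raise ValueError(f"offset {offset} outside window of width {self.width}")
        idx = [AA_INDEX[m] for m in members]
        if position_specific:
            col = offset + h
            total = self.totals[col]
            if total == 0:
                return 0.0
            return float(self.counts[col, idx].sum() / total)
        if self.pooled_total == 0:
            return 0.0
        return float(self.pooled_counts[idx].sum() / self.pooled_total)

    def frequency_matrix(self, position_specific: bool = True) -> np.ndarray:
        """``(w, 20)`` matrix of per-position residue probabilities."""
        if position_specific:
            with np.errstate(invalid="ignore", divide="ignore"):
                freq = self.counts / np.where(self.totals[:, None] == 0, 1, self.totals[:, None])
            return freq
        if self.pooled_total == 0:
            return np.zeros_like(self.counts, dtype=float)
        pooled = self.pooled_counts / self.pooled_total
        return np.tile(pooled, (self.width, 1))

    # -- reduction ----------------------------------------------------

    def reduce(self, fixed_pairs: Sequence[PositionalPair]) -> "BackgroundModel":
        """Recompile the background from windows matching every fixed pair."""
        if not fixed_pairs:
            return self
        offsets = [p.offset for p in fixed_pairs]
        if len(set(offsets)) != len(offsets):
            raise ValueError("fixed pairs must have unique offsets")
        h = (self.width - 1) // 2
        mask = np.ones(self.n_sequences, dtype=bool)
        for pair in fixed_pairs:
            col = pair.offset + h
            codes = [AA_INDEX[m] for m in pair.members]
            mask &= np.isin(self._encoded[:, col], codes)
        kept = [self.windows[i] for i in np.flatnonzero(mask)]
        if not kept:
            raise BackgroundExhausted(
                f"background exhausted after fixing {[p.display() for p in fixed_pairs]}"
            )
        return BackgroundModel(
            kept,
            self.width,
            central_residue_filter=self.central_residue_filter,
            fixed_prefix=self.fixed_prefix + tuple(fixed_pairs),
        )

    def reversed(self) -> "BackgroundModel":
        """Background over character-reversed windows (for reversal checks)."""
        return BackgroundModel(
            [w[::-1] for w in self.windows],
            self.width,
            central_residue_filter=self.central_residue_filter,
        )


def _token_members(token) -> frozenset:
    if isinstance(token, PositionalPair):
        return token.members
    if isinstance(token, str):
        if len(token) != 1 or token not in STANDARD_AA:
            raise ValueError(f"unknown residue token {token!r}")
        return frozenset(token)
    return frozenset(token)


def enumerate_windows(
    sequences: Iterable[str], width: int, central_residue: Optional[str] = None
) -> list[str]:
    """All length-``width`` windows of the sequences, one per residue position.

    Windows at the termini are padded with ``-``.  Used both for background
    compilation and as the sampling pool for null experiments.
    """
    h = (width - 1) // 2
    pad = GAP * h
    out: list[str] = []
    for seq in sequences:
        s = pad + seq.upper() + pad
        for center in range(len(seq)):
            if central_residue is not None and seq[center].upper() != central_residue:
                continue
            out.append(s[center : center + width])
    return out


def build_background(
    source,
    width: int,
    central_residue: Optional[str] = None,
) -> BackgroundModel:
    """Build a background from a proteome mapping/list or pre-aligned windows.

    ``source`` may be a ``{accession: sequence}`` dict (or plain list of
    protein sequences), or a :class:`SequenceSet` of pre-aligned windows.
    """
    if isinstance(source, SequenceSet):
        if source.width != width:
            raise ValueError(
                f"background windows have width {source.width}, expected {width}"
            )
        return BackgroundModel.from_windows(source, central_residue)
    return BackgroundModel.from_proteome(source, width, central_residue)
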