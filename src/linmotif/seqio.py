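"""Input/output: pre-aligned window files, FASTA proteomes, site tables,
window extraction and the pre-processing filters applied before motif
deconvolution.

Conventions
-----------
* Site positions are 1-based (proteomics convention); window offsets are
  relative to the central column, ``-(w-1)/2 .. +(w-1)/2``.
* Input is case-insensitive; the canonical form is uppercase.
* Nonstandard residue codes (``U B Z O J *``) are normalized to ``X`` and
  excluded from all frequency counts, as is terminal ``-`` padding.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

import pandas as pd
from Bio import SeqIO

from .types import (
    GAP,
    STANDARD_AA,
    UNKNOWN,
    CompoundGroup,
    Motif,
    PositionalPair,
    SequenceSet,
    SequenceWindow,
    SiteRecord,
    render_pattern,
)

_NONSTANDARD = set("UBZOJ*")
_VALID = set(STANDARD_AA) | {UNKNOWN, GAP}


class ParseError(ValueError):
    """Malformed input file (wrong width, illegal character, bad field)."""


def normalize_residues(seq: str) -> str:
    """Uppercase and map nonstandard residue codes to ``X``.

    Raises :class:`ParseError` on characters that are not amino acids,
    ``X`` or terminal ``-`` padding.
    """
    up = seq.upper()
    out = []
    for ch in up:
        if ch in _NONSTANDARD:
            out.append(UNKNOWN)
        elif ch in _VALID:
            out.append(ch)
        else:
            raise ParseError(f"illegal residue character {ch!r} in sequence {seq!r}")
    norm = "".join(out)
    _check_terminal_padding(norm)
    return norm


def _check_terminal_padding(seq: str) -> None:
    core = seq.strip(GAP)
    if GAP in core:
        raise ParseError(f"'-' padding must be terminal, got {seq!r}")


def read_prealigned(
    path: Union[str, Path, TextIO], expected_width: Optional[int] = None
) -> SequenceSet:
    """Read a pre-aligned window file.

    Each non-empty line is ``SEQ``, ``LABEL<TAB>SEQ`` or
    ``LABEL<TAB>SEQ<TAB>INTENSITY``.  All windows must share one width;
    a mismatch is a hard error naming the offending line.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    windows: list[SequenceWindow] = []
    width = expected_width
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        label: Optional[str] = None
        intensity: Optional[float] = None
        if len(fields) == 1:
            seq = fields[0].strip()
        elif len(fields) == 2:
            label, seq = fields[0].strip(), fields[1].strip()
        elif len(fields) == 3:
            label, seq = fields[0].strip(), fields[1].strip()
            try:
                intensity = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"bad intensity at line {lineno}: {fields[2]!r}") from exc
            if intensity < 0:
                raise ParseError(f"negative intensity at line {lineno}")
        else:
            raise ParseError(f"too many fields at line {lineno}")
        try:
            seq = normalize_residues(seq)
        except ParseError as exc:
            raise ParseError(f"{exc} (line {lineno})") from None
        if width is None:
            width = len(seq)
        elif len(seq) != width:
            raise ParseError(
                f"inconsistent width at line {lineno}: got {len(seq)}, expected {width}"
            )
        windows.append(SequenceWindow(seq, sample_label=label, intensity=intensity))
    if width is None:
        raise ParseError("no sequences found")
    return SequenceSet(windows, width=width)


def write_prealigned(seqs: SequenceSet, path: Union[str, Path]) -> None:
    """Write a SequenceSet back to the pre-aligned text dialect."""
    with open(path, "w") as fh:
        for w in seqs:
            if w.intensity is not None:
                fh.write(f"{w.sample_label or ''}\t{w.residues}\t{w.intensity:g}\n")
            elif w.sample_label is not None:
                fh.write(f"{w.sample_label}\t{w.residues}\n")
            else:
                fh.write(f"{w.residues}\n")


def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read a FASTA proteome into ``{accession: sequence}``.

    UniProt-style ``db|ACC|NAME`` ids are additionally indexed by the bare
    accession, first exact match winning.
    """
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id not in proteome:
            proteome[rec.id] = seq
        parts = rec.id.split("|")
        if len(parts) >= 3 and parts[1] and parts[1] not in proteome:
            proteome[parts[1]] = seq
    if not proteome:
        raise ParseError(f"no FASTA records in {path}")
    return proteome


def read_site_table(path: Union[str, Path]) -> list[SiteRecord]:
    """Read a TSV site table: accession, position, modification[, residue]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    try:
        acc_c = cols["accession"]
        pos_c = cols["position"]
        mod_c = cols["modification"]
    except KeyError as exc:
        raise ParseError(f"site table missing required column: {exc}") from None
    res_c = cols.get("residue")
    records = []
    for _, row in df.iterrows():
        residue = None
        if res_c is not None and pd.notna(row[res_c]):
            residue = str(row[res_c]).strip().upper() or None
        records.append(
            SiteRecord(
                protein_accession=str(row[acc_c]).strip(),
                position=int(row[pos_c]),
                modification=str(row[mod_c]).strip(),
                expected_residue=residue,
            )
        )
    return records


def extract_window(
    protein_sequence: str, site: SiteRecord, width: int
) -> Optional[SequenceWindow]:
    """Extract the width-``w`` window centered on a 1-based site position.

    Positions beyond the protein termini are padded with ``-``.  Returns
    ``None`` (a rejection, not an error) when ``expected_residue`` is set
    and disagrees with the protein residue at the site; raises for an
    out-of-range position.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError(f"width must be odd and positive, got {width}")
    seq = protein_sequence.upper()
    n = len(seq)
    pos0 = site.position - 1
    if not 0 <= pos0 < n:
        raise ValueError(
            f"site position {site.position} out of range for protein of length {n}"
        )
    if site.expected_residue is not None and seq[pos0] != site.expected_residue.upper():
        return None
    h = (width - 1) // 2
    lo, hi = pos0 - h, pos0 + h + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - n)
    core = seq[max(lo, 0) : min(hi, n)]
    residues = GAP * left_pad + normalize_residues(core) + GAP * right_pad
    return SequenceWindow(
        residues,
        source=(site.protein_accession, site.position, site.modification),
    )


@dataclass
class ExtractionReport:
    """Bookkeeping from batch window extraction."""

    extracted: int = 0
    rejected_mismatch: int = 0
    unmapped: int = 0
    out_of_range: int = 0
    unmapped_accessions: list[str] = field(default_factory=list)


def extract_windows(
    proteome: dict[str, str],
    sites: Iterable[SiteRecord],
    width: int,
) -> tuple[SequenceSet, ExtractionReport]:
    """Extract windows for a batch of sites, counting rejections.

    Sites whose accession is absent from the proteome are reported as
    unmapped; expected-residue mismatches are counted as rejections.
    """
    report = ExtractionReport()
    windows: list[SequenceWindow] = []
    for site in sites:
        seq = proteome.get(site.protein_accession)
        if seq is None:
            report.unmapped += 1
            report.unmapped_accessions.append(site.protein_accession)
            continue
        try:
            win = extract_window(seq, site, width)
        except ValueError:
            report.out_of_range += 1
            continue
        if win is None:
            report.rejected_mismatch += 1
            continue
        windows.append(win)
        report.extracted += 1
    return SequenceSet(windows, width=width), report


def dedup_sites(sites: list[SiteRecord]) -> list[SiteRecord]:
    """Collapse exact duplicates on (accession, position, modification).

    Records differing in any of the three keys are all retained; the first
    occurrence order is preserved.  Idempotent.
    """
    seen: set[tuple[str, int, str]] = set()
    out = []
    for s in sites:
        key = (s.protein_accession, s.position, s.modification)
        if key in seen:
            continue
        seen.add(key)
        out.append(s)
    return out


def filter_min_occurrence(
    sites_by_modification: dict[str, list], min_n: int = 50
) -> dict[str, list]:
    """Drop modifications with fewer than ``min_n`` sites (default 50)."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    return {mod: s for mod, s in sites_by_modification.items() if len(s) >= min_n}


def dedup_sequences(seqs: SequenceSet) -> SequenceSet:
    """Eliminate redundancy at the plain-sequence level (first copy kept)."""
    seen: set[str] = set()
    keep = []
    for w in seqs:
        if w.residues in seen:
            continue
        seen.add(w.residues)
        keep.append(w)
    return SequenceSet(keep, width=seqs.width)


_MOTIF_COLUMNS = ["pattern", "fixed_pairs", "support", "class", "pair_pvalues", "matched_count"]


def _serialize_pair(pair: PositionalPair) -> str:
    if pair.is_group:
        return f"{pair.token}={''.join(sorted(pair.members))}@{pair.offset:+d}"
    return f"{pair.token}@{pair.offset:+d}"


def _parse_pair(text: str) -> PositionalPair:
    head, offset = text.rsplit("@", 1)
    if "=" in head:
        name, members = head.split("=", 1)
        return PositionalPair(int(offset), name, frozenset(members))
    return PositionalPair(int(offset), head)


def write_motif_table(motifs: list[Motif], path: Union[str, Path]) -> None:
    """Write motifs as a TSV: pattern, fixed pairs, support, class, p-values.

    Rows in (support descending, pattern lexicographic) order, matching the
    engine's deterministic output order.
    """
    rows = sorted(motifs, key=lambda m: (-m.support, m.pattern))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MOTIF_COLUMNS)
        for m in rows:
            pairs = sorted(m.pairs, key=lambda p: p.offset)
            writer.writerow(
                [
                    m.pattern,
                    ";".join(_serialize_pair(p) for p in pairs),
                    m.support,
                    m.complexity_class,
                    ";".join(f"{r.p:.6e}" for r in sorted(m.trail, key=lambda r: r.pair.offset)),
                    len(m.matched_ids),
                ]
            )


def read_motif_table(path: Union[str, Path], width: Optional[int] = None) -> list[Motif]:
    """Read back a motif TSV written by :func:`write_motif_table`.

    The per-window matched-id sets are not recoverable from the table; the
    matched count is restored as an anonymous id range.
    """
    from .engine import classify_pairs  # local import avoids a cycle

    motifs = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pairs = tuple(
                sorted(
                    (_parse_pair(t) for t in row["fixed_pairs"].split(";") if t),
                    key=lambda p: p.offset,
                )
            )
            pattern = row["pattern"]
            w = width if width is not None else _pattern_width(pattern)
            pvals = [float(x) for x in row["pair_pvalues"].split(";") if x]
            trail = tuple(
                # reconstructed stubs: only p survives serialization
                _stub_result(pair, p)
                for pair, p in zip(sorted(pairs, key=lambda q: q.offset), pvals)
            )
            motifs.append(
                Motif(
                    pairs=pairs,
                    support=int(row["support"]),
                    matched_ids=frozenset(range(int(row["matched_count"]))),
                    pattern=render_pattern(pairs, w),
                    complexity_class=classify_pairs(pairs),
                    trail=trail,
                )
            )
    return motifs


def _stub_result(pair, p):
    from .types import EnrichmentResult

    return EnrichmentResult(pair=pair, k=0, n=0, p0=0.0, p=p, m=0, significant=True)


def _pattern_width(pattern: str) -> int:
    w = 0
    in_group = False
    for ch in pattern:
        if ch == "[":
            in_group = True
            w += 1
        elif ch == "]":
            in_group = False
        elif not in_group:
            w += 1
    return w


def read_compound_groups(path: Union[str, Path]) -> list[CompoundGroup]:
    """Read compound residue groups, one per line, ``name:RESIDUES``."""
    groups = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ParseError(f"bad group definition at line {lineno}: {line!r}")
        name, members = line.split(":", 1)
        groups.append(CompoundGroup(name.strip(), frozenset(members.strip().upper())))
    return groups
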