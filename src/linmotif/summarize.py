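"""Post-extraction analytics.

Cross-sample comparison works by matching every sequence of every
sample/modification group against a single non-redundant motif list,
testing each match count against its expected probability under the
background, masking non-significant cells, and converting the significant
counts to percentages of the group size.  Further summaries: positional
load (how often each window position is fixed by a group's motifs),
fixed-residue composition differentials between modification types,
intensity aggregation, and the ln(x+1)/center/scale transform plus
average-linkage ordering used before heatmap rendering.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .background import BackgroundModel
from .engine import binomial_pvalue, matches_window
from .types import Motif, SequenceSet, SequenceWindow


def matches(window: SequenceWindow, motif: Motif) -> bool:
    """True iff the window residue at every fixed offset equals the token
    (or belongs to the group); '-' and X never match."""
    return matches_window(window.residues, motif.pairs, len(window.residues))


def dedup_motifs(motifs: Sequence[Motif]) -> list[Motif]:
    """Non-redundant motif list: one representative per fixed-pair set,
    first occurrence kept."""
    seen = set()
    out = []
    for m in motifs:
        if m.key in seen:
            continue
        seen.add(m.key)
        out.append(m)
    return out


@dataclass
class PatternMatchMatrix:
    """Motifs x groups exact-match counts with significance-masked percentages.

    ``percent`` holds ``100 * count / group_size`` where the count is
    significantly over-represented (Bonferroni over motifs x groups), NaN
    elsewhere.
    """

    motifs: list[Motif]
    groups: list[str]
    counts: pd.DataFrame
    pvalues: pd.DataFrame
    percent: pd.DataFrame
    group_sizes: pd.Series
    alpha: float
    n_tests: int


def expected_match_probability(
    motif: Motif, bg: BackgroundModel, position_specific: bool = True
) -> float:
    """Null probability of matching all fixed pairs: the product of the
    per-offset background frequencies (positional independence)."""
    p = 1.0
    for pair in motif.pairs:
        p *= bg.frequency(pair.offset, pair.members, position_specific)
    return p


def build_match_matrix(
    motifs: Sequence[Motif],
    grouped_sets: dict[str, SequenceSet],
    bg: BackgroundModel,
    alpha: float = 0.001,
    position_specific: bool = True,
) -> PatternMatchMatrix:
    """Count exact matches of each motif in each group and keep the
    significantly over-represented cells as percentages."""
    motif_list = dedup_motifs(motifs)
    groups = list(grouped_sets)
    widths = {s.width for s in grouped_sets.values()}
    if len(widths) > 1:
        raise ValueError(f"groups have mixed widths: {sorted(widths)}")
    index = [m.pattern for m in motif_list]
    counts = pd.DataFrame(0, index=index, columns=groups, dtype=int)
    pvalues = pd.DataFrame(1.0, index=index, columns=groups)
    sizes = pd.Series({g: len(s) for g, s in grouped_sets.items()})
    m_tests = max(1, len(motif_list) * len(groups))
    for motif, row in zip(motif_list, index):
        p_exp = expected_match_probability(motif, bg, position_specific)
        for g in groups:
            seqs = grouped_sets[g]
            k = sum(
                matches_window(w.residues, motif.pairs, seqs.width) for w in seqs
            )
            counts.loc[row, g] = k
            pvalues.loc[row, g] = binomial_pvalue(k, len(seqs), p_exp)
    significant = pvalues <= alpha / m_tests
    percent = 100.0 * counts / sizes
    percent = percent.where(significant)
    return PatternMatchMatrix(
        motifs=motif_list,
        groups=groups,
        counts=counts,
        pvalues=pvalues,
        percent=percent,
        group_sizes=sizes,
        alpha=alpha,
        n_tests=m_tests,
    )


def positional_load(
    motifs_by_group: dict[str, Sequence[Motif]], width: int
) -> pd.DataFrame:
    """Percentage of each group's motifs fixing any residue at each offset."""
    h = (width - 1) // 2
    offsets = list(range(-h, h + 1))
    rows = {}
    for group, motifs in motifs_by_group.items():
        if not motifs:
            raise ValueError(f"group {group!r} has no motifs")
        load = np.zeros(width)
        for m in motifs:
            for off in m.offsets():
                load[off + h] += 1
        rows[group] = 100.0 * load / len(motifs)
    return pd.DataFrame.from_dict(rows, orient="index", columns=offsets)


class DifferentialStatus(str, enum.Enum):
    """Sentinel codes for the composition differential's special cases."""

    BOTH = "both"
    A_ONLY = "inf_a_only"
    B_ONLY = "inf_b_only"
    ABSENT = "absent_both"


def _fixed_residue_percentages(motifs: Sequence[Motif]) -> pd.Series:
    counter: dict[tuple[int, str], int] = {}
    for m in motifs:
        for pair in m.pairs:
            key = (pair.offset, pair.token if not pair.is_group else "".join(sorted(pair.members)))
            counter[key] = counter.get(key, 0) + 1
    total = sum(counter.values())
    if total == 0:
        return pd.Series(dtype=float)
    return pd.Series(counter, dtype=float) * 100.0 / total


def composition_differential(
    motifs_type_a: Sequence[Motif], motifs_type_b: Sequence[Motif]
) -> pd.DataFrame:
    """Per-(offset, token) log2 ratio of fixed-residue percentage frequencies.

    ``log2_ratio`` is ``log2(pct_a / pct_b)``; the three special cases are
    encoded in ``status`` (present only in A / only in B / absent in both)
    with +-inf / NaN in the numeric column.  ``combined_pct`` (the summed
    percentage) supports point-size encoding in downstream plots.
    """
    pa = _fixed_residue_percentages(motifs_type_a)
    pb = _fixed_residue_percentages(motifs_type_b)
    keys = sorted(set(pa.index) | set(pb.index))
    records = []
    for key in keys:
        a = float(pa.get(key, 0.0))
        b = float(pb.get(key, 0.0))
        if a > 0 and b > 0:
            value, status = np.log2(a / b), DifferentialStatus.BOTH
        elif a > 0:
            value, status = np.inf, DifferentialStatus.A_ONLY
        elif b > 0:
            value, status = -np.inf, DifferentialStatus.B_ONLY
        else:
            value, status = np.nan, DifferentialStatus.ABSENT
        records.append(
            {
                "offset": key[0],
                "token": key[1],
                "pct_a": a,
                "pct_b": b,
                "log2_ratio": value,
                "status": status.value,
                "combined_pct": a + b,
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["offset", "token", "pct_a", "pct_b", "log2_ratio", "status", "combined_pct"]
    )


def abundance_matrix(
    grouped_sets: dict[str, SequenceSet], motifs: Sequence[Motif]
) -> pd.DataFrame:
    """Motif x condition arithmetic means of matched-window intensities.

    Windows without an intensity are excluded from the mean; a motif with
    no matching window (or no intensities) in a condition gives NaN, never 0.
    """
    motif_list = dedup_motifs(motifs)
    out = pd.DataFrame(
        np.nan, index=[m.pattern for m in motif_list], columns=list(grouped_sets)
    )
    for motif in motif_list:
        for g, seqs in grouped_sets.items():
            vals = [
                w.intensity
                for w in seqs
                if w.intensity is not None
                and matches_window(w.residues, motif.pairs, seqs.width)
            ]
            if vals:
                out.loc[motif.pattern, g] = float(np.mean(vals))
    return out


def transform_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """ln(x+1), then per-row centering and unit sample-variance scaling.

    Scaling uses the sample standard deviation (ddof=1, as R's ``scale``).
    Rows with zero variance after the log transform become all-zero rows
    (rather than NaN), keeping matrix shapes stable for joins.
    """
    values = np.asarray(matrix, dtype=float)
    if (values < 0).any():
        raise ValueError("transform_counts requires non-negative entries")
    logged = np.log1p(values)
    centered = logged - logged.mean(axis=1, keepdims=True)
    if logged.shape[1] > 1:
        std = logged.std(axis=1, ddof=1, keepdims=True)
    else:
        std = np.zeros((logged.shape[0], 1))
    scaled = np.divide(centered, std, out=np.zeros_like(centered), where=std > 0)
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


@dataclass
class ClusterExport:
    """Average-linkage ordering of a matrix plus its dendrogram merges."""

    matrix: pd.DataFrame
    row_order: list
    col_order: list
    row_linkage: Optional[np.ndarray]
    col_linkage: Optional[np.ndarray]


def _linkage_order(values: np.ndarray):
    if values.shape[0] < 2:
        return None, list(range(values.shape[0]))
    link = average(pdist(values, metric="euclidean"))
    return link, [int(i) for i in leaves_list(link)]


def cluster_export(matrix: pd.DataFrame, cluster_columns: bool = True) -> ClusterExport:
    """Reorder rows (and optionally columns) by agglomerative
    average-linkage clustering on Euclidean distances.

    The input must be free of missing values (fill masked cells first).
    The linkage arrays are SciPy merge lists, directly consumable by
    dendrogram renderers.
    """
    values = np.asarray(matrix, dtype=float)
    if np.isnan(values).any():
        raise ValueError("cluster_export requires a matrix without missing values")
    row_link, row_order = _linkage_order(values)
    if cluster_columns and values.shape[1] >= 2:
        col_link, col_order = _linkage_order(values.T)
    else:
        col_link, col_order = None, list(range(values.shape[1]))
    ordered = matrix.iloc[row_order, col_order]
    return ClusterExport(
        matrix=ordered,
        row_order=[matrix.index[i] for i in row_order],
        col_order=[matrix.columns[i] for i in col_order],
        row_linkage=row_link,
        col_linkage=col_link,
    )


def fill_masked(percent: pd.DataFrame, fill: float = 0.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill masked (non-significant) cells for clustering; returns the
    filled matrix and a boolean mask marking the filled cells."""
    mask = percent.isna()
    return percent.fillna(fill), mask
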