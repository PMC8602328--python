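"""Motif deconvolution engine.

The algorithm detects over-represented positional residues in aligned
sequence data by an exact one-sided binomial test per (offset, residue)
pair, Bonferroni-corrected over the scan family.  It then selects *all*
maximally enriched pairs (tie branching), partitions the foreground into
possibly overlapping subsets — one per selected pair, a window matching
several pairs joining every corresponding subset — plus a remainder of
windows matching none, recompiles the background for each pair subset,
and recurses.  Each terminated pair-extension branch emits a motif: the
accumulated fixed pairs together with the windows that match all of them.

Selecting every maximally enriched pair simultaneously, rather than an
arbitrary first one, is what removes the positional bias of greedy
Motif-X-style set reduction: statistically identical pairs (same residue,
same count, same background frequency) are branch points, not an ordering
decision.

Beyond single residues, scans can include *compound residue groups* —
named sets of residues sharing a physicochemical property, tested as one
token whose background probability is the sum over members.  No central
residue needs to be declared; the central column competes like any other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import binom as _binom

from .background import BackgroundExhausted, BackgroundModel
from .types import (
    AA_INDEX,
    STANDARD_AA,
    CompoundGroup,
    EnrichmentResult,
    Motif,
    PositionalPair,
    SequenceSet,
    render_pattern,
)

_N_AA = len(STANDARD_AA)

#: Standard physicochemical partition of the 20 residues, used when
#: compound-group screening is enabled without a custom definition file.
DEFAULT_COMPOUND_GROUPS: tuple[CompoundGroup, ...] = (
    CompoundGroup("acidic", frozenset("DE")),
    CompoundGroup("aliphatic", frozenset("AVLIM")),
    CompoundGroup("aromatic", frozenset("FWY")),
    CompoundGroup("basic", frozenset("KRH")),
    CompoundGroup("polar", frozenset("STNQ")),
    CompoundGroup("tiny", frozenset("GPC")),
)

#: Relative tolerance on log p-values for the maximal-enrichment tie test.
TIE_LOG_RTOL = 1e-9

#: Below this foreground size the binomial tail is summed term by term
#: (exact to ~n*eps); above it the survival function is evaluated through
#: the regularized incomplete beta.
_DIRECT_SUM_MAX_N = 64


@dataclass
class EngineConfig:
    """Tunable parameters of a deconvolution run.

    ``alpha`` is the familywise significance level applied with Bonferroni
    correction over each scan's ``width * (20 + #groups)`` tests;
    ``min_support`` is the minimum number of matching sequences for a
    subset to be pursued and a motif to be emitted.  Defaults follow the
    Motif-X-compatible convention: alpha 0.001, support 20.
    """

    alpha: float = 0.001
    min_support: int = 20
    width: Optional[int] = None
    position_specific_background: bool = True
    compound_groups: tuple[CompoundGroup, ...] = ()
    require_central_residue: Optional[frozenset[str]] = None
    dedup_sequences: bool = False
    #: "all" = branch on every maximally enriched pair (the default);
    #: "first" = greedy single-pair selection (ablation reproducing the
    #: positional-bias failure mode of sequential set reduction).
    tie_strategy: str = "all"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.tie_strategy not in ("all", "first"):
            raise ValueError("tie_strategy must be 'all' or 'first'")
        if isinstance(self.require_central_residue, (set, str)):
            self.require_central_residue = frozenset(self.require_central_residue)
        self.compound_groups = tuple(
            sorted(self.compound_groups, key=lambda g: g.name)
        )


def binomial_pvalue(k: int, n: int, p0: float) -> float:
    """One-sided exact binomial survival probability ``P(X >= k)``.

    For small ``n`` the tail is summed directly with a multiplicative
    term recurrence (all terms positive, relative error ~``n * eps``);
    for large ``n`` the survival function is evaluated via the
    regularized incomplete beta.  ``P(X >= 0) = 1`` always; ``p0 = 0``
    with ``k > 0`` gives exactly 0.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be a probability, got {p0}")
    if k == 0:
        return 1.0
    if p0 == 0.0:
        return 0.0
    if p0 == 1.0:
        return 1.0
    if n <= _DIRECT_SUM_MAX_N:
        q0 = 1.0 - p0
        # first term via logs to dodge under/overflow, then recurrence
        logt = (
            math.lgamma(n + 1)
            - math.lgamma(k + 1)
            - math.lgamma(n - k + 1)
            + k * math.log(p0)
            + (n - k) * math.log(q0)
        )
        term = math.exp(logt)
        total = term
        ratio = p0 / q0
        for i in range(k, n):
            term *= (n - i) / (i + 1) * ratio
            total += term
        return min(total, 1.0)
    return float(_binom.sf(k - 1, n, p0))


def _pvalues(k: np.ndarray, n: np.ndarray, p0: np.ndarray) -> np.ndarray:
    """Vectorized dispatch of :func:`binomial_pvalue`."""
    k = np.asarray(k)
    n = np.asarray(n)
    p0 = np.asarray(p0)
    if n.size and n.max() <= _DIRECT_SUM_MAX_N:
        it = np.nditer([k, n, p0], flags=["multi_index"])
        out = np.empty(k.shape)
        for kv, nv, pv in it:
            out[it.multi_index] = binomial_pvalue(int(kv), int(nv), float(pv))
        return out
    with np.errstate(divide="ignore"):
        out = _binom.sf(k - 1, n, np.clip(p0, 0.0, 1.0))
    out = np.where(k == 0, 1.0, out)
    out = np.where((p0 <= 0.0) & (k > 0), 0.0, out)
    out = np.where(p0 >= 1.0, 1.0, out)
    return out


def _candidate_tokens(cfg: EngineConfig) -> list[tuple[str, frozenset, list[int]]]:
    """(token, members, codes) in canonical order: singles A..Y, then groups."""
    toks: list[tuple[str, frozenset, list[int]]] = [
        (aa, frozenset(aa), [AA_INDEX[aa]]) for aa in STANDARD_AA
    ]
    for g in cfg.compound_groups:
        toks.append((g.name, g.members, sorted(AA_INDEX[m] for m in g.members)))
    return toks


def n_tests(cfg: EngineConfig, width: int) -> int:
    """Bonferroni family size of one scan: every offset times every token."""
    return width * (_N_AA + len(cfg.compound_groups))


def _scan_encoded(
    enc: np.ndarray, width: int, bg: BackgroundModel, cfg: EngineConfig
) -> list[EnrichmentResult]:
    h = (width - 1) // 2
    n_win = enc.shape[0]
    counts = np.zeros((width, 22), dtype=np.int64)
    for col in range(width):
        counts[col] = np.bincount(enc[:, col], minlength=22)
    n_eff = counts[:, :_N_AA].sum(axis=1)  # '-' and X cells are not counted
    freq = bg.frequency_matrix(cfg.position_specific_background)
    tokens = _candidate_tokens(cfg)
    m = n_tests(cfg, width)
    threshold = cfg.alpha / m

    pairs: list[PositionalPair] = []
    ks: list[int] = []
    ns: list[int] = []
    p0s: list[float] = []
    for col in range(width):
        offset = col - h
        for token, members, codes in tokens:
            k = int(counts[col, codes].sum())
            if k == 0:
                continue
            if float(freq[col, codes].sum()) == 0.0:
                # token absent from the background: the binomial test is
                # undefined (any occurrence would be infinitely significant);
                # such pairs are untestable and never claimed enriched
                continue
            pairs.append(PositionalPair(offset, token, members))
            ks.append(k)
            ns.append(int(n_eff[col]))
            p0s.append(float(freq[col, codes].sum()))
    if not pairs:
        return []
    pvals = _pvalues(np.array(ks), np.array(ns), np.array(p0s))
    return [
        EnrichmentResult(
            pair=pair,
            k=k,
            n=n,
            p0=p0,
            p=float(p),
            m=m,
            significant=bool(p <= threshold),
        )
        for pair, k, n, p0, p in zip(pairs, ks, ns, p0s, pvals)
    ]


def scan_enrichment(
    fg: SequenceSet, bg: BackgroundModel, cfg: EngineConfig
) -> list[EnrichmentResult]:
    """Binomial enrichment scan of every (offset, token) pair with k > 0.

    Results are ordered offset-ascending, singles alphabetical before
    groups — the canonical candidate order.
    """
    if len(fg) == 0:
        raise ValueError("foreground is empty")
    if fg.width != bg.width:
        raise ValueError(f"width mismatch: foreground {fg.width}, background {bg.width}")
    return _scan_encoded(fg.encoded(), fg.width, bg, cfg)


def _log_p(p: float) -> float:
    return math.log(p) if p > 0.0 else -math.inf


def select_maximal(
    results: Sequence[EnrichmentResult], cfg: Optional[EngineConfig] = None
) -> list[PositionalPair]:
    """All significant pairs tied (on log p, rel. tol. 1e-9) for minimum p.

    When a single residue and a compound group containing it are both
    maximal with identical match count, the group adds no sequences and
    only the more specific single residue is kept.  With the greedy
    ablation (``tie_strategy="first"``) only the first maximal pair in
    canonical order is returned.  Empty when nothing is significant.
    """
    sig = [r for r in results if r.significant]
    if not sig:
        return []
    logs = [_log_p(r.p) for r in sig]
    best = min(logs)
    if best == -math.inf:
        maximal = [r for r, lp in zip(sig, logs) if lp == -math.inf]
    else:
        tol = TIE_LOG_RTOL * abs(best)
        maximal = [r for r, lp in zip(sig, logs) if lp - best <= tol]
    singles = [r for r in maximal if not r.pair.is_group]
    kept = []
    for r in maximal:
        if r.pair.is_group and any(
            s.pair.offset == r.pair.offset
            and s.pair.token in r.pair.members
            and s.k == r.k
            for s in singles
        ):
            continue
        kept.append(r)
    if cfg is not None and cfg.tie_strategy == "first":
        kept = kept[:1]
    return [r.pair for r in kept]


def _match_mask(enc: np.ndarray, pair: PositionalPair, width: int) -> np.ndarray:
    col = pair.offset + (width - 1) // 2
    codes = [AA_INDEX[m] for m in pair.members]
    return np.isin(enc[:, col], codes)


def matches_window(residues: str, pairs: Sequence[PositionalPair], width: int) -> bool:
    """Exact match of a window against fixed pairs ('-'/X never match)."""
    h = (width - 1) // 2
    for pair in pairs:
        if residues[pair.offset + h] not in pair.members:
            return False
    return True


def partition(
    fg: SequenceSet, pairs: Sequence[PositionalPair]
) -> tuple[dict[PositionalPair, SequenceSet], SequenceSet]:
    """Split the foreground into per-pair (overlapping) subsets + remainder.

    A window matching several pairs joins every corresponding subset; the
    remainder holds the windows matching none.
    """
    if not pairs:
        raise ValueError("partition requires at least one pair")
    enc = fg.encoded()
    subsets: dict[PositionalPair, SequenceSet] = {}
    matched_any = np.zeros(len(fg), dtype=bool)
    for pair in pairs:
        mask = _match_mask(enc, pair, fg.width)
        matched_any |= mask
        subsets[pair] = fg.subset(np.flatnonzero(mask))
    remainder = fg.subset(np.flatnonzero(~matched_any))
    return subsets, remainder


def classify_pairs(pairs: Sequence[PositionalPair]) -> str:
    """Complexity class from the fixed offsets (offset 0 = modified site)."""
    offsets = {p.offset for p in pairs}
    if not offsets:
        raise ValueError("motif has no fixed pairs")
    if 0 in offsets:
        return "I" if len(offsets) > 1 else "II"
    return "III"


def classify_motif(motif: Motif, central_index: Optional[int] = None) -> str:
    """Class I: central + flanking fixed; II: central only; III: flanking only.

    Offsets are center-relative, so ``central_index`` is informational.
    """
    return classify_pairs(motif.pairs)


def extract_motifs(
    fg: SequenceSet, bg: BackgroundModel, cfg: Optional[EngineConfig] = None
) -> list[Motif]:
    """Run the full recursive deconvolution and return the motif list.

    The recursion: scan -> select all maximal pairs -> on none, emit the
    accumulated prefix (pair-extension branches only, support permitting)
    -> otherwise partition, recurse into each pair subset with a
    recompiled background, and into the remainder with the unchanged
    prefix and background.  Pair subsets below ``min_support`` are
    dropped.  The output is order-invariant in the input windows and
    sorted by (support descending, pattern).
    """
    if cfg is None:
        cfg = EngineConfig()
    if len(fg) == 0:
        raise ValueError("foreground is empty")
    if fg.width != bg.width:
        raise ValueError(f"width mismatch: foreground {fg.width}, background {bg.width}")

    if cfg.require_central_residue is not None:
        c = fg.central_index
        keep = [i for i, w in enumerate(fg.windows) if w.residues[c] in cfg.require_central_residue]
        fg = fg.subset(keep)
    if cfg.dedup_sequences:
        seen: set[str] = set()
        keep = []
        for i, w in enumerate(fg.windows):
            if w.residues not in seen:
                seen.add(w.residues)
                keep.append(i)
        fg = fg.subset(keep)
    if len(fg) == 0:
        return []

    width = fg.width
    enc = fg.encoded()
    emitted: dict[frozenset, Motif] = {}

    def emit(prefix, indices, trail):
        pairs = tuple(sorted(prefix, key=lambda p: p.offset))
        key = frozenset(pairs)
        if key in emitted:
            return  # same pair set reached via a different branch order
        emitted[key] = Motif(
            pairs=pairs,
            support=len(indices),
            matched_ids=frozenset(int(i) for i in indices),
            pattern=render_pattern(pairs, width),
            complexity_class=classify_pairs(pairs),
            trail=tuple(trail),
        )

    def recurse(indices: np.ndarray, branch_bg: BackgroundModel, prefix, trail, emit_on_term: bool):
        sub = enc[indices]
        results = _scan_encoded(sub, width, branch_bg, cfg)
        fixed_offsets = {p.offset for p in prefix}
        candidates = [r for r in results if r.pair.offset not in fixed_offsets]
        pairs = select_maximal(candidates, cfg)
        if not pairs:
            if emit_on_term and prefix and len(indices) >= cfg.min_support:
                emit(prefix, indices, trail)
            return
        by_pair = {r.pair: r for r in candidates}
        matched_any = np.zeros(len(indices), dtype=bool)
        for pair in pairs:
            mask = _match_mask(sub, pair, width)
            matched_any |= mask
            sub_idx = indices[mask]
            if len(sub_idx) < cfg.min_support:
                continue
            res = by_pair[pair]
            try:
                reduced = branch_bg.reduce([pair])
            except BackgroundExhausted:
                emit(prefix + [pair], sub_idx, trail + [res])
                continue
            recurse(sub_idx, reduced, prefix + [pair], trail + [res], True)
        rem_idx = indices[~matched_any]
        if len(rem_idx):
            recurse(rem_idx, branch_bg, prefix, trail, False)

    recurse(np.arange(len(fg)), bg, [], [], False)
    return sorted(emitted.values(), key=lambda m: (-m.support, m.pattern))


def motif_set_key(motifs: Sequence[Motif]) -> frozenset:
    """Canonical identity of a motif list: {(pair set, support)}."""
    return frozenset((m.key, m.support) for m in motifs)


def negate_offsets(motif: Motif, width: int) -> Motif:
    """Mirror a motif across the central column (offset i -> -i)."""
    pairs = tuple(
        sorted(
            (PositionalPair(-p.offset, p.token, p.members) for p in motif.pairs),
            key=lambda p: p.offset,
        )
    )
    return replace(
        motif,
        pairs=pairs,
        pattern=render_pattern(pairs, width),
        complexity_class=classify_pairs(pairs),
        trail=(),
    )


def reverse_equivalence_check(
    fg: SequenceSet,
    bg: BackgroundModel,
    cfg: Optional[EngineConfig] = None,
    extractor: Callable[..., list[Motif]] = None,
) -> bool:
    """True iff motifs from the reversed run, offsets negated, equal the
    forward run's exactly.

    Reversing the foreground requires reversing the background windows as
    well, so both runs see commensurate statistics.  ``extractor`` can be
    substituted (e.g. a deliberately order-dependent mock) to validate the
    check itself.
    """
    extract = extractor or extract_motifs
    forward = extract(fg, bg, cfg)
    rev = extract(fg.reversed(), bg.reversed(), cfg)
    mirrored = [negate_offsets(m, fg.width) for m in rev]
    return motif_set_key(forward) == motif_set_key(mirrored)
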