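"""Synthetic fixture generators for validation experiments.

These generators reproduce, at desk scale, the constructed datasets used
to validate the deconvolution engine:

* a positional-bias demonstration set — two statistically identical
  enriched positional residues (aspartate at the first and last window
  position) coupled through a single shared sequence, the configuration
  that breaks greedy single-pair set reduction;
* uniform random proteomes standing in for a reference proteome in
  desk-scale runs;
* null foregrounds sampled uniformly (without replacement) from a
  background window pool, for false-positive-rate estimation.

Every generator is a pure function of its arguments and seed: identical
inputs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .background import BackgroundModel, enumerate_windows
from .types import STANDARD_AA, SequenceSet, SequenceWindow


@dataclass
class GeneratorSpec:
    """Parameters of random-sequence generation.

    ``residue_frequencies`` defaults to the uniform distribution over the
    20 standard amino acids.
    """

    seed: int
    width: int = 15
    n_sequences: int = 0
    residue_frequencies: dict[str, float] = field(default_factory=dict)

    def probabilities(self) -> np.ndarray:
        if not self.residue_frequencies:
            return np.full(len(STANDARD_AA), 1.0 / len(STANDARD_AA))
        p = np.array([self.residue_frequencies.get(aa, 0.0) for aa in STANDARD_AA])
        if not np.isclose(p.sum(), 1.0):
            raise ValueError(f"residue frequencies sum to {p.sum()}, expected 1")
        return p


_AA_ARR = np.array(list(STANDARD_AA))


def _random_residues(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    return _AA_ARR[rng.choice(len(_AA_ARR), size=n, p=probs)]


def generate_bias_demo(
    seed: int, width: int = 15, n_background: int = 5000
) -> tuple[SequenceSet, SequenceSet]:
    """The 39-sequence positional-bias demonstration set plus a background.

    19 windows carry D at the first position (offset ``-(w-1)/2``), 19
    carry D at the last position, and one carries D at both; all have S at
    the center and uniform-random residues elsewhere.  Exactly 20 windows
    have D at each anchor (the random filler never places a stray D at the
    opposite anchor), so the two enriched positional residues are
    statistically identical but not mutually exclusive — the configuration
    that defeats greedy single-pair set reduction.

    The background is ``n_background`` S-centered windows with
    uniform-random residues elsewhere, generated in mirror pairs (each
    window together with its reverse) so that mirror positions are exactly
    equifrequent and the two anchors really are statistically identical
    against it.
    """
    if width < 3 or width % 2 == 0:
        raise ValueError("width must be odd and >= 3")
    rng = np.random.default_rng(seed)
    h = (width - 1) // 2
    probs = np.full(len(STANDARD_AA), 1.0 / len(STANDARD_AA))
    no_d = np.array([aa for aa in STANDARD_AA if aa != "D"])

    def make(d_first: bool, d_last: bool) -> str:
        chars = _random_residues(rng, width, probs)
        chars[h] = "S"
        chars[0] = "D" if d_first else rng.choice(no_d)
        chars[-1] = "D" if d_last else rng.choice(no_d)
        return "".join(chars)

    fg = (
        [make(True, False) for _ in range(19)]
        + [make(False, True) for _ in range(19)]
        + [make(True, True)]
    )
    bg = []
    for _ in range((n_background + 1) // 2):
        chars = _random_residues(rng, width, probs)
        chars[h] = "S"
        s = "".join(chars)
        bg.extend([s, s[::-1]])
    return (
        SequenceSet([SequenceWindow(s) for s in fg], width=width),
        SequenceSet([SequenceWindow(s) for s in bg], width=width),
    )


def generate_reversed(
    fg: SequenceSet, bg: SequenceSet
) -> tuple[SequenceSet, SequenceSet]:
    """Character-reverse every window of both sets (for reversal tests)."""
    return fg.reversed(), bg.reversed()


def sample_null(
    pool: Union[BackgroundModel, SequenceSet, list],
    n: int,
    central_residue: Optional[str] = None,
    seed: int = 0,
) -> SequenceSet:
    """Uniform sample of ``n`` windows, without replacement, from a pool.

    The pool may be a background model (its windows), a sequence set, or a
    plain window list; with ``central_residue`` set, sampling is
    restricted to matching centers.  Reproducible from ``seed``.
    """
    if isinstance(pool, BackgroundModel):
        seqs = pool.windows
        width = pool.width
    elif isinstance(pool, SequenceSet):
        seqs = pool.sequences()
        width = pool.width
    else:
        seqs = list(pool)
        if not seqs:
            raise ValueError("empty pool")
        width = len(seqs[0])
    if central_residue is not None:
        c = (width - 1) // 2
        seqs = [s for s in seqs if s[c] == central_residue]
    if n > len(seqs):
        raise ValueError(f"cannot sample {n} from a pool of {len(seqs)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(seqs), size=n, replace=False)
    return SequenceSet([SequenceWindow(seqs[i]) for i in idx], width=width)


def generate_proteome(
    spec: GeneratorSpec, n_proteins: int, protein_length: int
) -> str:
    """FASTA text of i.i.d.-residue proteins drawn from the spec frequencies."""
    rng = np.random.default_rng(spec.seed)
    probs = spec.probabilities()
    records = []
    for i in range(n_proteins):
        seq = "".join(_random_residues(rng, protein_length, probs))
        records.append(f">synthetic_{i:05d}\n{seq}\n")
    return "".join(records)


def proteome_sequences(fasta_text: str) -> list[str]:
    """Plain sequence list from generated FASTA text (no file round trip)."""
    seqs = []
    cur: list[str] = []
    for line in fasta_text.splitlines():
        if line.startswith(">"):
            if cur:
                seqs.append("".join(cur))
                cur = []
        else:
            cur.append(line.strip())
    if cur:
        seqs.append("".join(cur))
    return seqs


def null_window_pool(
    proteome_seqs: list[str], width: int, central_residue: Optional[str] = None
) -> list[str]:
    """All width-``w`` windows of a proteome: the null sampling pool."""
    return enumerate_windows(proteome_seqs, width, central_residue)


def false_positive_experiment(
    proteome_seqs: list[str],
    width: int = 15,
    sample_sizes: tuple[int, ...] = (100, 10000),
    replicates_per_condition: int = 25,
    seed: int = 0,
    config=None,
) -> dict:
    """Estimate the null false-positive rate of the deconvolution engine.

    For every central residue present in the proteome and every sample
    size, foregrounds are drawn uniformly without replacement from the
    residue's background window pool and run through motif extraction;
    a replicate counts as a false positive when at least one motif is
    reported.  Since the foregrounds are random subsets of the background,
    no motif should ever be found.

    Returns a dict with the per-condition hit counts and the overall
    fraction (as a percentage of replicates).
    """
    from .engine import EngineConfig, extract_motifs

    cfg = config or EngineConfig()
    rng = np.random.default_rng(seed)
    total = 0
    hits = 0
    per_condition = {}
    for aa in STANDARD_AA:
        pool = null_window_pool(proteome_seqs, width, aa)
        if not pool:
            continue
        bg = BackgroundModel.from_windows(pool, central_residue=aa)
        for size in sample_sizes:
            if size > len(pool):
                raise ValueError(
                    f"pool for {aa} has {len(pool)} windows < sample size {size}"
                )
            n_hit = 0
            for _ in range(replicates_per_condition):
                sub_seed = int(rng.integers(0, 2**31 - 1))
                fg = sample_null(pool, size, seed=sub_seed)
                if extract_motifs(fg, bg, cfg):
                    n_hit += 1
            per_condition[f"{aa}/{size}"] = n_hit
            hits += n_hit
            total += replicates_per_condition
    return {
        "replicates": total,
        "hits": hits,
        "rate_percent": 100.0 * hits / total if total else 0.0,
        "per_condition": per_condition,
    }
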