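"""Positional enrichment analysis, consensus calling, and clone selection.

The analytical core of the pipeline.  Post-selection clones, aligned by loop
length, give an observed positional amino-acid frequency matrix; dividing by
the library's theoretical matrix yields per-cell fold-changes.  A position is
"hot" for a residue when the fold-change reaches the threshold (3 by default)
with at least ``min_count`` supporting observations.  The hot sets form a
per-length consensus (rendered ``V R X X D/I ...``); each clone is scored by
how many of its residues fall in the hot set at their position, and a clone
is selected when it matches at least ``min_matches`` hot residues (3, the
average number of antigen contacts per CDR3 loop) OR belongs to a redundancy
family.  Small helpers normalize recovered phage titers to a common input for
round-over-round enrichment factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .library_model import AA_ALPHABET, PositionalFrequencyTable
from .families import CloneFamily
from .repertoire_io import CloneRecord

__all__ = [
    "EnrichmentProfile",
    "ConsensusProfile",
    "CloneScore",
    "SelectionResult",
    "observed_frequencies",
    "enrichment_ratios",
    "call_hot_positions",
    "score_clone",
    "select_clones",
    "recovery_normalization",
    "round_enrichment",
]

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


def observed_frequencies(
    records: Iterable[CloneRecord], chain: str, length_class: int
) -> PositionalFrequencyTable:
    """Observed per-position amino-acid frequencies for one length class.

    Counts every QC-passing CDR3 of the requested chain whose length matches
    the class; frequency = count / n_sequences.  An empty class gives an
    all-zero table with ``n_sequences = 0``.  The integer count matrix rides
    along on the returned table's ``counts`` attribute.
    """
    counts = np.zeros((length_class, len(AA_ALPHABET)), dtype=np.int64)
    n = 0
    for rec in records:
        cdr3 = rec.cdr3(chain)
        if cdr3 is None or len(cdr3) != length_class:
            continue
        for p, ch in enumerate(cdr3):
            try:
                counts[p, _AA_INDEX[ch]] += 1
            except KeyError:
                raise ValueError(
                    f"non-amino-acid character {ch!r} in clone {rec.clone_id!r}; run qc_filter first"
                ) from None
        n += 1
    freq = counts / n if n else np.zeros_like(counts, dtype=float)
    idx = range(1, length_class + 1)
    return PositionalFrequencyTable(
        chain=chain,
        length_class=length_class,
        n_sequences=n,
        freq=pd.DataFrame(freq, index=idx, columns=list(AA_ALPHABET)),
        counts=pd.DataFrame(counts, index=idx, columns=list(AA_ALPHABET)),
    )


@dataclass
class EnrichmentProfile:
    """Observed/expected fold-change matrix for one (chain, length class).

    Cells where the design encodes nothing (expected 0) but something was
    observed are flagged as non-library residues (candidate sequencing errors
    or mutations) and carry an infinite sentinel ratio; they are never called
    hot.  ``pvalues`` holds uncorrected one-sided binomial tail probabilities
    against the theoretical frequency, for information only.
    """

    chain: str
    length_class: int
    ratio: pd.DataFrame
    observed_counts: pd.DataFrame
    expected: pd.DataFrame
    n_sequences: int
    non_library: list[tuple[int, str]] = field(default_factory=list)
    pvalues: Optional[pd.DataFrame] = None


def enrichment_ratios(
    observed: PositionalFrequencyTable,
    theoretical: PositionalFrequencyTable,
    pseudocount_policy: str = "none",
) -> EnrichmentProfile:
    """Per-cell fold-change of observed over expected frequency.

    ``pseudocount_policy='none'`` uses raw frequencies (ratio 0 where nothing
    was observed); ``'laplace'`` add-one smooths the observed counts, for
    exploratory use.  Expected-zero/observed-positive cells get the infinite
    sentinel and are listed in ``non_library`` rather than producing a
    silently huge ratio.
    """
    if pseudocount_policy not in ("none", "laplace"):
        raise ValueError(f"unknown pseudocount_policy {pseudocount_policy!r}")
    if (
        observed.length_class != theoretical.length_class
        or list(observed.freq.columns) != list(theoretical.freq.columns)
    ):
        raise ValueError("observed and theoretical tables have mismatched dimensions")
    if observed.counts is None:
        raise ValueError("observed table carries no count matrix")
    n = observed.n_sequences
    counts = observed.counts.values.astype(float)
    if pseudocount_policy == "laplace":
        obs = (counts + 1.0) / (n + len(AA_ALPHABET)) if n else counts
    else:
        obs = observed.freq.values
    exp = theoretical.freq.values
    ratio = np.zeros_like(obs)
    pos_exp = exp > 0
    ratio[pos_exp] = obs[pos_exp] / exp[pos_exp]
    sentinel = (~pos_exp) & (observed.counts.values > 0)
    ratio[sentinel] = np.inf
    ratio[observed.counts.values == 0] = 0.0
    non_library = [
        (int(observed.freq.index[i]), AA_ALPHABET[j]) for i, j in zip(*np.nonzero(sentinel))
    ]
    pvals = np.ones_like(obs)
    if n > 0:
        k = observed.counts.values
        pvals[pos_exp] = stats.binom.sf(k[pos_exp] - 1, n, exp[pos_exp])
    idx, cols = observed.freq.index, observed.freq.columns
    return EnrichmentProfile(
        chain=observed.chain,
        length_class=observed.length_class,
        ratio=pd.DataFrame(ratio, index=idx, columns=cols),
        observed_counts=observed.counts.copy(),
        expected=theoretical.freq.copy(),
        n_sequences=n,
        non_library=sorted(non_library),
        pvalues=pd.DataFrame(pvals, index=idx, columns=cols),
    )


@dataclass
class ConsensusProfile:
    """Hot-position sets for one length class ("consensus" sequence).

    ``hot`` maps position -> residues over-represented at least
    ``fold_threshold``-fold with ``min_count`` supporting observations; an
    empty set renders as ``X``.  ``insufficient`` marks classes with too few
    sequences for the fold rule to mean anything.
    """

    chain: str
    length_class: int
    hot: dict[int, frozenset]
    fold_threshold: float
    min_count: int
    n_sequences: int = 0
    insufficient: bool = False
    non_library: list[tuple[int, str]] = field(default_factory=list)

    def hot_cells(self) -> set[tuple[int, str]]:
        return {(p, a) for p, s in self.hot.items() for a in s}

    def render(self, prefix: str = "VR") -> str:
        """Table-style consensus line: prefix residues, then ``X`` or ``/``-joined hot sets."""
        tokens = list(prefix)
        for p in range(1, self.length_class + 1):
            s = self.hot.get(p, frozenset())
            tokens.append("/".join(sorted(s)) if s else "X")
        return " ".join(tokens)


def call_hot_positions(
    profile: EnrichmentProfile,
    fold_threshold: float = 3.0,
    min_count: int = 2,
    min_class_n: int = 10,
) -> ConsensusProfile:
    """Call over-represented residues per position.

    A residue is hot when its fold-change is >= ``fold_threshold`` (>= 3:
    "at least by a factor of 3") and it was observed at least ``min_count``
    times.  Classes with fewer than ``min_class_n`` sequences return an empty
    consensus marked insufficient — too few clones for a frequency comparison.
    Non-library sentinel cells are excluded from hot sets and reported apart.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if profile.n_sequences < 1:
        raise ValueError("profile built from no sequences")
    base = dict(
        chain=profile.chain,
        length_class=profile.length_class,
        fold_threshold=fold_threshold,
        min_count=min_count,
        n_sequences=profile.n_sequences,
        non_library=list(profile.non_library),
    )
    if profile.n_sequences < min_class_n:
        return ConsensusProfile(hot={}, insufficient=True, **base)
    hot: dict[int, frozenset] = {}
    ratio = profile.ratio
    counts = profile.observed_counts
    finite = np.isfinite(ratio.values)
    mask = finite & (ratio.values >= fold_threshold) & (counts.values >= min_count)
    for i, j in zip(*np.nonzero(mask)):
        p = int(ratio.index[i])
        hot.setdefault(p, set()).add(AA_ALPHABET[j])  # type: ignore[arg-type]
    hot = {p: frozenset(s) for p, s in hot.items()}
    return ConsensusProfile(hot=hot, insufficient=False, **base)


@dataclass
class CloneScore:
    clone_id: Optional[str]
    match_count: int
    matched_positions: list[tuple[int, str]]


def score_clone(
    cdr3: str, consensus: ConsensusProfile, clone_id: Optional[str] = None
) -> CloneScore:
    """Count positions where the clone carries a hot residue.

    Multi-residue hot sets match any member (a ``D/I`` position matches D or
    I).  ``X`` placeholders in masked fixture rows never match.  The loop must
    already have the invariant prefix stripped and match the class length.
    """
    if len(cdr3) != consensus.length_class:
        raise ValueError(
            f"CDR3 length {len(cdr3)} does not match consensus length class "
            f"{consensus.length_class}"
        )
    matched = [
        (p, cdr3[p - 1])
        for p in range(1, consensus.length_class + 1)
        if cdr3[p - 1] in consensus.hot.get(p, frozenset())
    ]
    return CloneScore(clone_id=clone_id, match_count=len(matched), matched_positions=matched)


@dataclass
class SelectionResult:
    clone_id: str
    selected: bool
    reasons: frozenset
    score: CloneScore
    family_ids: tuple[str, ...] = ()


def select_clones(
    scores: Sequence[CloneScore],
    redundancy: Mapping[str, Sequence[CloneFamily]],
    min_matches: int = 3,
) -> list[SelectionResult]:
    """Combine the bias and redundancy criteria into selection verdicts.

    A clone is selected iff it matches at least ``min_matches`` hot residues
    (reason ``bias``) or sits in a redundancy family (reason ``redundancy``).
    Output ordering is deterministic: selected first, then by descending
    match count, then clone id.
    """
    out = []
    for sc in scores:
        reasons = set()
        if sc.match_count >= min_matches:
            reasons.add("bias")
        fams = redundancy.get(sc.clone_id, ())
        if fams:
            reasons.add("redundancy")
        out.append(
            SelectionResult(
                clone_id=sc.clone_id,
                selected=bool(reasons),
                reasons=frozenset(reasons),
                score=sc,
                family_ids=tuple(f.family_id for f in fams),
            )
        )
    out.sort(key=lambda r: (not r.selected, -r.score.match_count, r.clone_id))
    return out


def recovery_normalization(
    output_cfu: float, input_cfu: float, reference_input: float = 1e12
) -> float:
    """Scale a recovered titer to the reference phage input (10^12 cfu)."""
    if input_cfu <= 0 or output_cfu < 0:
        raise ValueError("cfu counts must be positive (input) and non-negative (output)")
    return output_cfu * reference_input / input_cfu


def round_enrichment(norm_r2: float, norm_r1: float) -> float:
    """Round-over-round fold factor of normalized recoveries."""
    if norm_r1 <= 0 or norm_r2 < 0:
        raise ValueError("normalized recoveries must be positive")
    return norm_r2 / norm_r1
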