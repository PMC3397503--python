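"""Packaged worked example: the published VH CDR3 consensus/clone table.

For the three most common VH CDR3 loop lengths (10, 13 and 14 randomized
positions after the invariant VR prefix), the published selection experiment
reported the per-length consensus of over-represented residues and the
thirteen selected clones aligned against it, with residues masked as ``X``
wherever a clone did not match a hot position.  That table is transcribed
here so the headline selection result can be reproduced without sequence
data (none was deposited).  Clone rows are the printed masked strings: only
hot-matching residues are spelled out, so scoring them against the consensus
recovers the printed highlighted-identity counts exactly.

``synthetic_observed_counts`` builds a synthetic count matrix whose hot calls
reproduce a given hot-set dictionary against a theoretical table — a
stand-in for the unpublished per-clone sequence data behind the consensus.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .enrichment import ConsensusProfile
from .families import CloneFamily
from .library_model import AA_ALPHABET, PositionalFrequencyTable

__all__ = [
    "TABLE1_CONSENSUS",
    "TABLE1_CLONES",
    "TABLE1_REDUNDANT_FAMILIES",
    "table1_consensus",
    "table1_clones",
    "table1_redundancy",
    "synthetic_observed_counts",
]

#: Published hot sets per length class: position -> string of hot residues.
TABLE1_CONSENSUS: Mapping[int, Mapping[int, str]] = {
    10: {3: "DI", 4: "R", 6: "Y", 8: "V", 9: "E", 10: "D"},
    13: {1: "V", 2: "ACNQ", 3: "MN", 4: "W", 5: "EL", 6: "E", 8: "N",
         9: "EW", 10: "E", 11: "E"},
    14: {1: "ES", 2: "DEM", 3: "W", 4: "IRW", 5: "P", 6: "MW", 7: "G",
         9: "E", 12: "Y", 14: "N"},
}

#: The thirteen selected clones: (clone_id, length class, masked loop).
TABLE1_CLONES: tuple[tuple[str, int, str], ...] = (
    ("F8.32.F2", 10, "XXIXXXXXEX"),
    ("H8.32.F1", 10, "XXDXXXXVXD"),
    ("D6.32.F2", 10, "XXXRXYXXEX"),
    ("H4.32.F1", 10, "XXDXXYXVXX"),
    ("E1.31.F2", 13, "XAXXEXXNXXXXX"),
    ("E6.32F2", 13, "XNXXLXXNXXXXX"),
    ("L1.32F1", 13, "VNNXXXXNEXXXX"),
    ("I7.31.F1", 13, "XXNWXXXXXEXXX"),
    ("B2.32.F1", 14, "EXXWPXXXEXXXXX"),
    ("C7.31CF2", 14, "SMXIXXXXXXXYXX"),
    ("D6.31.F2", 14, "EEXWXXXXXXXXXX"),
    ("G4.31.F1", 14, "XDXRXMXXXXXXXN"),
    ("G8.31.F1", 14, "EXWXXWGXXXXXXX"),
)

#: Redundancy families reported among the printed clones: each was recovered
#: twice as an independent colony (partner clone in parentheses in the study).
TABLE1_REDUNDANT_FAMILIES: Mapping[str, tuple[str, ...]] = {
    "F8.32.F2": ("E8.32.F2",),
    "H8.32.F1": ("I8.32.F1",),
}


def table1_consensus(length_class: int) -> ConsensusProfile:
    """The published consensus for one VH length class as a ConsensusProfile."""
    hot = {p: frozenset(res) for p, res in TABLE1_CONSENSUS[length_class].items()}
    return ConsensusProfile(
        chain="VH",
        length_class=length_class,
        hot=hot,
        fold_threshold=3.0,
        min_count=2,
        n_sequences=0,
    )


def table1_clones(length_class: int | None = None) -> list[tuple[str, int, str]]:
    rows = [r for r in TABLE1_CLONES if length_class is None or r[1] == length_class]
    return list(rows)


def table1_redundancy() -> dict[str, list[CloneFamily]]:
    """Redundancy flags for the published clone set, as cluster output would give."""
    flags: dict[str, list[CloneFamily]] = {}
    for k, (cid, partners) in enumerate(sorted(TABLE1_REDUNDANT_FAMILIES.items()), 1):
        members = sorted((cid,) + partners)
        fam = CloneFamily(
            family_id=f"whole_scfv:{k:04d}",
            criterion="whole_scfv",
            members=members,
            representative=members[0],
        )
        flags[cid] = [fam]
    return flags


def synthetic_observed_counts(
    theoretical: PositionalFrequencyTable,
    hot_sets: Mapping[int, str],
    n_sequences: int = 62,
    fold: float = 3.5,
) -> PositionalFrequencyTable:
    """Synthetic count matrix whose fold-3 hot calls equal ``hot_sets``.

    Stand-in for unpublished post-selection sequence data: each hot cell gets
    ``ceil(fold * expected * n)`` counts (clearly above the 3-fold line), and
    the remainder of each position's column is spread over non-hot residues
    in proportion to the theoretical spectrum (largest-remainder rounding), so
    no non-hot cell can reach 3-fold.  Raises if the construction cannot keep
    that guarantee at the requested depth.
    """
    L = theoretical.length_class
    counts = np.zeros((L, len(AA_ALPHABET)), dtype=np.int64)
    for p in range(1, L + 1):
        exp_row = theoretical.freq.loc[p]
        hot = hot_sets.get(p, "")
        used = 0
        for a in hot:
            c = math.ceil(fold * float(exp_row[a]) * n_sequences)
            if c < 2:
                raise ValueError(
                    f"depth n={n_sequences} too low to support hot call at ({p},{a})"
                )
            counts[p - 1, AA_ALPHABET.index(a)] = c
            used += c
        if used > n_sequences:
            raise ValueError(f"hot cells at position {p} need more than n counts")
        rem = n_sequences - used
        non_hot = [a for a in AA_ALPHABET if a not in hot and float(exp_row[a]) > 0]
        wts = np.array([float(exp_row[a]) for a in non_hot])
        wts = wts / wts.sum()
        exact = wts * rem
        base = np.floor(exact).astype(np.int64)
        leftover = rem - int(base.sum())
        order = np.lexsort((np.array(non_hot), -(exact - base)))
        for i in order[:leftover]:
            base[i] += 1
        for a, c in zip(non_hot, base):
            counts[p - 1, AA_ALPHABET.index(a)] = c
            if c >= 2 and c / n_sequences >= 3.0 * float(exp_row[a]):
                raise ValueError(
                    f"construction would make non-hot cell ({p},{a}) cross 3-fold"
                )
    idx = range(1, L + 1)
    freq = counts / n_sequences
    return PositionalFrequencyTable(
        chain=theoretical.chain,
        length_class=L,
        n_sequences=n_sequences,
        freq=pd.DataFrame(freq, index=idx, columns=list(AA_ALPHABET)),
        counts=pd.DataFrame(counts, index=idx, columns=list(AA_ALPHABET)),
    )
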