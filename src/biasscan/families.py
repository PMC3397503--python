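"""Redundancy-family clustering of clones by CDR3 near-identity.

Independent colonies carrying the same (or almost the same) CDR3 are the
strongest evidence of selection: the odds of re-drawing one clone from a
~1.5e9-variant library are negligible, so recurrence implies enrichment.
Clones are grouped into families when their CDR3 domains differ by at most
``max_mutations`` (default 2, the strict reading of "less than 3 mutations"
per domain).  Distances are length-stratified Hamming distances — the
pipeline aligns by length and the library fixes loop lengths per sub-library,
so no gapped alignment is ever needed; loops of different lengths are simply
incomparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .library_model import AA_ALPHABET
from .repertoire_io import CloneRecord

__all__ = [
    "CRITERIA",
    "CloneFamily",
    "cdr3_distance",
    "cluster_families",
    "redundancy_flags",
]

CRITERIA = ("whole_scfv", "vh_only", "vl_only")
_AA_SET = frozenset(AA_ALPHABET)


@dataclass
class CloneFamily:
    family_id: str
    criterion: str
    members: list[str]
    representative: str
    max_intra_distance: int = 0

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def redundant(self) -> bool:
        return self.size >= 2


def cdr3_distance(a: str, b: str) -> Optional[int]:
    """Hamming distance between equal-length CDR3s; None when incomparable.

    Raises on characters outside the 20-letter amino-acid alphabet — masked
    or artifact-bearing sequences must be QC-filtered before clustering.
    """
    for s in (a, b):
        bad = set(s) - _AA_SET
        if bad:
            raise ValueError(f"non-amino-acid character(s) {sorted(bad)!r} in CDR3 {s!r}")
    if len(a) != len(b):
        return None
    return sum(x != y for x, y in zip(a, b))


def _domains(rec: CloneRecord, criterion: str) -> Optional[tuple[str, ...]]:
    if criterion == "vh_only":
        return (rec.vh_cdr3,) if rec.vh_cdr3 else None
    if criterion == "vl_only":
        return (rec.vl_cdr3,) if rec.vl_cdr3 else None
    if criterion == "whole_scfv":
        if rec.vh_cdr3 and rec.vl_cdr3:
            return (rec.vh_cdr3, rec.vl_cdr3)
        return None
    raise ValueError(f"unknown criterion {criterion!r}")


def _encode(seqs: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def _pairwise_linked(domain_lists: list[tuple[str, ...]], max_mutations: int) -> np.ndarray:
    """Boolean adjacency: every domain's Hamming distance <= cutoff."""
    n = len(domain_lists)
    linked = np.ones((n, n), dtype=bool)
    n_domains = len(domain_lists[0])
    for d in range(n_domains):
        enc = _encode([doms[d] for doms in domain_lists])
        dist = (enc[:, None, :] != enc[None, :, :]).sum(axis=2)
        linked &= dist <= max_mutations
    np.fill_diagonal(linked, True)
    return linked


def cluster_families(
    records: Iterable[CloneRecord],
    max_mutations: int = 2,
    criterion: str = "vh_only",
    linkage: str = "single",
) -> list[CloneFamily]:
    """Partition clones into families under the mutation cutoff.

    Two clones are linked iff each of the criterion's domains is within
    ``max_mutations`` mismatches (and the same length).  ``single`` linkage
    takes connected components of that graph (the default: the narrative
    pairs clones transitively through shared domains); ``complete`` peels off
    maximal cliques, largest first, ties broken by lexicographically smallest
    member list.  Every clone lands in exactly one family; representatives
    are the lexicographically lowest member id.
    """
    if linkage not in ("single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    records = sorted(records, key=lambda r: r.clone_id)  # canonical order
    items = []
    for rec in records:
        doms = _domains(rec, criterion)
        if doms is None:
            if criterion == "whole_scfv":
                raise ValueError(
                    f"whole_scfv clustering requires both chains; clone {rec.clone_id!r} "
                    "is missing one"
                )
            continue
        for d in doms:
            bad = set(d) - _AA_SET
            if bad:
                raise ValueError(
                    f"non-amino-acid character(s) {sorted(bad)!r} in clone {rec.clone_id!r}"
                )
        items.append((rec.clone_id, doms))

    # length stratification: only equal-length domains are comparable
    groups: dict[tuple[int, ...], list[tuple[str, tuple[str, ...]]]] = {}
    for cid, doms in items:
        groups.setdefault(tuple(len(d) for d in doms), []).append((cid, doms))

    raw_families: list[list[str]] = []
    for key in sorted(groups):
        members = groups[key]
        ids = [cid for cid, _ in members]
        doms = [d for _, d in members]
        linked = _pairwise_linked(doms, max_mutations)
        if linkage == "single":
            n_comp, labels = connected_components(csr_matrix(linked), directed=False)
            for comp in range(n_comp):
                raw_families.append([ids[i] for i in np.flatnonzero(labels == comp)])
        else:
            raw_families.extend(_greedy_cliques(ids, linked))

    raw_families = [sorted(f) for f in raw_families]
    raw_families.sort(key=lambda f: f[0])
    out = []
    by_id = {cid: doms for cid, doms in items}
    for k, fam in enumerate(raw_families, start=1):
        max_d = 0
        for i in range(len(fam)):
            for j in range(i + 1, len(fam)):
                dists = [
                    cdr3_distance(a, b)
                    for a, b in zip(by_id[fam[i]], by_id[fam[j]])
                ]
                max_d = max(max_d, max(dists))
        out.append(
            CloneFamily(
                family_id=f"{criterion}:{k:04d}",
                criterion=criterion,
                members=fam,
                representative=fam[0],
                max_intra_distance=max_d,
            )
        )
    return out


def _greedy_cliques(ids: list[str], linked: np.ndarray) -> list[list[str]]:
    """Peel maximal cliques: largest first, ties by lexicographic members."""
    g = nx.Graph()
    g.add_nodes_from(range(len(ids)))
    for i, j in zip(*np.nonzero(np.triu(linked, k=1))):
        g.add_edge(int(i), int(j))
    out = []
    remaining = g
    while remaining.number_of_nodes():
        cliques = [sorted(c, key=lambda i: ids[i]) for c in nx.find_cliques(remaining)]
        best = min(cliques, key=lambda c: (-len(c), [ids[i] for i in c]))
        out.append([ids[i] for i in best])
        remaining = remaining.subgraph(
            [n for n in remaining.nodes if n not in set(best)]
        ).copy()
    return out


def redundancy_flags(
    families: Iterable[CloneFamily],
) -> dict[str, list[CloneFamily]]:
    """Clone ids found in any family of size >= 2, with the families that fired.

    Families may come from several criteria; the union is taken and each
    flagged clone carries every (criterion, family) that linked it.
    """
    flags: dict[str, list[CloneFamily]] = {}
    for fam in families:
        if fam.redundant:
            for cid in fam.members:
                flags.setdefault(cid, []).append(fam)
    for cid in flags:
        flags[cid].sort(key=lambda f: (f.criterion, f.family_id))
    return flags
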