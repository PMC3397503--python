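"""Expected amino-acid composition of a degenerate-codon antibody library.

A semi-synthetic scFv library diversifies only the CDR3 loops, using degenerate
oligonucleotides so that each randomized position encodes a designed mixture of
amino acids.  The library is organised as sub-libraries, one per (chain, CDR3
length class); positions are numbered 1..N starting just after the invariant
``VR`` prefix of the VH loop.  This module turns a degenerate-codon design into
the *theoretical* positional amino-acid frequency table against which
post-selection repertoires are compared, and provides the sampling primitive
used by the synthetic-data generator.

Frequencies are computed exactly (as rationals) by enumerating every concrete
codon a degenerate codon expands to, translating with the standard genetic
code, and tallying.  Stop codons are handled by policy: ``renormalize``
(default) removes their mass — the physical library cannot display
stop-containing clones because sub-libraries were pre-screened for in-frame
expression — while ``keep_as_missing`` reports it separately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Data import CodonTable, IUPACData

__all__ = [
    "AA_ALPHABET",
    "CHAIN_VH",
    "CHAIN_VL_KAPPA",
    "CHAIN_VL_LAMBDA",
    "VALID_IUPAC",
    "DegenerateCodon",
    "OligoDesign",
    "SubLibrarySpec",
    "LibrarySpec",
    "PositionalFrequencyTable",
    "CodonSpectrum",
    "expand_degenerate_codon",
    "codon_aa_frequencies",
    "theoretical_table",
    "pooled_theoretical",
    "sample_cdr3",
    "analysis_chain",
    "default_library",
    "load_library",
    "dump_library",
]

#: The 20 standard amino acids, alphabetical one-letter order.  All frequency
#: tables use this column order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

CHAIN_VH = "VH"
CHAIN_VL_KAPPA = "VL_kappa"
CHAIN_VL_LAMBDA = "VL_lambda"
CHAINS = (CHAIN_VH, CHAIN_VL_KAPPA, CHAIN_VL_LAMBDA)

#: IUPAC nucleotide ambiguity codes accepted in degenerate codons.
VALID_IUPAC = frozenset("ACGTRYSWKMBDHVN")

_IUPAC_SETS: Mapping[str, str] = {
    s: IUPACData.ambiguous_dna_values[s] for s in VALID_IUPAC
}
_STANDARD_CODE = CodonTable.unambiguous_dna_by_id[1]
_STOP_CODONS = frozenset(_STANDARD_CODE.stop_codons)

STOP_POLICIES = ("renormalize", "keep_as_missing")


@dataclass(frozen=True)
class DegenerateCodon:
    """One codon written in IUPAC ambiguity codes, e.g. ``NNK``."""

    symbols: str

    def __post_init__(self) -> None:
        s = self.symbols.upper()
        if len(s) != 3:
            raise ValueError(f"degenerate codon must have 3 symbols, got {self.symbols!r}")
        for ch in s:
            if ch not in VALID_IUPAC:
                raise ValueError(
                    f"invalid IUPAC nucleotide code {ch!r} in codon {self.symbols!r}"
                )
        object.__setattr__(self, "symbols", s)

    @property
    def degeneracy(self) -> int:
        """Number of concrete codons in the expansion (1..64)."""
        return math.prod(len(_IUPAC_SETS[c]) for c in self.symbols)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.symbols


@dataclass(frozen=True)
class OligoDesign:
    """Ordered degenerate codons, one per randomized CDR3 position."""

    codons: tuple[DegenerateCodon, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "codons",
            tuple(c if isinstance(c, DegenerateCodon) else DegenerateCodon(c) for c in self.codons),
        )

    def __len__(self) -> int:
        return len(self.codons)


@dataclass
class PositionalFrequencyTable:
    """Per-position amino-acid proportions for one (chain, length class).

    ``n_sequences`` is 0 for theoretical (design-derived) tables.  ``freq`` is
    indexed by position 1..length_class (numbered just after the invariant
    prefix) with the 20 amino acids as columns; each row sums to 1 unless the
    position observed no residue at all, in which case it is all-zero.
    ``counts`` optionally carries the integer count matrix behind an observed
    table.
    """

    chain: str
    length_class: int
    n_sequences: int
    freq: pd.DataFrame
    counts: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.freq = self.freq.astype(float)

    def validate(self, atol: float = 1e-9) -> None:
        if list(self.freq.columns) != list(AA_ALPHABET):
            raise ValueError("frequency table columns must be the 20 amino acids, alphabetical")
        if list(self.freq.index) != list(range(1, self.length_class + 1)):
            raise ValueError("frequency table rows must be positions 1..length_class")
        if (self.freq.values < 0).any():
            raise ValueError("frequencies must be non-negative")
        sums = self.freq.sum(axis=1).values
        for pos, s in zip(self.freq.index, sums):
            if not (abs(s - 1.0) <= atol or s == 0.0):
                raise ValueError(f"row sum at position {pos} is {s!r}, expected 1 (or all-zero)")

    def zero_positions(self) -> list[int]:
        """Positions with no observed residue (all-zero rows)."""
        return [int(p) for p, s in self.freq.sum(axis=1).items() if s == 0.0]

    def copy(self) -> "PositionalFrequencyTable":
        return PositionalFrequencyTable(
            chain=self.chain,
            length_class=self.length_class,
            n_sequences=self.n_sequences,
            freq=self.freq.copy(),
            counts=None if self.counts is None else self.counts.copy(),
        )


@dataclass
class SubLibrarySpec:
    """One sub-library: a chain, a CDR3 length class, and its design.

    Exactly one of ``design`` (degenerate codons) or ``frequencies`` (an
    explicit per-position table, used when the oligonucleotide scheme is known
    only through its translated spectrum) must be given.
    """

    chain: str
    length_class: int
    weight: float = 1.0
    design: Optional[OligoDesign] = None
    frequencies: Optional[PositionalFrequencyTable] = None

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}; expected one of {CHAINS}")
        if self.length_class < 1:
            raise ValueError("length_class must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if (self.design is None) == (self.frequencies is None):
            raise ValueError("exactly one of design/frequencies must be provided")
        if self.design is not None and len(self.design) != self.length_class:
            raise ValueError(
                f"design has {len(self.design)} codons but length_class is {self.length_class}"
            )
        if self.frequencies is not None:
            if self.frequencies.length_class != self.length_class:
                raise ValueError("explicit frequency table length mismatch")
            self.frequencies.validate()


@dataclass
class LibrarySpec:
    """The designed library: sub-libraries plus bookkeeping.

    ``diversity_estimate`` (the ~1.5e9 variants of the source library) is
    metadata only and never computed.  Mixing weights are normalized within
    each analysis chain group (VH; VL = kappa + lambda pooled).
    """

    sublibraries: list[SubLibrarySpec]
    invariant_prefix: str = "VR"
    diversity_estimate: Optional[float] = None

    def __post_init__(self) -> None:
        seen = set()
        for sub in self.sublibraries:
            key = (sub.chain, sub.length_class)
            if key in seen:
                raise ValueError(f"duplicate sub-library for {key}")
            seen.add(key)

    def group(self, chain_group: str) -> list[SubLibrarySpec]:
        """Sub-libraries of one analysis chain group ('VH' or 'VL'), sorted."""
        subs = [s for s in self.sublibraries if analysis_chain(s.chain) == chain_group]
        return sorted(subs, key=lambda s: (s.length_class, s.chain))

    def normalized_weights(self, chain_group: str) -> dict[tuple[str, int], float]:
        subs = self.group(chain_group)
        total = sum(s.weight for s in subs)
        if not subs:
            return {}
        if total == 0:
            warnings.warn(
                f"all {chain_group} sub-library weights are zero; falling back to uniform mixing"
            )
            return {(s.chain, s.length_class): 1.0 / len(subs) for s in subs}
        return {(s.chain, s.length_class): s.weight / total for s in subs}

    def length_classes(self, chain_group: str) -> list[int]:
        return sorted({s.length_class for s in self.group(chain_group)})

    def prefix_for(self, chain_group: str) -> str:
        return self.invariant_prefix if chain_group == "VH" else ""


def analysis_chain(chain: str) -> str:
    """Collapse the kappa/lambda distinction: analysis sees 'VH' or 'VL'."""
    return "VH" if chain == CHAIN_VH else "VL"


# ---------------------------------------------------------------------------
# Codon arithmetic
# ---------------------------------------------------------------------------

def _as_codon(codon: "DegenerateCodon | str") -> DegenerateCodon:
    return codon if isinstance(codon, DegenerateCodon) else DegenerateCodon(codon)


def expand_degenerate_codon(codon: "DegenerateCodon | str") -> dict[str, int]:
    """Enumerate the concrete codons a degenerate codon stands for.

    Returns a mapping concrete codon -> multiplicity (all 1: the expansion is
    the plain Cartesian product of the per-symbol nucleotide sets).
    """
    codon = _as_codon(codon)
    out = {}
    for bases in product(*(_IUPAC_SETS[s] for s in codon.symbols)):
        out["".join(bases)] = 1
    return out


@dataclass(frozen=True)
class CodonSpectrum:
    """Exact translated spectrum of one degenerate codon.

    ``freq`` maps every one of the 20 amino acids to an exact Fraction;
    ``stop_mass`` is the stop-codon fraction (0 under ``renormalize``).
    """

    freq: Mapping[str, Fraction]
    stop_mass: Fraction

    def as_array(self) -> np.ndarray:
        return np.array([float(self.freq[a]) for a in AA_ALPHABET])


def codon_aa_frequencies(
    codon: "DegenerateCodon | str", stop_policy: str = "renormalize"
) -> CodonSpectrum:
    """Amino-acid frequency vector encoded by a degenerate codon.

    With ``stop_policy='renormalize'`` the stop-codon mass is removed and the
    amino-acid frequencies renormalized to sum to 1 (a codon expanding only to
    stops is an error).  With ``keep_as_missing`` amino-acid mass sums to
    ``1 - stop_mass``.
    """
    if stop_policy not in STOP_POLICIES:
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    codon = _as_codon(codon)
    counts = {a: 0 for a in AA_ALPHABET}
    stops = 0
    for concrete in expand_degenerate_codon(codon):
        if concrete in _STOP_CODONS:
            stops += 1
        else:
            counts[_STANDARD_CODE.forward_table[concrete]] += 1
    total = codon.degeneracy
    if stop_policy == "renormalize":
        coding = total - stops
        if coding == 0:
            raise ValueError(
                f"codon {codon.symbols} expands only to stop codons; no amino acid to renormalize over"
            )
        freq = {a: Fraction(c, coding) for a, c in counts.items()}
        return CodonSpectrum(freq=freq, stop_mass=Fraction(0))
    freq = {a: Fraction(c, total) for a, c in counts.items()}
    return CodonSpectrum(freq=freq, stop_mass=Fraction(stops, total))


def theoretical_table(
    sub: SubLibrarySpec, stop_policy: str = "renormalize"
) -> PositionalFrequencyTable:
    """Expected positional frequency table of one sub-library.

    Position p's row is the translated spectrum of the p-th degenerate codon;
    ``n_sequences = 0`` marks the table as theoretical.  A sub-library given as
    an explicit frequency table is returned as a validated copy.
    """
    if sub.frequencies is not None:
        out = sub.frequencies.copy()
        out.n_sequences = 0
        out.validate()
        return out
    rows = [codon_aa_frequencies(c, stop_policy).as_array() for c in sub.design.codons]
    freq = pd.DataFrame(
        np.vstack(rows),
        index=range(1, sub.length_class + 1),
        columns=list(AA_ALPHABET),
    )
    table = PositionalFrequencyTable(
        chain=sub.chain, length_class=sub.length_class, n_sequences=0, freq=freq
    )
    table.validate()
    return table


def pooled_theoretical(
    library: LibrarySpec,
    chain_group: str,
    length_class: int,
    stop_policy: str = "renormalize",
) -> PositionalFrequencyTable:
    """Weight-mixed theoretical table for one analysis chain and length class.

    VL kappa and lambda sub-libraries of the same loop length are pooled by
    their (renormalized) mixing weights, because sequenced clones do not carry
    the kappa/lambda label at the CDR3-table level.
    """
    subs = [s for s in library.group(chain_group) if s.length_class == length_class]
    if not subs:
        raise KeyError(f"no {chain_group} sub-library of length {length_class}")
    tables = [theoretical_table(s, stop_policy) for s in subs]
    if len(tables) == 1:
        out = tables[0].copy()
        out.chain = chain_group
        return out
    weights = np.array([s.weight for s in subs], dtype=float)
    if weights.sum() == 0:
        weights = np.ones_like(weights)
    weights = weights / weights.sum()
    mixed = sum(w * t.freq for w, t in zip(weights, tables))
    out = PositionalFrequencyTable(
        chain=chain_group, length_class=length_class, n_sequences=0, freq=mixed
    )
    out.validate()
    return out


def sample_cdr3(
    sub: SubLibrarySpec,
    rng: "np.random.Generator | int",
    stop_policy: str = "renormalize",
    n: Optional[int] = None,
) -> "str | list[str]":
    """Draw CDR3 string(s) from a sub-library's theoretical distribution.

    Each position is drawn independently from that position's row.  With
    ``n=None`` one string is returned; otherwise a list of ``n`` (drawn
    vectorized, so large samples are cheap).  Reproducible: the same integer
    seed gives the same draw.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    table = theoretical_table(sub, stop_policy)
    count = 1 if n is None else n
    aa = np.array(list(AA_ALPHABET))
    mat = np.empty((count, sub.length_class), dtype="<U1")
    for p in range(1, sub.length_class + 1):
        mat[:, p - 1] = rng.choice(aa, size=count, p=table.freq.loc[p].values)
    seqs = ["".join(row) for row in mat]
    return seqs[0] if n is None else seqs


# ---------------------------------------------------------------------------
# Default library and YAML round-trip
# ---------------------------------------------------------------------------

def default_library() -> LibrarySpec:
    """A stand-in for the source library's unpublished oligonucleotide design.

    13 VH sub-libraries with loops of 5..17 randomized positions after the
    invariant VR prefix, and 5 VL sub-libraries (kappa 9-10, lambda 9-11),
    every position NNK.  The true per-position codon scheme is not public, so
    NNK is used as an explicit stand-in; real designs (or explicit frequency
    tables) can be dropped in via the YAML config.  VH weights follow a
    discretized bell over loop length centred near the most common natural
    CDR3-H lengths; VL weights split kappa/lambda roughly 60:40.
    """
    subs: list[SubLibrarySpec] = []
    vh_lengths = list(range(5, 18))
    raw = np.exp(-((np.array(vh_lengths) - 12.0) ** 2) / (2 * 2.5**2))
    vh_weights = raw / raw.sum()
    for L, w in zip(vh_lengths, vh_weights):
        subs.append(
            SubLibrarySpec(
                chain=CHAIN_VH,
                length_class=L,
                weight=float(w),
                design=OligoDesign(tuple(DegenerateCodon("NNK") for _ in range(L))),
            )
        )
    vl_spec = [
        (CHAIN_VL_KAPPA, 9, 0.35),
        (CHAIN_VL_KAPPA, 10, 0.25),
        (CHAIN_VL_LAMBDA, 9, 0.15),
        (CHAIN_VL_LAMBDA, 10, 0.15),
        (CHAIN_VL_LAMBDA, 11, 0.10),
    ]
    for chain, L, w in vl_spec:
        subs.append(
            SubLibrarySpec(
                chain=chain,
                length_class=L,
                weight=w,
                design=OligoDesign(tuple(DegenerateCodon("NNK") for _ in range(L))),
            )
        )
    return LibrarySpec(
        sublibraries=subs, invariant_prefix="VR", diversity_estimate=1.5e9
    )


def dump_library(library: LibrarySpec, path) -> None:
    """Write a library design to YAML (codons spelled out per position)."""
    doc = {
        "invariant_prefix": library.invariant_prefix,
        "diversity_estimate": library.diversity_estimate,
        "sublibraries": [
            {
                "chain": s.chain,
                "length_class": s.length_class,
                "weight": s.weight,
                "codons": [c.symbols for c in s.design.codons]
                if s.design is not None
                else None,
            }
            for s in library.sublibraries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_library(path) -> LibrarySpec:
    """Read a library design from YAML.

    ``codons`` may be a list (one IUPAC codon per position) or a single codon
    string applied to every position.  Missing weights fall back to uniform
    mixing, with a warning.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    subs = []
    missing_weight = False
    for entry in doc["sublibraries"]:
        codons = entry["codons"]
        L = int(entry["length_class"])
        if isinstance(codons, str):
            codons = [codons] * L
        weight = entry.get("weight")
        if weight is None:
            missing_weight = True
            weight = 1.0
        subs.append(
            SubLibrarySpec(
                chain=entry["chain"],
                length_class=L,
                weight=float(weight),
                design=OligoDesign(tuple(DegenerateCodon(c) for c in codons)),
            )
        )
    if missing_weight:
        warnings.warn("sub-library weights missing in config; using uniform fallback")
    return LibrarySpec(
        sublibraries=subs,
        invariant_prefix=doc.get("invariant_prefix", "VR"),
        diversity_estimate=doc.get("diversity_estimate"),
    )
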