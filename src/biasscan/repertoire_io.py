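"""Clone I/O, anchor-based CDR3 extraction, and QC filtering.

Sequenced colony picks arrive either as pre-extracted CDR3 tables (TSV) or as
FASTA (nucleotide or amino acid).  Because the library is built on a single
fixed scFv framework, CDR3 delineation reduces to deterministic anchor
extraction: the loop is the substring strictly between a unique upstream and a
unique downstream framework anchor, with the invariant ``VR`` prefix stripped
for VH.  The QC filter plays the role of the colony-PCR screen in the wet
protocol: clones with missing anchors, internal stops, or loop lengths outside
the declared length classes are rejected with a reason.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .library_model import AA_ALPHABET, PositionalFrequencyTable

__all__ = [
    "QC_OK",
    "QC_ANCHOR_MISSING",
    "QC_INTERNAL_STOP",
    "QC_FRAMESHIFT_LENGTH",
    "QC_DUPLICATE_READ",
    "FRACTIONS",
    "CloneRecord",
    "AnchorSpec",
    "ExtractionResult",
    "QCReport",
    "DEFAULT_VH_ANCHORS",
    "DEFAULT_VL_ANCHORS",
    "SCAFFOLD",
    "extract_cdr3",
    "read_clones",
    "write_clones",
    "qc_filter",
    "write_frequency_table",
    "read_frequency_table",
]

QC_OK = "ok"
QC_ANCHOR_MISSING = "anchor_missing"
QC_INTERNAL_STOP = "internal_stop"
QC_FRAMESHIFT_LENGTH = "frameshift_length"
QC_DUPLICATE_READ = "duplicate_read"

FRACTIONS = ("F1", "F2", "F3", "native")

_ROUND_RE = re.compile(r"^round(\d+)$", re.IGNORECASE)


@dataclass
class CloneRecord:
    """One sequenced clone: CDR3s plus fraction/round bookkeeping.

    ``fraction`` is the recovery compartment (F1 endothelial-surface, F2
    intra-tissular, F3 internalized) or ``native`` for unselected library
    material; ``round`` is the biopanning round the colony was picked from.
    """

    clone_id: str
    fraction: str = "native"
    round: int = 0
    vh_cdr3: Optional[str] = None
    vl_cdr3: Optional[str] = None
    vh_length_class: Optional[int] = None
    vl_length_class: Optional[int] = None
    qc: set = field(default_factory=lambda: {QC_OK})

    def __post_init__(self) -> None:
        if self.vh_cdr3 is not None and self.vh_length_class is None:
            self.vh_length_class = len(self.vh_cdr3)
        if self.vl_cdr3 is not None and self.vl_length_class is None:
            self.vl_length_class = len(self.vl_cdr3)

    def cdr3(self, chain_group: str) -> Optional[str]:
        return self.vh_cdr3 if chain_group == "VH" else self.vl_cdr3


@dataclass(frozen=True)
class AnchorSpec:
    """Framework anchors bracketing one chain's CDR3 in the fixed scaffold."""

    upstream: str
    downstream: str
    chain: str = "VH"

    def __post_init__(self) -> None:
        if not self.upstream or not self.downstream:
            raise ValueError("anchors must be non-empty")


# Synthetic stand-in scaffold for the fixed scFv framework; the generator
# assembles full-length clones from these parts and extraction inverts it.
SCAFFOLD = {
    "vh_framework": (
        "EVQLVESGGGLVQPGGSLRLSCAASGFTFSDYWMSWVRQAPGKGLEWVGEINPDSSTINYTPSLKDK"
        "FIISRDNAKNSLYLQMNSLRAEDTAVYYCA"
    ),
    "vh_downstream": "WGQGTLVTVSS",
    "linker": "GGGGSGGGGSGGGGS",
    "vl_framework": (
        "DIQMTQSPSSLSASVGDRVTITCRASQSISSYLNWYQQKPGKAPKLLIYAASSLQSGVPSRFSGSGS"
        "GTDFTLTISSLQPEDFATYYC"
    ),
    "vl_downstream": "FGQGTKVEIK",
}

DEFAULT_VH_ANCHORS = AnchorSpec(upstream="AVYYCA", downstream="WGQGT", chain="VH")
DEFAULT_VL_ANCHORS = AnchorSpec(upstream="FATYYC", downstream="FGQGT", chain="VL")


@dataclass(frozen=True)
class ExtractionResult:
    cdr3: Optional[str]
    status: str  # "ok" or "anchor_missing"
    prefix_stripped: bool


def extract_cdr3(
    sequence: str, anchors: AnchorSpec, invariant_prefix: str = "VR"
) -> ExtractionResult:
    """Extract the CDR3 strictly between the two framework anchors.

    Either anchor absent, or present more than once (ambiguous), gives status
    ``anchor_missing`` — never a silent choice.  If the extracted substring
    begins with the invariant prefix it is stripped and the fact recorded.
    """
    up, down = anchors.upstream, anchors.downstream
    if sequence.count(up) != 1 or sequence.count(down) != 1:
        return ExtractionResult(None, QC_ANCHOR_MISSING, False)
    start = sequence.index(up) + len(up)
    end = sequence.index(down)
    if end < start:
        return ExtractionResult(None, QC_ANCHOR_MISSING, False)
    loop = sequence[start:end]
    stripped = False
    if invariant_prefix and loop.startswith(invariant_prefix):
        loop = loop[len(invariant_prefix):]
        stripped = True
    return ExtractionResult(loop, QC_OK, stripped)


def _parse_header(header: str) -> tuple[str, str, int]:
    """Parse ``clone_id|fraction|roundN`` pipe-delimited FASTA header tokens."""
    tokens = header.split("|")
    clone_id = tokens[0]
    fraction = "native"
    rnd = 0
    unknown = []
    for tok in tokens[1:]:
        m = _ROUND_RE.match(tok)
        if m:
            rnd = int(m.group(1))
        elif tok in FRACTIONS:
            fraction = tok
        elif tok:
            unknown.append(tok)
    if unknown:
        warnings.warn(
            f"unknown header token(s) {unknown!r} for record {clone_id!r}; fraction kept as {fraction!r}"
        )
    return clone_id, fraction, rnd


def read_clones(
    path,
    format: str,
    vh_anchors: Optional[AnchorSpec] = None,
    vl_anchors: Optional[AnchorSpec] = None,
    invariant_prefix: str = "VR",
) -> list[CloneRecord]:
    """Read clone records from TSV or FASTA.

    ``cdr3_tsv`` expects columns clone_id, vh_cdr3, vl_cdr3, fraction, round
    (the CDR3 columns may be empty).  FASTA input is translated first when
    nucleotide (``fasta_nt``, declared frame 0) and CDR3s are then located by
    anchor search; anchors default to the synthetic scaffold's.  Duplicate
    reads (same clone_id and identical sequences) are collapsed onto one
    record flagged ``duplicate_read``.
    """
    if format == "cdr3_tsv":
        records = _read_cdr3_tsv(path)
    elif format in ("fasta_aa", "fasta_nt"):
        records = _read_fasta(
            path,
            translate=(format == "fasta_nt"),
            vh_anchors=vh_anchors or DEFAULT_VH_ANCHORS,
            vl_anchors=vl_anchors,
            invariant_prefix=invariant_prefix,
        )
    else:
        raise ValueError(f"unknown clone format {format!r}")
    if not records:
        warnings.warn(f"no clone records read from {path}")
    return _collapse_duplicates(records)


def _read_cdr3_tsv(path) -> list[CloneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and "clone_id" not in df.columns:
        return []
    if "clone_id" not in df.columns:
        raise ValueError("cdr3_tsv must have a clone_id column")
    records = []
    for _, row in df.iterrows():
        fraction = row.get("fraction", "native") or "native"
        if fraction not in FRACTIONS:
            warnings.warn(
                f"unknown fraction token {fraction!r} for clone {row['clone_id']!r}; kept as native"
            )
            fraction = "native"
        records.append(
            CloneRecord(
                clone_id=row["clone_id"],
                fraction=fraction,
                round=int(row["round"]) if row.get("round", "") != "" else 0,
                vh_cdr3=row.get("vh_cdr3") or None,
                vl_cdr3=row.get("vl_cdr3") or None,
            )
        )
    return records


def _read_fasta(
    path, translate: bool, vh_anchors: AnchorSpec, vl_anchors: Optional[AnchorSpec],
    invariant_prefix: str,
) -> list[CloneRecord]:
    records = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"malformed FASTA: empty sequence at record {idx} ({rec.id!r})")
        if translate:
            seq = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
        clone_id, fraction, rnd = _parse_header(rec.description.split()[0])
        qc = set()
        vh = extract_cdr3(seq, vh_anchors, invariant_prefix)
        if vh.status != QC_OK:
            qc.add(QC_ANCHOR_MISSING)
        vl = None
        if vl_anchors is not None:
            vl = extract_cdr3(seq, vl_anchors, invariant_prefix="")
            if vl.status != QC_OK:
                qc.add(QC_ANCHOR_MISSING)
        records.append(
            CloneRecord(
                clone_id=clone_id,
                fraction=fraction,
                round=rnd,
                vh_cdr3=vh.cdr3,
                vl_cdr3=None if vl is None else vl.cdr3,
                qc=qc or {QC_OK},
            )
        )
    return records


def _collapse_duplicates(records: list[CloneRecord]) -> list[CloneRecord]:
    seen: dict[tuple, CloneRecord] = {}
    out = []
    for rec in records:
        key = (rec.clone_id, rec.vh_cdr3, rec.vl_cdr3)
        if key in seen:
            seen[key].qc.add(QC_DUPLICATE_READ)
        else:
            seen[key] = rec
            out.append(rec)
    return out


def write_clones(records: Iterable[CloneRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "clone_id": r.clone_id,
                "fraction": r.fraction,
                "round": r.round,
                "vh_cdr3": r.vh_cdr3 or "",
                "vl_cdr3": r.vl_cdr3 or "",
            }
            for r in records
        ],
        columns=["clone_id", "fraction", "round", "vh_cdr3", "vl_cdr3"],
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class QCReport:
    passing: list[CloneRecord]
    rejected: list[CloneRecord]
    reasons: Counter

    @property
    def pass_rate(self) -> float:
        n = len(self.passing) + len(self.rejected)
        return len(self.passing) / n if n else float("nan")


_AA_SET = frozenset(AA_ALPHABET)


def _chain_problems(cdr3: Optional[str], classes: Optional[set]) -> list[str]:
    if cdr3 is None:
        return []
    problems = []
    if "*" in cdr3:
        problems.append(QC_INTERNAL_STOP)
    if classes is not None and len(cdr3) not in classes:
        problems.append(QC_FRAMESHIFT_LENGTH)
    return problems


def qc_filter(
    records: Iterable[CloneRecord],
    vh_length_classes: Optional[Iterable[int]] = None,
    vl_length_classes: Optional[Iterable[int]] = None,
) -> QCReport:
    """Split records into passing and rejected, with per-reason counts.

    Mirrors the colony-PCR screen: rejects missing/ambiguous anchors, internal
    stop codons, and CDR3 lengths outside the declared length classes.
    Passing records are returned untouched; rejected ones are copies with the
    failure flags added.  ``|passing| + |rejected| == |input|`` always.
    """
    vh_classes = set(vh_length_classes) if vh_length_classes is not None else None
    vl_classes = set(vl_length_classes) if vl_length_classes is not None else None
    passing, rejected, reasons = [], [], Counter()
    for rec in records:
        problems = []
        if QC_ANCHOR_MISSING in rec.qc or (rec.vh_cdr3 is None and rec.vl_cdr3 is None):
            problems.append(QC_ANCHOR_MISSING)
        problems += _chain_problems(rec.vh_cdr3, vh_classes)
        problems += _chain_problems(rec.vl_cdr3, vl_classes)
        if problems:
            bad = replace(rec, qc=(rec.qc - {QC_OK}) | set(problems))
            rejected.append(bad)
            for p in sorted(set(problems)):
                reasons[p] += 1
        else:
            passing.append(rec)
    return QCReport(passing=passing, rejected=rejected, reasons=reasons)


# ---------------------------------------------------------------------------
# Frequency-table TSV round trip
# ---------------------------------------------------------------------------

def write_frequency_table(table: PositionalFrequencyTable, path) -> None:
    """Write one table as TSV with a small metadata header.

    Values are printed with 12 significant digits, which round-trips through
    ``read_frequency_table`` losslessly at that precision.
    """
    table.validate()
    with open(path, "w") as fh:
        fh.write(f"# chain={table.chain}\n")
        fh.write(f"# length_class={table.length_class}\n")
        fh.write(f"# n_sequences={table.n_sequences}\n")
        fh.write("position\t" + "\t".join(AA_ALPHABET) + "\n")
        for pos in table.freq.index:
            vals = "\t".join(f"{v:.12g}" for v in table.freq.loc[pos].values)
            fh.write(f"{pos}\t{vals}\n")


def read_frequency_table(path) -> PositionalFrequencyTable:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", index_col="position")
    table = PositionalFrequencyTable(
        chain=meta.get("chain", "VH"),
        length_class=int(meta.get("length_class", len(df))),
        n_sequences=int(meta.get("n_sequences", 0)),
        freq=df,
    )
    table.validate(atol=1e-9)
    return table
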