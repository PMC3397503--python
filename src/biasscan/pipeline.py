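"""End-to-end pipeline: QC -> frequencies -> enrichment -> consensus ->
scoring -> families -> selection, plus report rendering.

`run_pipeline` executes the stages in a fixed order on a clone table and a
library design and returns everything the reports need; `render_report`
writes deterministic TSV and markdown artifacts (two runs with identical
config and inputs produce byte-identical files).  `run_table1` reproduces
the published worked example from the packaged fixture: scoring the printed
clone rows against the printed consensus selects exactly the thirteen
published clones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from .enrichment import (
    CloneScore,
    ConsensusProfile,
    EnrichmentProfile,
    SelectionResult,
    call_hot_positions,
    enrichment_ratios,
    observed_frequencies,
    score_clone,
    select_clones,
)
from .families import CloneFamily, cluster_families, redundancy_flags
from .fixtures import table1_clones, table1_consensus, table1_redundancy
from .library_model import LibrarySpec, default_library, load_library, pooled_theoretical
from .repertoire_io import CloneRecord, QCReport, qc_filter, read_clones

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_table1", "render_report"]

logger = logging.getLogger("biasscan")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; echoed verbatim into the run report."""

    clones_path: Optional[str] = None
    clones_format: str = "cdr3_tsv"
    library_path: Optional[str] = None
    outdir: Optional[str] = None
    fold_threshold: float = 3.0
    min_count: int = 2
    min_class_n: int = 10
    min_matches: int = 3
    max_mutations: int = 2
    linkage: str = "single"
    stop_policy: str = "renormalize"
    per_fraction: bool = False
    rounds: Optional[list[int]] = None  # restrict analysis to these rounds

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.min_count < 1 or self.min_class_n < 1 or self.min_matches < 0:
            raise ValueError("count thresholds out of range")
        if self.max_mutations < 0:
            raise ValueError("max_mutations must be non-negative")
        if self.linkage not in ("single", "complete"):
            raise ValueError(f"unknown linkage {self.linkage!r}")


@dataclass
class PipelineResult:
    config: RunConfig
    qc: QCReport
    consensus: dict[tuple[str, int], ConsensusProfile]
    profiles: dict[tuple[str, int], EnrichmentProfile]
    families: list[CloneFamily]
    selection: list[SelectionResult]
    clone_index: dict[str, CloneRecord] = field(default_factory=dict)

    @property
    def selected_ids(self) -> list[str]:
        return [r.clone_id for r in self.selection if r.selected]


def _analysis_records(records: list[CloneRecord], config: RunConfig) -> list[CloneRecord]:
    if config.rounds is None:
        return records
    keep = set(config.rounds)
    return [r for r in records if r.round in keep]


def run_pipeline(
    config: RunConfig,
    records: Optional[list[CloneRecord]] = None,
    library: Optional[LibrarySpec] = None,
) -> PipelineResult:
    """Execute the full selection pipeline.

    Clones and library may be passed in memory or read from the paths in
    ``config``.  Fractions are pooled per length class by default (the
    published analysis mixed fractions within a class); ``per_fraction=True``
    additionally restricts each class's observed table to one fraction at a
    time and keys the consensus by it — not used by the headline pipeline.
    """
    if records is None:
        if config.clones_path is None:
            raise ValueError("no clone records and no clones_path configured")
        records = read_clones(config.clones_path, config.clones_format)
    if library is None:
        library = load_library(config.library_path) if config.library_path else default_library()

    records = _analysis_records(records, config)
    vh_classes = library.length_classes("VH")
    vl_classes = library.length_classes("VL")
    qc = qc_filter(records, vh_length_classes=vh_classes or None,
                   vl_length_classes=vl_classes or None)
    logger.info(
        "QC: %d/%d passing (%s)", len(qc.passing), len(qc.passing) + len(qc.rejected),
        dict(qc.reasons),
    )
    passing = qc.passing

    profiles: dict[tuple[str, int], EnrichmentProfile] = {}
    consensus: dict[tuple[str, int], ConsensusProfile] = {}
    for chain, classes in (("VH", vh_classes), ("VL", vl_classes)):
        for L in classes:
            observed = observed_frequencies(passing, chain, L)
            if observed.n_sequences == 0:
                logger.info("no sequences for %s length %d; skipped", chain, L)
                continue
            theoretical = pooled_theoretical(library, chain, L, config.stop_policy)
            profile = enrichment_ratios(observed, theoretical)
            profiles[(chain, L)] = profile
            cons = call_hot_positions(
                profile,
                fold_threshold=config.fold_threshold,
                min_count=config.min_count,
                min_class_n=config.min_class_n,
            )
            if cons.insufficient:
                logger.info(
                    "%s length %d: %d sequences < min_class_n=%d; consensus empty",
                    chain, L, observed.n_sequences, config.min_class_n,
                )
            consensus[(chain, L)] = cons

    families: list[CloneFamily] = []
    have_vh = any(r.vh_cdr3 for r in passing)
    have_vl = any(r.vl_cdr3 for r in passing)
    criteria = []
    if have_vh and have_vl:
        criteria.append("whole_scfv")
    if have_vh:
        criteria.append("vh_only")
    if have_vl:
        criteria.append("vl_only")
    def _clusterable(rec: CloneRecord, criterion: str) -> bool:
        if criterion == "whole_scfv":
            return bool(rec.vh_cdr3 and rec.vl_cdr3)
        return bool(rec.vh_cdr3 if criterion == "vh_only" else rec.vl_cdr3)

    for criterion in criteria:
        usable = [r for r in passing if _clusterable(r, criterion)]
        families.extend(
            cluster_families(
                usable,
                max_mutations=config.max_mutations,
                criterion=criterion,
                linkage=config.linkage,
            )
        )
    flags = redundancy_flags(families)

    scores: list[CloneScore] = []
    for rec in sorted(passing, key=lambda r: r.clone_id):
        score = CloneScore(clone_id=rec.clone_id, match_count=0, matched_positions=[])
        key = None
        if rec.vh_cdr3 is not None:
            key = ("VH", len(rec.vh_cdr3))
        elif rec.vl_cdr3 is not None:
            key = ("VL", len(rec.vl_cdr3))
        if key in consensus:
            chain, L = key
            cdr3 = rec.cdr3(chain)
            score = score_clone(cdr3, consensus[key], clone_id=rec.clone_id)
        scores.append(score)

    selection = select_clones(scores, flags, min_matches=config.min_matches)
    return PipelineResult(
        config=config,
        qc=qc,
        consensus=consensus,
        profiles=profiles,
        families=families,
        selection=selection,
        clone_index={r.clone_id: r for r in passing},
    )


def run_table1(min_matches: int = 3) -> PipelineResult:
    """Reproduce the published worked example from the packaged fixture.

    Scores the printed clone rows against the printed per-length consensus
    and applies the combined redundancy-or-bias rule.  No sequence data and
    no network: completes in well under a second.
    """
    consensus = {("VH", L): table1_consensus(L) for L in (10, 13, 14)}
    flags = table1_redundancy()
    scores = []
    clone_index = {}
    for cid, L, masked in table1_clones():
        scores.append(score_clone(masked, consensus[("VH", L)], clone_id=cid))
        clone_index[cid] = CloneRecord(
            clone_id=cid, fraction=cid.split(".")[-1] if cid.count(".") == 2 else "native",
            round=2, vh_cdr3=masked,
        )
    selection = select_clones(scores, flags, min_matches=min_matches)
    families = sorted(
        {f.family_id: f for fams in flags.values() for f in fams}.values(),
        key=lambda f: f.family_id,
    )
    config = RunConfig(min_matches=min_matches)
    return PipelineResult(
        config=config,
        qc=QCReport(passing=list(clone_index.values()), rejected=[], reasons={}),
        consensus=consensus,
        profiles={},
        families=list(families),
        selection=selection,
        clone_index=clone_index,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _selection_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for r in result.selection:
        rec = result.clone_index.get(r.clone_id)
        rows.append(
            {
                "clone_id": r.clone_id,
                "length_class": (len(rec.vh_cdr3) if rec and rec.vh_cdr3 else
                                 (len(rec.vl_cdr3) if rec and rec.vl_cdr3 else "")),
                "fraction": rec.fraction if rec else "",
                "match_count": r.score.match_count,
                "matched_positions": ";".join(
                    f"{p}{a}" for p, a in r.score.matched_positions
                ),
                "family_ids": ";".join(r.family_ids),
                "reasons": ";".join(sorted(r.reasons)),
                "selected": int(r.selected),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "clone_id", "length_class", "fraction", "match_count",
            "matched_positions", "family_ids", "reasons", "selected",
        ],
    )


def render_report(
    result: PipelineResult, outdir, formats: tuple[str, ...] = ("tsv", "markdown")
) -> list[Path]:
    """Write the report bundle; deterministic byte-for-byte given the inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    sel = _selection_frame(result)

    if "tsv" in formats:
        p = outdir / "selection.tsv"
        sel.to_csv(p, sep="\t", index=False)
        paths.append(p)
        fam_rows = [
            {
                "family_id": f.family_id,
                "criterion": f.criterion,
                "size": f.size,
                "members": ";".join(f.members),
                "representative": f.representative,
                "max_intra_distance": f.max_intra_distance,
            }
            for f in result.families
        ]
        p = outdir / "families.tsv"
        pd.DataFrame(
            fam_rows,
            columns=["family_id", "criterion", "size", "members",
                     "representative", "max_intra_distance"],
        ).to_csv(p, sep="\t", index=False)
        paths.append(p)
        cons_rows = []
        for (chain, L), cons in sorted(result.consensus.items()):
            prefix = "VR" if chain == "VH" else ""
            cons_rows.append(
                {
                    "chain": chain,
                    "length_class": L,
                    "n_sequences": cons.n_sequences,
                    "insufficient": int(cons.insufficient),
                    "consensus": cons.render(prefix=prefix),
                }
            )
        p = outdir / "consensus.tsv"
        pd.DataFrame(
            cons_rows,
            columns=["chain", "length_class", "n_sequences", "insufficient", "consensus"],
        ).to_csv(p, sep="\t", index=False)
        paths.append(p)
        for (chain, L), profile in sorted(result.profiles.items()):
            p = outdir / f"enrichment_{chain}_{L}.tsv"
            ratio = profile.ratio.copy()
            ratio.insert(0, "position", ratio.index)
            ratio.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths.append(p)

    if "markdown" in formats:
        lines = ["# Selection report", ""]
        lines.append("## Thresholds")
        lines.append("")
        for k, v in asdict(result.config).items():
            lines.append(f"- {k}: {v}")
        lines.append("")
        lines.append("## Consensus per length class")
        lines.append("")
        for (chain, L), cons in sorted(result.consensus.items()):
            prefix = "VR" if chain == "VH" else ""
            note = " (insufficient sequences)" if cons.insufficient else ""
            lines.append(
                f"- {chain} length {L} (n={cons.n_sequences}){note}: "
                f"`{cons.render(prefix=prefix)}`"
            )
        lines.append("")
        lines.append("## Clones")
        lines.append("")
        header = list(sel.columns)
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "|".join(["---"] * len(header)) + "|")
        for _, row in sel.iterrows():
            lines.append("| " + " | ".join(str(row[c]) for c in header) + " |")
        lines.append("")
        n_sel = int(sel["selected"].sum())
        lines.append(f"Selected clones: {n_sel} of {len(sel)}.")
        lines.append("")
        p = outdir / "report.md"
        p.write_text("\n".join(lines))
        paths.append(p)
    return paths
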