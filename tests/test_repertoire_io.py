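"""Clone reading, anchor extraction, QC filtering, table round-trips."""

import warnings

import numpy as np
import pytest

from biasscan.library_model import theoretical_table
from biasscan.repertoire_io import (
    DEFAULT_VH_ANCHORS,
    DEFAULT_VL_ANCHORS,
    AnchorSpec,
    CloneRecord,
    extract_cdr3,
    qc_filter,
    read_clones,
    read_frequency_table,
    write_clones,
    write_frequency_table,
)
from biasscan.synthetic import assemble_scfv

from conftest import make_clone


class TestExtraction:
    def test_loop_between_anchors_with_prefix_stripped(self):
        seq = assemble_scfv("AAAAAAAA", "QQSYSTPLT")
        res = extract_cdr3(seq, DEFAULT_VH_ANCHORS, invariant_prefix="VR")
        assert res.cdr3 == "AAAAAAAA"
        assert res.status == "ok" and res.prefix_stripped

    def test_missing_downstream_anchor_flags_record(self):
        seq = assemble_scfv("AAAAAAAA", "QQSYSTPLT").replace("WGQGT", "")
        res = extract_cdr3(seq, DEFAULT_VH_ANCHORS)
        assert res.status == "anchor_missing" and res.cdr3 is None

    def test_ambiguous_anchor_never_silently_chosen(self):
        seq = assemble_scfv("AAAAAAAA", "QQSYSTPLT")
        res = extract_cdr3(seq + DEFAULT_VH_ANCHORS.upstream, DEFAULT_VH_ANCHORS)
        assert res.status == "anchor_missing"

    def test_extraction_inverts_generator_assembly(self, small_library, rng):
        """extract_cdr3 is the left inverse of the synthetic assembler."""
        from biasscan.library_model import sample_cdr3

        vh_sub = small_library.group("VH")[0]
        vl_sub = small_library.group("VL")[0]
        for _ in range(25):
            vh = sample_cdr3(vh_sub, rng)
            vl = sample_cdr3(vl_sub, rng)
            seq = assemble_scfv(vh, vl)
            got_vh = extract_cdr3(seq, DEFAULT_VH_ANCHORS, "VR")
            got_vl = extract_cdr3(seq, DEFAULT_VL_ANCHORS, "")
            if got_vh.status == "ok":
                assert got_vh.cdr3 == vh
            if got_vl.status == "ok":
                assert got_vl.cdr3 == vl


class TestReadClones:
    def test_tsv_round_trip_is_identity(self, tmp_path):
        records = [
            make_clone("A1.32.F1", vh="ARDYWGGGSLDYW"[:13], vl="QQSYSTPLT", fraction="F1"),
            make_clone("B2.32.F3", vh="GYSSWMDVKHRPE", fraction="F3"),
        ]
        path = tmp_path / "clones.tsv"
        write_clones(records, path)
        back = read_clones(path, "cdr3_tsv")
        assert len(back) == 2
        for a, b in zip(records, back):
            assert (a.clone_id, a.fraction, a.round, a.vh_cdr3, a.vl_cdr3) == (
                b.clone_id, b.fraction, b.round, b.vh_cdr3, b.vl_cdr3)

    def test_fasta_header_tokens_parsed(self, tmp_path):
        seq = assemble_scfv("GYSSWMDVKHRPE", "QQSYSTPLT")
        path = tmp_path / "clones.fasta"
        path.write_text(f">A5.31.F1|F1|round2\n{seq}\n")
        recs = read_clones(path, "fasta_aa", vl_anchors=DEFAULT_VL_ANCHORS)
        assert recs[0].clone_id == "A5.31.F1"
        assert recs[0].fraction == "F1" and recs[0].round == 2
        assert recs[0].vh_cdr3 == "GYSSWMDVKHRPE"
        assert recs[0].vl_cdr3 == "QQSYSTPLT"

    def test_nucleotide_fasta_translated_before_anchor_search(self, tmp_path):
        from Bio.Seq import Seq

        protein = assemble_scfv("GYSSWMDVKHRPE", "QQSYSTPLT")
        codon_for = {  # one arbitrary codon per residue
            "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
            "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
            "P": "CCG", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACC", "V": "GTT",
            "W": "TGG", "Y": "TAT",
        }
        nt = "".join(codon_for[a] for a in protein)
        assert str(Seq(nt).translate()) == protein
        path = tmp_path / "clones.fna"
        path.write_text(f">X1.32.F2|F2|round2\n{nt}\n")
        recs = read_clones(path, "fasta_nt", vl_anchors=DEFAULT_VL_ANCHORS)
        assert recs[0].vh_cdr3 == "GYSSWMDVKHRPE" and recs[0].vl_cdr3 == "QQSYSTPLT"

    def test_unknown_fraction_kept_native_with_warning(self, tmp_path):
        path = tmp_path / "clones.tsv"
        path.write_text("clone_id\tvh_cdr3\tfraction\tround\nX1\tAAAAA\tF9\t2\n")
        with pytest.warns(UserWarning, match="F9"):
            recs = read_clones(path, "cdr3_tsv")
        assert recs[0].fraction == "native"

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("clone_id\tvh_cdr3\tvl_cdr3\tfraction\tround\n")
        with pytest.warns(UserWarning, match="no clone records"):
            assert read_clones(path, "cdr3_tsv") == []

    def test_duplicate_reads_collapsed_with_flag(self, tmp_path):
        path = tmp_path / "clones.tsv"
        rows = ["clone_id\tvh_cdr3\tfraction\tround"]
        rows.append("A1.32.F1\tAAAAA\tF1\t2")
        rows.append("A1.32.F1\tAAAAA\tF1\t2")  # same well, same sequence
        rows.append("B1.32.F1\tAAAAA\tF1\t2")  # other well, same sequence: kept
        path.write_text("\n".join(rows) + "\n")
        recs = read_clones(path, "cdr3_tsv")
        assert len(recs) == 2
        assert "duplicate_read" in recs[0].qc
        assert recs[1].qc == {"ok"}


class TestQCFilter:
    def test_rejection_reasons_counted(self):
        records = [
            make_clone("ok1", vh="GYSSWMDVKHRPE"),
            make_clone("stop", vh="GYSSW*DVKHRPE"),
            make_clone("short", vh="GYSSWMDVK"),  # length 9: not a VH class
            CloneRecord(clone_id="noanchor", qc={"anchor_missing"}),
        ]
        report = qc_filter(records, vh_length_classes=[13])
        assert [r.clone_id for r in report.passing] == ["ok1"]
        assert report.reasons["internal_stop"] == 1
        assert report.reasons["frameshift_length"] == 1
        assert report.reasons["anchor_missing"] == 1
        assert len(report.passing) + len(report.rejected) == len(records)

    def test_passing_records_not_mutated(self):
        rec = make_clone("ok1", vh="GYSSWMDVKHRPE")
        before = set(rec.qc)
        qc_filter([rec], vh_length_classes=[13])
        assert rec.qc == before

    def test_artifact_injection_rate_recovered(self, small_library):
        """~5% injected artifacts are caught; count deterministic per seed."""
        from biasscan.synthetic import demo_scenario

        scenario = demo_scenario(with_spikes=False)
        records, _ = scenario.run(seed=3)
        r2 = [r for r in records if r.round == 2]
        report = qc_filter(r2, vh_length_classes=[13], vl_length_classes=[9])
        n = len(r2)
        assert n == 600
        # Binomial(600, 0.05): mean 30, essentially always within [10, 60]
        assert 10 <= len(report.rejected) <= 60
        again = qc_filter(
            [r for r in scenario.run(seed=3)[0] if r.round == 2],
            vh_length_classes=[13], vl_length_classes=[9],
        )
        assert len(again.rejected) == len(report.rejected)


class TestFrequencyTableIO:
    def test_write_read_round_trip(self, tmp_path, nnk_vh13):
        table = theoretical_table(nnk_vh13)
        path = tmp_path / "theo.tsv"
        write_frequency_table(table, path)
        back = read_frequency_table(path)
        assert back.chain == table.chain
        assert back.length_class == 13 and back.n_sequences == 0
        assert np.allclose(back.freq.values, table.freq.values, atol=1e-12)

    def test_corrupt_row_sum_error_names_position(self, tmp_path, nnk_vh13):
        table = theoretical_table(nnk_vh13)
        path = tmp_path / "theo.tsv"
        write_frequency_table(table, path)
        lines = path.read_text().splitlines()
        parts = lines[4].split("\t")  # position 1 data row
        parts[1] = "0.5"  # break the row sum
        lines[4] = "\t".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="position 1"):
            read_frequency_table(path)
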