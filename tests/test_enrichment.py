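"""Observed frequencies, fold-change ratios, hot calling, scoring, selection."""

import numpy as np
import pandas as pd
import pytest

from biasscan.enrichment import (
    call_hot_positions,
    enrichment_ratios,
    observed_frequencies,
    recovery_normalization,
    round_enrichment,
    score_clone,
    select_clones,
)
from biasscan.families import CloneFamily
from biasscan.fixtures import (
    TABLE1_CONSENSUS,
    synthetic_observed_counts,
    table1_clones,
    table1_consensus,
    table1_redundancy,
)
from biasscan.library_model import AA_ALPHABET, theoretical_table

from conftest import make_clone


class TestObservedFrequencies:
    def test_identical_sequences_give_unit_frequencies(self):
        records = [make_clone(f"C{i}", vh="ACDE") for i in range(4)]
        table = observed_frequencies(records, "VH", 4)
        assert table.n_sequences == 4
        for p, a in enumerate("ACDE", start=1):
            assert table.freq.loc[p, a] == 1.0
        assert np.allclose(table.freq.sum(axis=1).values, 1.0)

    def test_mixed_position(self):
        records = [make_clone("A", vh="AA"), make_clone("B", vh="AC")]
        table = observed_frequencies(records, "VH", 2)
        assert table.freq.loc[2, "A"] == 0.5 and table.freq.loc[2, "C"] == 0.5

    def test_empty_class_all_zero(self):
        table = observed_frequencies([], "VH", 5)
        assert table.n_sequences == 0
        assert (table.freq.values == 0).all()
        assert table.zero_positions() == [1, 2, 3, 4, 5]

    def test_sampling_converges_to_theoretical(self, nnk_vh13, rng):
        from biasscan.library_model import sample_cdr3

        seqs = sample_cdr3(nnk_vh13, rng, n=10_000)
        records = [make_clone(f"S{i}", vh=s) for i, s in enumerate(seqs)]
        observed = observed_frequencies(records, "VH", 13)
        theo = theoretical_table(nnk_vh13)
        assert np.abs(observed.freq.values - theo.freq.values).max() < 0.02


class TestEnrichmentRatios:
    def test_identity_when_observed_equals_theoretical(self, nnk_vh13):
        theo = theoretical_table(nnk_vh13)
        observed = theo.copy()
        observed.n_sequences = 31
        observed.counts = (theo.freq * 31).round().astype(int)
        profile = enrichment_ratios(observed, theo)
        finite = profile.ratio.values[np.isfinite(profile.ratio.values)]
        pos = profile.ratio.values[observed.counts.values > 0]
        assert np.allclose(pos, 1.0)

    def test_simple_fold_arithmetic(self):
        idx = [1]
        cols = list(AA_ALPHABET)
        exp = pd.DataFrame(np.full((1, 20), 0.05), index=idx, columns=cols)
        obs_counts = pd.DataFrame(np.zeros((1, 20), dtype=int), index=idx, columns=cols)
        obs_counts.loc[1, "A"] = 30
        obs_counts.loc[1, "C"] = 70
        from biasscan.library_model import PositionalFrequencyTable

        theo = PositionalFrequencyTable("VH", 1, 0, exp)
        obs = PositionalFrequencyTable("VH", 1, 100, obs_counts / 100, counts=obs_counts)
        profile = enrichment_ratios(obs, theo)
        assert profile.ratio.loc[1, "A"] == pytest.approx(0.30 / 0.05)
        assert profile.ratio.loc[1, "W"] == 0.0

    def test_non_library_residue_flagged_not_huge(self, nnk_vh13):
        # TGG-only design encodes W exclusively; anything else is non-library
        from conftest import nnk_design
        from biasscan.library_model import (
            CHAIN_VH, DegenerateCodon, OligoDesign, SubLibrarySpec)

        sub = SubLibrarySpec(
            chain=CHAIN_VH, length_class=3,
            design=OligoDesign(tuple(DegenerateCodon("TGG") for _ in range(3))),
        )
        theo = theoretical_table(sub)
        records = [make_clone("A", vh="WAW"), make_clone("B", vh="WWW")]
        observed = observed_frequencies(records, "VH", 3)
        profile = enrichment_ratios(observed, theo)
        assert (2, "A") in profile.non_library
        assert np.isinf(profile.ratio.loc[2, "A"])
        cons = call_hot_positions(profile, min_class_n=1, min_count=1)
        assert "A" not in cons.hot.get(2, frozenset())

    def test_dimension_mismatch_rejected(self, nnk_vh13):
        theo = theoretical_table(nnk_vh13)
        records = [make_clone("A", vh="ACDE")]
        observed = observed_frequencies(records, "VH", 4)
        with pytest.raises(ValueError, match="dimensions"):
            enrichment_ratios(observed, theo)


class TestHotCalling:
    def test_uniform_observed_gives_all_x(self, nnk_vh13):
        theo = theoretical_table(nnk_vh13)
        counts = (theo.freq * 310).round().astype(int)
        observed = theo.copy()
        observed.n_sequences = 310
        observed.counts = counts
        profile = enrichment_ratios(observed, theo)
        cons = call_hot_positions(profile)
        assert cons.hot == {}
        assert cons.render() == "V R " + " ".join(["X"] * 13)

    def test_insufficient_sequences_returns_empty_marked(self, nnk_vh13):
        theo = theoretical_table(nnk_vh13)
        records = [make_clone(f"C{i}", vh="GYSSWMDVKHRPE") for i in range(5)]
        observed = observed_frequencies(records, "VH", 13)
        profile = enrichment_ratios(observed, theo)
        cons = call_hot_positions(profile, min_class_n=10)
        assert cons.insufficient and cons.hot == {}

    def test_threshold_validation(self, nnk_vh13):
        theo = theoretical_table(nnk_vh13)
        records = [make_clone(f"C{i}", vh="GYSSWMDVKHRPE") for i in range(12)]
        profile = enrichment_ratios(observed_frequencies(records, "VH", 13), theo)
        with pytest.raises(ValueError, match="fold_threshold"):
            call_hot_positions(profile, fold_threshold=1.0)

    def test_monotone_in_thresholds(self, nnk_vh13):
        theo = theoretical_table(nnk_vh13)
        table = synthetic_observed_counts(theo, TABLE1_CONSENSUS[13], n_sequences=62)
        profile = enrichment_ratios(table, theo)
        base = call_hot_positions(profile, fold_threshold=3.0, min_count=2)
        for fold, min_count in [(3.5, 2), (3.0, 5), (4.0, 8)]:
            tighter = call_hot_positions(profile, fold_threshold=fold, min_count=min_count)
            assert tighter.hot_cells() <= base.hot_cells()


class TestScoring:
    def test_table1_rows_match_published_counts(self):
        expected = {
            10: [2, 3, 3, 3],
            13: [3, 3, 5, 3],
            14: [4, 4, 3, 4, 4],
        }
        for L, counts in expected.items():
            cons = table1_consensus(L)
            got = [
                score_clone(masked, cons, clone_id=cid).match_count
                for cid, _, masked in table1_clones(L)
            ]
            assert got == counts

    def test_score_equals_bruteforce_membership_count(self):
        rng = np.random.default_rng(5)
        cons = table1_consensus(13)
        for _ in range(50):
            cdr3 = "".join(AA_ALPHABET[k] for k in rng.integers(0, 20, 13))
            oracle = sum(
                1 for p in range(1, 14) if cdr3[p - 1] in cons.hot.get(p, frozenset())
            )
            assert score_clone(cdr3, cons).match_count == oracle

    def test_multi_residue_hot_set_matches_any_member(self):
        cons = table1_consensus(10)
        a = score_clone("XXDXXXXXXX", cons).match_count
        b = score_clone("XXIXXXXXXX", cons).match_count
        assert a == b == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            score_clone("SHORT", table1_consensus(13))


class TestSelection:
    def _scores(self):
        cons = {L: table1_consensus(L) for L in (10, 13, 14)}
        return [
            score_clone(masked, cons[L], clone_id=cid)
            for cid, L, masked in table1_clones()
        ]

    def test_published_selection_set(self):
        results = select_clones(self._scores(), table1_redundancy(), min_matches=3)
        assert sum(r.selected for r in results) == 13
        f8 = next(r for r in results if r.clone_id == "F8.32.F2")
        assert f8.reasons == frozenset({"redundancy"})
        h8 = next(r for r in results if r.clone_id == "H8.32.F1")
        assert h8.reasons == frozenset({"bias", "redundancy"})

    def test_below_cutoff_unflagged_not_selected(self):
        results = select_clones(self._scores(), {}, min_matches=3)
        f8 = next(r for r in results if r.clone_id == "F8.32.F2")
        assert not f8.selected and f8.reasons == frozenset()

    def test_min_matches_extremes(self):
        scores = self._scores()
        all_in = select_clones(scores, {}, min_matches=0)
        assert all(r.selected for r in all_in)
        only_redundant = select_clones(scores, table1_redundancy(), min_matches=99)
        assert {r.clone_id for r in only_redundant if r.selected} == {
            "F8.32.F2", "H8.32.F1"}

    def test_deterministic_ordering(self):
        results = select_clones(self._scores(), table1_redundancy(), min_matches=3)
        keys = [(not r.selected, -r.score.match_count, r.clone_id) for r in results]
        assert keys == sorted(keys)


class TestRecoveryNormalization:
    def test_reference_input_identity(self):
        assert recovery_normalization(500, 1e12) == 500

    def test_scaling(self):
        assert recovery_normalization(500, 1e13) == pytest.approx(50)

    def test_round_factor(self):
        r1 = recovery_normalization(100, 1e12)
        r2 = recovery_normalization(500, 1e12)
        assert round_enrichment(r2, r1) == pytest.approx(5.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            recovery_normalization(500, 0)
        with pytest.raises(ValueError):
            round_enrichment(5, 0)
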