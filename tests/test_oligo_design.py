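import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligoblock import (
    ConfigError,
    DesignConfig,
    InputError,
    Interval,
    ModificationPattern,
    OligoCandidate,
    TargetSpec,
    ThermoConditions,
    ThermoModelError,
    TranscriptRecord,
    Transcriptome,
    design_pipeline,
    fragment_window,
    melting_temperature,
    reverse_complement,
    screen_offtargets,
    select_oligo,
    tile_candidates,
)
from oligoblock.oligo_design import approximate_tm, duplex_thermodynamics
from oligoblock.synthetic_data import synth_transcriptome

from _oracles import oracle_offtargets
from conftest import random_dna


def make_candidate(sense_kmer, tid="t", start=0, pattern="full_lna"):
    return OligoCandidate(
        seq=reverse_complement(sense_kmer),
        target_site=Interval(tid, start, start + len(sense_kmer)),
        pattern=ModificationPattern.from_name(pattern, len(sense_kmer)),
    )


class TestModificationPattern:
    def test_alternating_starts_modified(self):
        p = ModificationPattern.from_name("alternating_lna", 5)
        assert p.chemistries == ("LNA", "DNA", "LNA", "DNA", "LNA")

    def test_presets_have_expected_models(self):
        assert ModificationPattern.from_name("full_lna", 4).has_thermo_model
        assert not ModificationPattern.from_name("full_ome", 4).has_thermo_model
        assert not ModificationPattern.from_name("alternating_moe", 4).has_thermo_model

    def test_unknown_preset(self):
        with pytest.raises(ConfigError):
            ModificationPattern.from_name("half_lna", 8)


class TestTileCandidates:
    def test_32mer_gives_17_designs(self, rng):
        w = fragment_window(random_dna(rng, 32), k=16)
        assert len(tile_candidates(w, 16)) == 17

    def test_window_equal_k_single_candidate(self, rng):
        w = fragment_window(random_dna(rng, 16), k=16)
        assert len(tile_candidates(w, 16)) == 1

    def test_50mer_k18_gives_33(self, rng):
        w = fragment_window(random_dna(rng, 50), k=18)
        assert len(tile_candidates(w, 18)) == 33  # L - k + 1

    @given(st.integers(12, 30), st.integers(0, 40), st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_cardinality_property(self, k, extra, seed):
        rng = np.random.default_rng(seed)
        L = k + extra
        w = fragment_window(random_dna(rng, L), k=k)
        assert len(tile_candidates(w, k)) == L - k + 1

    def test_candidates_are_reverse_complements_in_order(self, rng):
        seq = random_dna(rng, 20)
        w = fragment_window(seq, k=16)
        cands = tile_candidates(w, 16)
        for offset, c in enumerate(cands):
            assert c.seq == reverse_complement(seq[offset : offset + 16])
            assert (c.target_site.start, c.target_site.end) == (offset, offset + 16)

    def test_window_too_short(self, rng):
        w = fragment_window(random_dna(rng, 16), k=16)
        with pytest.raises(InputError):
            tile_candidates(w, 18)

    def test_k_out_of_range(self, rng):
        w = fragment_window(random_dna(rng, 40), k=16)
        with pytest.raises(ConfigError):
            tile_candidates(w, 8)


class TestScreenOfftargets:
    def test_unique_self_site_only(self, rng):
        seq = random_dna(rng, 200)
        tx = Transcriptome([TranscriptRecord("t", seq)])
        sense = seq[50:66]
        cand = make_candidate(sense, "t", 50)
        hits = screen_offtargets(cand, tx, max_mismatches=0, exclude=cand.target_site)
        assert hits == []

    def test_planted_two_mismatch_decoy(self):
        tx, manifest = synth_transcriptome(seed=5, decoy_mismatches=[2], n_decoys=1)
        src = manifest.truth["decoy_source"]
        cand = make_candidate(src["kmer"], src["transcript_id"], src["start"])
        hits = screen_offtargets(cand, tx, max_mismatches=3, exclude=cand.target_site)
        decoy = manifest.truth["decoys"][0]
        assert [(h.transcript_id, h.position.start, h.mismatches) for h in hits] == [
            (decoy["transcript_id"], decoy["start"], 2)
        ]

    def test_mm4_decoy_invisible_at_mm3(self):
        tx, manifest = synth_transcriptome(seed=6, decoy_mismatches=[0, 2, 4], n_decoys=3)
        src = manifest.truth["decoy_source"]
        cand = make_candidate(src["kmer"], src["transcript_id"], src["start"])
        hits = screen_offtargets(cand, tx, max_mismatches=3, exclude=cand.target_site)
        got = {(h.transcript_id, h.mismatches) for h in hits}
        assert got == {("decoy_1", 0), ("decoy_2", 2)}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        transcripts = [
            (f"t{i}", random_dna(rng, int(rng.integers(30, 250)))) for i in range(20)
        ]
        tx = Transcriptome([TranscriptRecord(tid, s) for tid, s in transcripts])
        # a k-mer taken from one transcript plus planted near-matches
        sense = transcripts[0][1][10:26]
        cand = make_candidate(sense, "t0", 10)
        for max_mm in (0, 1, 2, 3, 4):
            got = [
                (h.transcript_id, h.position.start, h.mismatches)
                for h in screen_offtargets(cand, tx, max_mm, exclude=cand.target_site)
            ]
            assert got == oracle_offtargets(sense, transcripts, max_mm, ("t0", 10))

    def test_n_counts_as_mismatch(self):
        # single 16-nt window carrying one N: conservative 1-mismatch hit
        tx = Transcriptome([TranscriptRecord("t", "ACGTACGTNCGTACGT")])
        cand = make_candidate("ACGTACGTACGTACGT")
        hits = screen_offtargets(cand, tx, max_mismatches=1)
        assert [(h.transcript_id, h.mismatches) for h in hits] == [("t", 1)]
        assert screen_offtargets(cand, tx, max_mismatches=0) == []

    def test_short_transcripts_skipped(self, rng):
        tx = Transcriptome([TranscriptRecord("short", "ACGT")])
        cand = make_candidate(random_dna(rng, 16))
        assert screen_offtargets(cand, tx) == []


class TestMeltingTemperature:
    def test_hand_summed_dna_8mer(self):
        # independent hand summation for ACGTACGT, all-DNA:
        # stacks AC CG GT TA AC CG GT
        dh = -8.4 - 10.6 - 8.4 - 7.2 - 8.4 - 10.6 - 8.4  # = -62.0
        ds = -22.4 - 27.2 - 22.4 - 21.3 - 22.4 - 27.2 - 22.4  # = -165.3
        dh += 2.3 + 2.3  # two terminal A/T initiations
        ds += 4.1 + 4.1
        import math

        tm_ref = dh * 1000.0 / (ds + 1.987 * math.log(0.25e-6 / 4.0))
        inv = (
            1.0 / tm_ref
            + (4.29 * 0.5 - 3.95) * 1e-5 * math.log(0.05)
            + 9.40e-6 * math.log(0.05) ** 2
        )
        expected = 1.0 / inv - 273.15
        got = melting_temperature("ACGTACGT")
        assert got == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(16.74, abs=0.01)  # frozen hand value

    def test_published_blocker_band(self):
        tm = melting_temperature(
            "ACCCACTACCATCGGA", pattern=ModificationPattern.from_name("full_lna", 16)
        )
        assert 89.9 - 5.0 <= tm <= 89.9 + 5.0

    def test_full_lna_beats_dna(self):
        seq = "ACCCACTACCATCGGA"
        full = melting_temperature(seq, pattern=ModificationPattern.from_name("full_lna", 16))
        dna = melting_temperature(seq)
        assert full > dna

    @pytest.mark.parametrize("seed", range(20))
    def test_chemistry_ordering_random_16mers(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 16)
        t_dna = melting_temperature(seq)
        t_alt = melting_temperature(seq, pattern=ModificationPattern.from_name("alternating_lna", 16))
        t_full = melting_temperature(seq, pattern=ModificationPattern.from_name("full_lna", 16))
        assert t_full > t_alt > t_dna

    def test_monotone_in_oligo_concentration(self, rng):
        seq = random_dna(rng, 16)
        tms = [
            melting_temperature(seq, ThermoConditions(oligo_concentration=c))
            for c in (0.05e-6, 0.25e-6, 1e-6, 5e-6, 20e-6)
        ]
        assert all(a < b for a, b in zip(tms, tms[1:]))

    def test_monotone_in_monovalent_salt(self, rng):
        for seq in (random_dna(rng, 16), "GC" * 8, "AT" * 8):
            tms = [
                melting_temperature(seq, ThermoConditions(monovalent_salt=na))
                for na in (0.01, 0.05, 0.115, 0.3)
            ]
            assert all(a < b for a, b in zip(tms, tms[1:]))

    def test_divalent_raises_tm(self):
        seq = "ACCCACTACCATCGGA"
        assert melting_temperature(
            seq, ThermoConditions(divalent_salt=0.003)
        ) > melting_temperature(seq)

    def test_ome_pattern_raises_with_guidance(self):
        with pytest.raises(ThermoModelError, match="approximate_tm"):
            melting_temperature(
                "ACGTACGTACGTACGT",
                pattern=ModificationPattern.from_name("full_ome", 16),
            )

    def test_approximate_tm_is_flagged(self):
        tm, is_estimate = approximate_tm(
            "ACGTACGTACGTACGT", ModificationPattern.from_name("full_moe", 16)
        )
        assert is_estimate
        assert tm > melting_temperature("ACGTACGTACGTACGT")

    def test_n_rejected(self):
        with pytest.raises(InputError):
            melting_temperature("ACGTNACG")

    def test_deterministic(self):
        p = ModificationPattern.from_name("full_lna", 16)
        a = melting_temperature("ACCCACTACCATCGGA", pattern=p)
        b = melting_temperature("ACCCACTACCATCGGA", pattern=p)
        assert a == b

    def test_duplex_thermodynamics_lna_stabilizes(self, rng):
        seq = random_dna(rng, 16)
        dh0, ds0 = duplex_thermodynamics(seq, [False] * 16)
        dh1, ds1 = duplex_thermodynamics(seq, [True] * 16)
        # LNA increments reduce the magnitude of both dH and dS but the net
        # free energy at duplex-relevant temperatures is more favorable
        t = 273.15 + 70.0
        assert dh1 - t * ds1 / 1000.0 < dh0 - t * ds0 / 1000.0


class TestSelectOligo:
    def _cands(self, tms, offcounts, rng):
        cands = []
        for i, (tm, n_off) in enumerate(zip(tms, offcounts)):
            sense = random_dna(rng, 16)
            c = make_candidate(sense, "t", i)
            c.tm_celsius = tm
            c.offtargets = [
                type("H", (), {})() for _ in range(0)
            ]
            c.offtargets = []
            for j in range(n_off):
                from oligoblock import OffTargetHit

                c.offtargets.append(
                    OffTargetHit("x", Interval("x", j, j + 16), 1)
                )
            cands.append(c)
        return cands

    def test_single_candidate_selected_despite_offtargets(self, rng):
        (cand,) = self._cands([70.0], [5], rng)
        res = select_oligo([cand])
        assert res.selected is cand
        assert res.fallback_used

    def test_argmax_tm_among_clean(self, rng):
        cands = self._cands([70.0, 85.0, 80.0], [0, 0, 0], rng)
        assert select_oligo(cands).selected.tm_celsius == 85.0

    def test_clean_candidate_preferred_over_higher_tm(self, rng):
        # the only off-target-free candidate has the 3rd-highest Tm
        cands = self._cands([90.0, 88.0, 84.0], [2, 1, 0], rng)
        res = select_oligo(cands)
        assert res.selected.tm_celsius == 84.0
        assert not res.fallback_used

    def test_fallback_min_offtarget_set(self, rng):
        cands = self._cands([90.0, 70.0, 85.0], [3, 1, 1], rng)
        res = select_oligo(cands)
        assert res.fallback_used
        assert res.selected.tm_celsius == 85.0

    def test_permutation_invariance(self, rng):
        cands = self._cands([70.0, 85.0, 85.0, 80.0], [0, 1, 1, 0], rng)
        base = select_oligo(cands, anchor_position=100).selected
        for perm_seed in range(10):
            perm = list(np.random.default_rng(perm_seed).permutation(len(cands)))
            got = select_oligo([cands[i] for i in perm], anchor_position=100).selected
            assert got is base

    def test_anchor_tiebreak(self, rng):
        cands = self._cands([80.0, 80.0], [0, 0], rng)
        # target sites at starts 0 and 1 -> ends 16 and 17; anchor at 17
        res = select_oligo(cands, anchor_position=17)
        assert res.selected.target_site.end == 17

    def test_empty_list(self):
        with pytest.raises(InputError):
            select_oligo([])

    def test_unscreened_rejected(self, rng):
        c = make_candidate(random_dna(rng, 16))
        c.tm_celsius = 50.0
        with pytest.raises(InputError):
            select_oligo([c])


class TestDesignPipeline:
    def test_fragment_mode_17_rows_one_selection(self, rng):
        frag = random_dna(rng, 32)
        tx = Transcriptome([TranscriptRecord("bg", random_dna(rng, 500))])
        report = design_pipeline(TargetSpec(mode="fragment", fragment_seq=frag), tx)
        assert len(report.rows) == 17
        assert len(report.selections) == 1
        assert sum(r["selected"] for r in report.rows) == 1

    def test_polya_mode_two_sites_two_oligos(self):
        tx, manifest = synth_transcriptome(seed=8, n_polya_sites=2)
        report = design_pipeline(TargetSpec(mode="polya", transcript_id="tx_0001"), tx)
        assert len(report.selections) == 2
        starts = sorted(s["start"] for s in manifest.truth["polya_sites"])
        # each selected oligo sits 5' of its site and does not overlap it
        for sel, site_start in zip(report.selections, starts):
            assert sel.target_site.end <= site_start

    def test_zero_sites_empty_report(self, rng, caplog):
        tx = Transcriptome([TranscriptRecord("flat", "CGCG" * 200)])
        report = design_pipeline(TargetSpec(mode="polya", transcript_id="flat"), tx)
        assert report.rows == []
        assert report.selections == []

    def test_report_files(self, tmp_path, rng):
        frag = random_dna(rng, 20)
        tx = Transcriptome([TranscriptRecord("bg", random_dna(rng, 300))])
        report = design_pipeline(TargetSpec(mode="fragment", fragment_seq=frag), tx)
        report.to_tsv(tmp_path / "r.tsv")
        report.to_json(tmp_path / "r.json")
        header = (tmp_path / "r.tsv").read_text().splitlines()[0].split("\t")
        assert "tm_c" in header and "n_offtargets_mm3" in header
        import json

        payload = json.loads((tmp_path / "r.json").read_text())
        assert payload["provenance"]["config"]["k"] == 16
        assert "parameter_tables" in payload["provenance"]
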