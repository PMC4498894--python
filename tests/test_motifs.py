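import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from classbsurvey.motifs import (
    AMBIGUITY_AA,
    STANDARD_AA,
    WILDCARD,
    PatternError,
    SequenceError,
    classify_sequence,
    parse_pattern,
    scan_sequence,
    thr_conservation,
    validate_bvmo_architecture,
)

from oracles import brute_scan


def _seq(*parts):
    """Assemble a sequence from (filler_length | motif_text) parts."""
    return "".join(p if isinstance(p, str) else "L" * p for p in parts)


class TestParse:
    def test_rossmann_motif(self):
        p = parse_pattern("GxGxx[G/A]", "rossmann")
        assert len(p) == 6
        assert p.positions[0] == frozenset("G")
        assert p.positions[1] is WILDCARD
        assert p.positions[2] == frozenset("G")
        assert p.positions[5] == frozenset("GA")

    def test_first_bvmo_fingerprint(self):
        p = parse_pattern("[A/G]GxWxxxx[F/Y]P[G/M]xxxD", "bvmo_fp1")
        assert len(p) == 15
        assert p.positions[0] == frozenset("AG")
        assert p.positions[8] == frozenset("FY")
        assert p.positions[9] == frozenset("P")
        assert p.positions[10] == frozenset("GM")
        assert p.positions[14] == frozenset("D")

    def test_single_wildcard(self):
        p = parse_pattern("x", "w")
        assert len(p) == 1 and p.positions[0] is WILDCARD

    @pytest.mark.parametrize("bad", ["[A/]", "[A", "G-G", "", "[/]", "Gx[J/A]"])
    def test_malformed_patterns_raise(self, bad):
        with pytest.raises(PatternError):
            parse_pattern(bad, "bad")

    def test_round_trip_up_to_bracket_normalization(self, registry):
        for pat in registry.values():
            assert parse_pattern(pat.render(), pat.pattern_id).positions == pat.positions


class TestScan:
    def test_hand_checked_window(self, registry):
        hits = scan_sequence("AAGAGAAGAA", registry["rossmann"], "s")
        assert [(h.start, h.end, h.matched_text) for h in hits] == [(3, 8, "GAGAAG")]

    def test_sequence_shorter_than_pattern(self, registry):
        assert scan_sequence("GAGA", registry["rossmann"]) == []

    def test_gapped_input_rejected(self, registry):
        with pytest.raises(SequenceError):
            scan_sequence("GAG-AAG", registry["rossmann"])

    def test_ambiguity_codes_satisfy_wildcards_only(self, registry):
        # X at a wildcard position: still a hit; X at a constrained one: no hit
        assert scan_sequence("GXGAAG", registry["rossmann"])
        assert not scan_sequence("XAGAAG", registry["rossmann"])

    def test_overlapping_hits_reported(self, registry):
        hits = scan_sequence("GGGGGGGG", registry["rossmann"])
        assert [h.start for h in hits] == [1, 2, 3]

    def test_matches_brute_force_on_random_sequences(self, registry):
        rng = np.random.default_rng(7)
        alphabet = np.array(list(STANDARD_AA))
        biased = np.array(list("GAFWPYDHKRTMGG"))
        for i in range(100):
            pool = alphabet if i % 2 else biased
            seq = "".join(rng.choice(pool, size=120))
            for pat in registry.values():
                got = [(h.start, h.end, h.matched_text) for h in scan_sequence(seq, pat)]
                assert got == brute_scan(seq, pat)

    @given(st.data())
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_widening_an_allowed_set_never_loses_hits(self, data):
        base = parse_pattern("GxGxx[G/A]", "r")
        seq = data.draw(st.text(alphabet="GALT", min_size=6, max_size=40))
        pos = data.draw(st.integers(0, 5))
        extra = data.draw(st.sampled_from(STANDARD_AA))
        wider_positions = list(base.positions)
        if wider_positions[pos] is None:
            return
        wider_positions[pos] = wider_positions[pos] | {extra}
        wider = parse_pattern(
            "".join(
                "x" if p is None else ("[" + "/".join(sorted(p)) + "]" if len(p) > 1 else next(iter(p)))
                for p in wider_positions
            ),
            "wide",
        )
        assert len(scan_sequence(seq, wider)) >= len(scan_sequence(seq, base))


class TestArchitecture:
    def test_valid_quadruple(self, registry):
        seq = _seq(9, "GAGAAG", 24, "AGAWAAAAFPGAAAD", 35, "FAGAAAHAAAWP", 38,
                   "GAGAAG", 50)
        hits = [h for pat in registry.values() for h in scan_sequence(seq, pat)]
        ok, chosen = validate_bvmo_architecture(hits)
        assert ok
        assert [h.pattern_id for h in chosen] == ["rossmann", "bvmo_fp1", "bvmo_fp2",
                                                  "rossmann"]
        assert all(a.end < b.start for a, b in zip(chosen, chosen[1:]))

    def test_single_rossmann_fails(self, registry):
        seq = _seq(9, "GAGAAG", 24, "AGAWAAAAFPGAAAD", 35, "FAGAAAHAAAWP", 88)
        hits = [h for pat in registry.values() for h in scan_sequence(seq, pat)]
        assert validate_bvmo_architecture(hits) == (False, None)

    def test_order_violation_fails(self, registry):
        # fingerprints swapped: rossmann - fp2 - fp1 - rossmann
        seq = _seq(9, "GAGAAG", 24, "FAGAAAHAAAWP", 35, "AGAWAAAAFPGAAAD", 38,
                   "GAGAAG", 50)
        hits = [h for pat in registry.values() for h in scan_sequence(seq, pat)]
        assert validate_bvmo_architecture(hits)[0] is False


class TestClassify:
    def test_planted_bvmo(self):
        seq = _seq(9, "GAGAAG", 24, "AGAWAAAAFPGAAAD", 35, "FAGAAAHAAAWP", 38,
                   "GAGAAG", 50)
        call = classify_sequence(seq, "b1")
        assert call.label == "BVMO" and call.architecture_ok and not call.ambiguous

    def test_fmo_motif_between_rossmanns(self):
        seq = _seq(9, "GAGAAG", 134, "FAGAAAHAAAYK", 18, "GAGAAG", 65)
        assert classify_sequence(seq).label == "FMO"

    def test_motif_free_sequence_unclassified(self):
        call = classify_sequence("L" * 200)
        assert call.label == "unclassified" and not call.hits

    def test_strict_thr_is_a_refinement(self):
        with_thr = _seq(9, "GAGAAG", 24, "AGAWAAAAFPGAAAD", 35, "FTGLRSHTAQWP", 38,
                        "GAGAAG", 50)
        without = with_thr.replace("FTGLRSHTAQWP", "FTGLRSHAAQWP")
        assert classify_sequence(with_thr, strict_thr=True).label == "BVMO"
        assert classify_sequence(without, strict_thr=True).label == "unclassified"
        assert classify_sequence(without, strict_thr=False).label == "BVMO"

    def test_strict_thr_bvmo_set_is_subset(self, survey):
        loose = {s for s, q in survey.proteome.items()
                 if classify_sequence(q, s).label == "BVMO"}
        strict = {s for s, q in survey.proteome.items()
                  if classify_sequence(q, s, strict_thr=True).label == "BVMO"}
        assert strict <= loose


class TestThrConservation:
    def _bvmo(self, fp2):
        return classify_sequence(
            _seq(9, "GAGAAG", 24, "AGAWAAAAFPGAAAD", 35, fp2, 38, "GAGAAG", 50))

    @pytest.mark.parametrize(
        "fp2s, expected",
        [
            (["FTGLRSHTAQWP"] * 4, 1.0),
            (["FTGLRSHAAQWP"] * 4, 0.0),
            (["FTGLRSHTAQWP"] * 3 + ["FTGLRSHAAQWP"], 0.75),
        ],
    )
    def test_fraction(self, fp2s, expected):
        calls = [self._bvmo(fp2) for fp2 in fp2s]
        assert thr_conservation(calls) == pytest.approx(expected)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            thr_conservation([])
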