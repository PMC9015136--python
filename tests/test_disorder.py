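import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import idpseq
from idpseq.charge import PkaSet, local_charge
from idpseq.disorder import (
    COLLAPSED,
    DISORDERED,
    EXTENDED,
    INSOLUBLE,
    ORDERED,
    charge_hydropathy_point,
    classify_charge_hydropathy,
    foldindex,
    foldindex_score,
    segment_calls,
)
from idpseq.errors import ValidationError
from idpseq.hydropathy import local_hydropathy, scaled_hydropathy
from idpseq.sequence import parse_sequence


def oracle_classify(h: float, q: float) -> str:
    """Independent re-coding of the two printed classification rules."""
    if h >= 0.7:
        return "insoluble"
    boundary = 2.785 * h - 1.151
    return "extended" if abs(q) > boundary else "collapsed"


class TestClassification:
    def test_grid_sweep_agrees_with_oracle(self):
        for h in np.linspace(0.0, 1.0, 101):
            for q in np.linspace(-1.0, 1.0, 81):
                assert classify_charge_hydropathy(float(h), float(q)) == oracle_classify(h, q)

    def test_zero_point_is_extended(self):
        # boundary at h=0 is negative, so |q|=0 already exceeds it
        assert classify_charge_hydropathy(0.0, 0.0) == EXTENDED

    def test_insolubility_overrides_boundary(self):
        assert classify_charge_hydropathy(0.8, 0.0) == INSOLUBLE
        assert classify_charge_hydropathy(0.7, 0.9) == INSOLUBLE

    def test_worked_boundary_case(self):
        # boundary = 2.785*0.5 - 1.151 = 0.2415 > 0.10
        assert classify_charge_hydropathy(0.5, 0.10) == COLLAPSED

    def test_boundary_equality_is_collapsed(self):
        h = 0.5
        q = 2.785 * h - 1.151
        assert classify_charge_hydropathy(h, q) == COLLAPSED
        assert classify_charge_hydropathy(h, np.nextafter(q, 2)) == EXTENDED

    @given(st.floats(0.0, 1.0), st.floats(-1.0, 1.0))
    def test_symmetric_in_charge_sign(self, h, q):
        assert classify_charge_hydropathy(h, q) == classify_charge_hydropathy(h, -q)

    def test_hydropathy_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_charge_hydropathy(1.2, 0.0)


class TestChargeHydropathyPoint:
    def test_poly_ile_is_insoluble(self):
        point = charge_hydropathy_point(parse_sequence("I" * 50))
        assert point.mean_hydropathy == 1.0
        assert point.label == INSOLUBLE

    def test_poly_gly_label_follows_boundary(self):
        point = charge_hydropathy_point(parse_sequence("G" * 50), include_termini=False)
        h = scaled_hydropathy("G")
        assert point.mean_hydropathy == pytest.approx(h)
        assert point.label == oracle_classify(h, point.mean_net_charge)

    def test_alpha_synuclein_is_collapsed(self, asyn):
        assert charge_hydropathy_point(asyn).label == COLLAPSED

    def test_alpha_synuclein_cterm_is_extended(self, asyn):
        assert charge_hydropathy_point(asyn.subsequence(104, 140)).label == EXTENDED
        assert charge_hydropathy_point(asyn.subsequence(1, 103)).label == COLLAPSED


class TestFoldIndex:
    def test_poly_ile_score_exact(self):
        result = foldindex(parse_sequence("I" * 120))
        assert np.allclose(result.profile.values, 2.785 - 1.151)
        assert set(result.calls) == {ORDERED}

    def test_poly_glu_is_disordered(self):
        pka = PkaSet(
            "e425", {"C": 8.0, "D": 4.0, "E": 4.25, "H": 6.0, "K": 10.0, "R": 12.0, "Y": 10.0},
            nterm=9.0, cterm=3.0,
        )
        result = foldindex(parse_sequence("E" * 120), pka_set=pka)
        assert np.allclose(result.profile.values, -1.840, atol=5e-4)
        assert set(result.calls) == {DISORDERED}

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError, match="odd"):
            foldindex(parse_sequence("I" * 120), window=50)

    def test_short_sequence_falls_back_to_whole_window(self):
        seq = parse_sequence("I" * 20)
        result = foldindex(seq, window=51)
        assert result.whole_sequence_window
        assert result.window == 20
        assert len(result.profile) == 1
        assert result.profile.positions.tolist() == [10]
        assert result.profile.values[0] == pytest.approx(2.785 - 1.151)

    def test_zero_score_called_ordered_and_flagged(self):
        # construct windows whose score is exactly zero via a custom flat scale
        flat = idpseq.HydropathyScale(
            "flat", {aa: 1.151 / 2.785 for aa in idpseq.STANDARD_AA}
        )
        # power-of-two length keeps the whole-sequence mean exactly equal
        # to the constant per-residue value, so the score is exactly 0.0
        res = foldindex(parse_sequence("G" * 32), window=51, scale=flat)
        assert res.profile.values.tolist() == [0.0]
        assert res.calls == (ORDERED,)
        assert res.boundary_positions == (16,)

    def test_score_recomputed_from_charge_and_hydropathy_modules(self, random_sequences):
        for seq in random_sequences(15, min_len=60, max_len=200, seed=17):
            result = foldindex(seq, window=51)
            h = local_hydropathy(seq, window=51)
            q = local_charge(seq, window=51)
            assert result.profile.positions.tolist() == h.positions.tolist()
            expected = 2.785 * h.values - np.abs(q.values) - 1.151
            assert np.allclose(result.profile.values, expected, atol=1e-12)
            for score, call in zip(result.profile.values, result.calls):
                assert call == (DISORDERED if score < 0 else ORDERED)

    def test_regions_partition_calls(self, random_sequences):
        for seq in random_sequences(10, min_len=60, max_len=300, seed=23):
            result = foldindex(seq, window=51)
            rebuilt = []
            for start, end, call in result.regions:
                rebuilt.extend([call] * (end - start + 1))
            assert tuple(rebuilt) == result.calls
            for (s1, e1, c1), (s2, e2, c2) in zip(result.regions, result.regions[1:]):
                assert c1 != c2
                assert s2 == e1 + 1

    def test_replacing_hydrophobics_with_glu_never_raises_score(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            residues = rng.choice(list(idpseq.STANDARD_AA), size=150)
            seq = idpseq.ProteinSequence("a", "".join(residues))
            mutated = "".join("E" if aa in "ILVFMC" else aa for aa in seq.residues)
            before = foldindex(seq).profile.values
            after = foldindex(idpseq.ProteinSequence("b", mutated)).profile.values
            assert np.all(after <= before + 1e-12)

    def test_fraction_disordered_on_alpha_synuclein_cterm(self, asyn):
        result = foldindex(asyn)
        disordered = [
            (s, e) for s, e, call in result.regions if call == DISORDERED
        ]
        # the C-terminal region is the disordered one
        assert disordered and disordered[-1][1] == result.profile.positions[-1]


class TestSegmentCalls:
    def test_gap_in_positions_splits_region(self):
        regions = segment_calls(np.array([5, 6, 9, 10]), ("ordered",) * 4)
        assert regions == ((5, 6, "ordered"), (9, 10, "ordered"))

    def test_alternating_calls(self):
        regions = segment_calls(np.array([1, 2, 3]), ("ordered", "disordered", "ordered"))
        assert regions == ((1, 1, "ordered"), (2, 2, "disordered"), (3, 3, "ordered"))


def test_foldindex_score_helper_matches_linear_form():
    assert foldindex_score(1.0, 0.0) == pytest.approx(1.634)
    assert foldindex_score(0.0, 1.0) == pytest.approx(-2.151)
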