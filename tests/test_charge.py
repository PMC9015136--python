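import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import idpseq
from idpseq.charge import (
    IPC_PROTEIN,
    PkaSet,
    load_pka_set,
    local_charge,
    net_charge,
    per_residue_charges,
    residue_charge,
)
from idpseq.errors import ValidationError
from idpseq.sequence import parse_sequence

LEHNINGER_LIKE = PkaSet(
    "test_set",
    {"C": 8.18, "D": 3.65, "E": 4.25, "H": 6.0, "K": 10.0, "R": 12.48, "Y": 10.07},
    nterm=9.69,
    cterm=2.34,
)


class TestResidueCharge:
    def test_non_ionizable_residues_are_exactly_zero(self):
        for aa in "GAVLIPFMWSTNQ":
            assert residue_charge(aa, 7.0) == 0.0

    def test_half_ionization_at_pka(self):
        assert residue_charge("E", IPC_PROTEIN.residue_pkas["E"]) == -0.5
        assert residue_charge("K", IPC_PROTEIN.residue_pkas["K"]) == 0.5

    def test_base_formula(self):
        # +1/(1+10^(pH-pKa)) with pKa(K)=10 at pH 7
        expected = 1.0 / (1.0 + 10.0 ** (7.0 - 10.0))
        assert residue_charge("K", 7.0, LEHNINGER_LIKE) == pytest.approx(expected)
        assert residue_charge("K", 7.0, LEHNINGER_LIKE) == pytest.approx(0.999, abs=1e-3)

    def test_acid_sign_and_range(self):
        for aa in "DECY":
            q = residue_charge(aa, 7.0)
            assert -1.0 <= q <= 0.0

    def test_unknown_residue(self):
        with pytest.raises(ValidationError):
            residue_charge("X", 7.0)

    @pytest.mark.parametrize("aa", list("DECYHKR"))
    def test_deprotonation_is_monotone_in_ph(self, aa):
        # raising pH removes protons everywhere: acids go 0 -> -1 and bases
        # +1 -> 0, so the signed charge is non-increasing for every group
        grid = np.arange(1.0, 13.01, 0.5)
        charges = [residue_charge(aa, ph) for ph in grid]
        assert np.all(np.diff(charges) <= 1e-15)
        if aa in "DECY":
            assert charges[0] > -0.5 > charges[-1]
        else:
            assert charges[0] > 0.5 > charges[-1]


class TestNetCharge:
    def test_homopolymer_glycine_is_neutral(self):
        res = net_charge(parse_sequence("GGGG"), include_termini=False)
        assert res.net_charge == 0.0
        assert res.mean_net_charge == 0.0

    def test_poly_glutamate_matches_formula(self):
        res = net_charge(parse_sequence("EEEE"), 7.0, LEHNINGER_LIKE, include_termini=False)
        expected = 4 * (-1.0 / (1.0 + 10.0 ** (4.25 - 7.0)))
        assert res.net_charge == pytest.approx(expected)
        assert res.net_charge == pytest.approx(-3.993, abs=1e-3)

    def test_symmetric_acid_base_pair_cancels(self):
        # pKa(E) and pKa(K) symmetric about pH 7.125 for this set
        symmetric = PkaSet(
            "sym", {"C": 8.0, "D": 4.0, "E": 4.25, "H": 6.0, "K": 10.0, "R": 12.0, "Y": 10.0},
            nterm=9.0, cterm=3.0,
        )
        ph = (4.25 + 10.0) / 2
        res = net_charge(parse_sequence("EK"), ph, symmetric, include_termini=False)
        assert res.net_charge == pytest.approx(0.0, abs=1e-12)

    def test_termini_add_one_base_one_acid(self):
        seq = parse_sequence("GGGG")
        without = net_charge(seq, include_termini=False).net_charge
        with_term = net_charge(seq, include_termini=True).net_charge
        nterm = 1.0 / (1.0 + 10.0 ** (7.0 - IPC_PROTEIN.nterm))
        cterm = -1.0 / (1.0 + 10.0 ** (IPC_PROTEIN.cterm - 7.0))
        assert with_term - without == pytest.approx(nterm + cterm)

    @pytest.mark.parametrize("n", [1, 5, 50])
    def test_homopolymer_mean_independent_of_length(self, n):
        res = net_charge(parse_sequence("E" * n), include_termini=False)
        single = residue_charge("E", 7.0)
        assert res.mean_net_charge == pytest.approx(single)

    def test_masked_positions_excluded_from_sum_and_mean(self):
        with pytest.warns(UserWarning):
            seq = parse_sequence("EXE", policy="mask")
        res = net_charge(seq, include_termini=False)
        assert res.net_charge == pytest.approx(2 * residue_charge("E", 7.0))
        assert res.mean_net_charge == pytest.approx(residue_charge("E", 7.0))


class TestLocalCharge:
    def test_window_equal_to_length_gives_single_center(self):
        prof = local_charge(parse_sequence("G" * 9), window=9)
        assert prof.positions.tolist() == [5]
        assert prof.values.tolist() == [0.0]

    def test_edge_positions_have_no_window(self):
        prof = local_charge(parse_sequence("E" * 11), window=9)
        assert prof.positions.tolist() == [5, 6, 7]

    def test_window_mean_matches_hand_computation(self):
        seq = parse_sequence("EEEEKKKKK")
        prof = local_charge(seq, window=3)
        qE, qK = residue_charge("E", 7.0), residue_charge("K", 7.0)
        # center position 5 covers residues 4..6 = E,K,K
        at5 = prof.values[prof.positions.tolist().index(5)]
        assert at5 == pytest.approx((qE + 2 * qK) / 3)

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError, match="odd"):
            local_charge(parse_sequence("E" * 10), window=4)

    def test_window_longer_than_sequence_suggests_net_charge(self):
        with pytest.raises(ValidationError, match="net_charge"):
            local_charge(parse_sequence("EEE"), window=9)

    def test_windows_never_include_termini(self):
        # a single full window over the whole chain must miss the terminal groups
        seq = parse_sequence("G" * 5)
        prof = local_charge(seq, window=5)
        assert prof.values.tolist() == [0.0]

    @given(st.integers(0, 2**31 - 1), st.integers(3, 21).filter(lambda w: w % 2 == 1))
    def test_brute_force_window_oracle(self, seed, window):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(window, 80))
        seq = idpseq.ProteinSequence(
            "r", "".join(rng.choice(list(idpseq.STANDARD_AA), size=length))
        )
        prof = local_charge(seq, window=window)
        charges = per_residue_charges(seq)
        half = window // 2
        expected_positions = list(range(half + 1, length - half + 1))
        assert prof.positions.tolist() == expected_positions
        for pos, value in zip(prof.positions, prof.values):
            manual = float(np.mean(charges[pos - 1 - half : pos + half]))
            assert value == pytest.approx(manual, abs=1e-12)


class TestPkaSets:
    def test_default_is_ipc_protein(self):
        assert idpseq.available_pka_sets()[0] == "IPC_protein"
        assert idpseq.get_pka_set("IPC_protein") is IPC_PROTEIN

    def test_unknown_name_lists_available(self):
        with pytest.raises(ValidationError, match="IPC_protein"):
            idpseq.get_pka_set("nosuch")

    def test_polarity_fixed_by_chemistry(self):
        assert residue_charge("D", 7.0) < 0 < residue_charge("R", 7.0)
        assert residue_charge("H", 7.0) > 0  # histidine is a base, partially charged

    def test_pka_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            PkaSet("bad", {**dict(IPC_PROTEIN.residue_pkas), "K": 15.0},
                   nterm=9.0, cterm=3.0)

    def test_file_round_trip(self, tmp_path):
        path = tmp_path / "custom.pka"
        lines = ["# custom set"]
        lines += [f"{aa}\t{pka}" for aa, pka in IPC_PROTEIN.residue_pkas.items()]
        lines += [f"NTERM\t{IPC_PROTEIN.nterm}", f"CTERM\t{IPC_PROTEIN.cterm}"]
        path.write_text("\n".join(lines) + "\n")
        loaded = load_pka_set(path)
        assert dict(loaded.residue_pkas) == dict(IPC_PROTEIN.residue_pkas)
        assert (loaded.nterm, loaded.cterm) == (IPC_PROTEIN.nterm, IPC_PROTEIN.cterm)
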