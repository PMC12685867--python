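"""Descriptor-family unit tests: worked examples, brute-force oracles on
short sequences, and normalization/limit identities."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bacpred as bp
from bacpred._alphabet import AA_INDEX
from bacpred._tables import CTD_PROPERTIES, physicochemical_distance_matrix
from bacpred.descriptors import ShortSequenceError

P = bp.DescriptorParams()


def seq(residues, sid="s"):
    return bp.ProteinSequence(sid, residues)


protein = st.text(alphabet=bp.ALPHABET, min_size=21, max_size=40)


class TestAAC:
    def test_homopolymer(self):
        v = bp.extract_aac(seq("AAAA"))
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_uniform(self):
        v = bp.extract_aac(seq("ARND"))
        np.testing.assert_allclose(v[:4], 0.25)
        assert v[4:].sum() == 0.0

    def test_cysteine_is_position_five(self):
        v = bp.extract_aac(seq("CCCCG"))
        assert v[4] == pytest.approx(0.8)  # aac_5
        assert v[7] == pytest.approx(0.2)  # aac_8 = glycine

    @given(protein)
    @settings(max_examples=30, deadline=None)
    def test_matches_counting_oracle(self, residues):
        v = bp.extract_aac(seq(residues))
        counts = Counter(residues)
        for aa, i in AA_INDEX.items():
            assert v[i] == pytest.approx(counts[aa] / len(residues))


class TestDC:
    def test_homopolymer(self):
        v = bp.extract_dc(seq("AAAAA"))
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_alternating(self):
        v = bp.extract_dc(seq("ACAC"))
        ac = AA_INDEX["A"] * 20 + AA_INDEX["C"]
        ca = AA_INDEX["C"] * 20 + AA_INDEX["A"]
        assert v[ac] == pytest.approx(2 / 3)
        assert v[ca] == pytest.approx(1 / 3)

    def test_length_and_sum(self):
        v = bp.extract_dc(seq("ACDEFGHIKL"))
        assert len(v) == 400
        assert v.sum() == pytest.approx(1.0)

    def test_too_short(self):
        with pytest.raises(ShortSequenceError):
            bp.extract_dc(seq("A"))

    @given(protein)
    @settings(max_examples=30, deadline=None)
    def test_matches_pair_oracle(self, residues):
        v = bp.extract_dc(seq(residues))
        pairs = Counter(zip(residues, residues[1:]))
        for (a, b), n in pairs.items():
            assert v[AA_INDEX[a] * 20 + AA_INDEX[b]] == pytest.approx(
                n / (len(residues) - 1))


class TestPseAAC:
    def test_homopolymer_has_zero_correlations(self):
        v = bp.extract_paac(seq("A" * 12))
        assert v[0] == pytest.approx(1.0)
        np.testing.assert_allclose(v[20:], 0.0)

    def test_weight_zero_collapses_to_aac(self):
        s = seq("ACDEFGHIKLMNP")
        v = bp.extract_paac(s, bp.DescriptorParams(w_paac=0.0))
        np.testing.assert_allclose(v[:20], bp.extract_aac(s), atol=1e-12)
        np.testing.assert_allclose(v[20:], 0.0)

    def test_normalization_and_nonnegativity(self):
        v = bp.extract_paac(seq("ACDEFGHIKLMNPQRSTVWY"))
        assert len(v) == 30
        assert (v >= 0).all()
        assert v.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_short(self):
        with pytest.raises(ShortSequenceError):
            bp.extract_paac(seq("ACDEFGHIKL"))  # L == lambda

    def test_matches_direct_formula_oracle(self):
        # independent elementwise reimplementation on a short sequence
        residues = "ACDEFGHIKLMNPQ"
        from bacpred._tables import PAAC_SCALES
        lam, w = 10, 0.05
        L = len(residues)
        idx = [AA_INDEX[c] for c in residues]
        taus = []
        for j in range(1, lam + 1):
            acc = 0.0
            for i in range(L - j):
                acc += sum(
                    (PAAC_SCALES[k, idx[i]] - PAAC_SCALES[k, idx[i + j]]) ** 2
                    for k in range(3)) / 3
            taus.append(acc / (L - j))
        freqs = [idx.count(r) / L for r in range(20)]
        denom = sum(freqs) + w * sum(taus)
        expected = [f / denom for f in freqs] + [w * t / denom for t in taus]
        np.testing.assert_allclose(bp.extract_paac(seq(residues)), expected, atol=1e-12)


class TestAPseAAC:
    def test_homopolymer_first20_indicator(self):
        v = bp.extract_apaac(seq("G" * 15))
        assert v[AA_INDEX["G"]] == pytest.approx(1.0)
        np.testing.assert_allclose(v[20:], 0.0)
        assert len(v) == 40

    def test_weight_zero_collapses_to_aac(self):
        s = seq("ACDEFGHIKLMNP")
        v = bp.extract_apaac(s, bp.DescriptorParams(w_apaac=0.0))
        np.testing.assert_allclose(v[:20], bp.extract_aac(s), atol=1e-12)
        np.testing.assert_allclose(v[20:], 0.0)

    def test_sums_to_one(self):
        v = bp.extract_apaac(seq("ACDEFGHIKLMNPQRSTVWY"))
        assert v.sum() == pytest.approx(1.0, abs=1e-9)


class TestCTD:
    def test_charge_on_kkdd(self):
        v = bp.extract_ctd(seq("KKDD"))
        comp = v[:21].reshape(7, 3)
        tran = v[21:42].reshape(7, 3)
        dist = v[42:].reshape(7, 3, 5)
        charge = 4  # fifth property
        np.testing.assert_allclose(comp[charge], [0.5, 0.0, 0.5])
        np.testing.assert_allclose(tran[charge], [0.0, 1 / 3, 0.0])
        np.testing.assert_allclose(dist[charge, 0], [25, 25, 25, 50, 50])

    def test_homopolymer_single_group_per_property(self):
        v = bp.extract_ctd(seq("AAAA"))
        comp = v[:21].reshape(7, 3)
        tran = v[21:42]
        for p in range(7):
            assert sorted(comp[p]) == [0.0, 0.0, 1.0]
        np.testing.assert_allclose(tran, 0.0)

    @given(protein)
    @settings(max_examples=30, deadline=None)
    def test_distribution_range_and_composition_sum(self, residues):
        v = bp.extract_ctd(seq(residues))
        comp = v[:21].reshape(7, 3)
        dist = v[42:]
        np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-9)
        assert ((dist >= 0) & (dist <= 100)).all()

    def test_matches_positional_oracle(self):
        # brute-force distribution quantiles for one property
        residues = "KRKDEDAK"
        v = bp.extract_ctd(seq(residues))
        dist = v[42:].reshape(7, 3, 5)
        groups = CTD_PROPERTIES[4][1]  # charge
        for g, members in enumerate(groups):
            pos = [i + 1 for i, c in enumerate(residues) if c in members]
            if not pos:
                continue
            k = len(pos)
            expected = [pos[0]] + [pos[math.ceil(q * k) - 1] for q in (0.25, 0.5, 0.75, 1.0)]
            np.testing.assert_allclose(dist[4, g], [100 * p / len(residues) for p in expected])


class TestSS:
    def test_all_helix(self):
        v = bp.extract_ss(seq("AAAA"), bp.SecondaryStructureString("s", "HHHH"))
        np.testing.assert_allclose(v, [1, 0, 0, 1, 0, 0])

    def test_mixed_states(self):
        v = bp.extract_ss(seq("AAAA"), bp.SecondaryStructureString("s", "HECH"))
        np.testing.assert_allclose(v, [0.5, 0.25, 0.25, 0.25, 0.25, 0.25])

    def test_fallback_predicts_and_has_length_six(self):
        v = bp.extract_ss(seq("ACDEFGHIKLMNPQRSTVWY"))
        assert len(v) == 6
        assert v[:3].sum() == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            bp.extract_ss(seq("AAAA"), bp.SecondaryStructureString("s", "HH"))


class TestSequenceOrder:
    def test_homopolymer_couplings_vanish(self):
        v = bp.extract_socn(seq("A" * 25))
        np.testing.assert_allclose(v, 0.0)
        assert len(v) == 20

    def test_single_term_matches_matrix_lookup(self):
        D = physicochemical_distance_matrix()
        s = seq("AC" + "A" * 19)  # L = 21 > maxlag
        v = bp.extract_socn(s)
        # tau_1 = d(A,C)^2 + d(C,A)^2 + 18 * d(A,A)^2
        assert v[0] == pytest.approx(2 * D[AA_INDEX["A"], AA_INDEX["C"]] ** 2)

    def test_short_sequence_error_names_minimum(self):
        with pytest.raises(ShortSequenceError, match="minimum length 21"):
            bp.extract_socn(seq("A" * 20))

    def test_qso_homopolymer_indicator(self):
        v = bp.extract_qso(seq("W" * 30))
        assert v[AA_INDEX["W"]] == pytest.approx(1.0)
        np.testing.assert_allclose(v[20:], 0.0)

    def test_qso_weight_zero_collapses_to_aac(self):
        s = seq("ACDEFGHIKLMNPQRSTVWYA")
        v = bp.extract_qso(s, bp.DescriptorParams(w_qso=0.0))
        np.testing.assert_allclose(v[:20], bp.extract_aac(s), atol=1e-12)

    @given(protein)
    @settings(max_examples=30, deadline=None)
    def test_qso_normalization(self, residues):
        v = bp.extract_qso(seq(residues))
        assert (v >= 0).all()
        assert v.sum() == pytest.approx(1.0, abs=1e-9)


class TestPSSMTransition:
    def test_zero_scores_give_quarter(self):
        prof = bp.PSSMProfile("s", np.zeros((3, 20)))
        v = bp.extract_pssm_transition(seq("ACD"), prof)
        np.testing.assert_allclose(v, 0.25)

    def test_one_hot_single_transition(self):
        scores = np.full((2, 20), -60.0)
        scores[0, AA_INDEX["A"]] = 60.0
        scores[1, AA_INDEX["C"]] = 60.0
        v = bp.extract_pssm_transition(seq("AC"), bp.PSSMProfile("s", scores))
        ac = AA_INDEX["A"] * 20 + AA_INDEX["C"]
        assert v[ac] == pytest.approx(1.0)
        assert v.sum() == pytest.approx(1.0)

    def test_length_contract_and_fallback(self):
        v = bp.extract_pssm_transition(seq("ACDEFGHIKL"))
        assert len(v) == 400
        assert (v > 0).all()  # logistic outputs never vanish

    def test_row_count_mismatch(self):
        with pytest.raises(ValueError, match="rows"):
            bp.extract_pssm_transition(seq("ACD"), bp.PSSMProfile("s", np.zeros((2, 20))))


class TestFeaturize:
    def test_schema_anchor_names(self):
        names = bp.full_feature_names()
        assert names[4] == "aac_5"                       # cysteine
        assert bp.ALPHABET[4] == "C"
        assert bp.ALPHABET[10] == "L" and bp.ALPHABET[12] == "M"
        dist_93 = names.index("dist_93")
        # dist block is property-major: dist_93 = property 7, group 1, 50%
        offset = dist_93 - names.index("dist_1")
        assert offset // 15 == 6                         # solvent accessibility
        assert (offset % 15) // 5 == 0                   # group 1 (buried)
        assert CTD_PROPERTIES[6][0] == "solvent_accessibility"
        assert bp.family_of("dist_93") == "CTD"

    def test_total_and_family_dimensionalities(self):
        s = seq("ACDEFGHIKLMNPQRSTVWYACDEF")
        fm = bp.featurize([s])
        assert fm.values.shape == (1, 1103)
        sizes = [size for _, _, size in bp.schema.FAMILY_BLOCKS]
        assert sizes == [20, 400, 30, 40, 21, 21, 105, 6, 20, 40, 400]

    def test_identical_sequences_identical_rows(self):
        a = seq("ACDEFGHIKLMNPQRSTVWYACDEF", "a")
        b = seq("ACDEFGHIKLMNPQRSTVWYACDEF", "b")
        fm = bp.featurize([a, b])
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_permuting_inputs_permutes_rows_only(self):
        a = seq("ACDEFGHIKLMNPQRSTVWYACDEF", "a")
        b = seq("WYACDEFGHIKLMNPQRSTVACDEF", "b")
        fm1 = bp.featurize([a, b])
        fm2 = bp.featurize([b, a])
        np.testing.assert_array_equal(fm1.values[0], fm2.values[1])
        np.testing.assert_array_equal(fm1.values[1], fm2.values[0])

    def test_short_sequence_rejected_with_id(self):
        with pytest.raises(ShortSequenceError, match="shorty"):
            bp.featurize([seq("ACDEF", "shorty")])

    def test_fallback_usage_recorded(self):
        s = seq("ACDEFGHIKLMNPQRSTVWYACDEF", "s1")
        fm = bp.featurize([s])
        assert fm.metadata["pssm_fallback_ids"] == ["s1"]
        assert fm.metadata["ss_fallback_ids"] == ["s1"]
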