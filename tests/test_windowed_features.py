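"""Window-averaged feature groups and matrix assembly."""

import numpy as np
import pytest

from proteus._aa_tables import AA_ORDER
from proteus.io_tracks import (
    DisorderProfile,
    PSSMProfile,
    SecondaryStructureProfile,
)
from proteus.windowed_features import (
    GROUP_RANGES,
    FeatureConfig,
    PssmScaler,
    assemble_features,
    composition_features,
    conservation_feature,
    feature_names,
    fit_pssm_scaler,
    group_columns,
    mutability_features,
    property_features,
    scale_pssm,
    ss_features,
)


def _pssm(scores, info=None):
    scores = np.asarray(scores, dtype=float)
    info = np.zeros(scores.shape[0]) if info is None else np.asarray(info, float)
    return PSSMProfile(scores, info)


class TestPssmScaler:
    def test_min_max_per_column(self):
        scores = np.zeros((3, 20))
        scores[:, 0] = [-2, 0, 3]  # column A
        scaler = fit_pssm_scaler([_pssm(scores)])
        assert scaler.mins[0] == -2 and scaler.maxs[0] == 3

    def test_degenerate_column_maps_to_half(self):
        scaler = fit_pssm_scaler([_pssm(np.ones((3, 20)))])
        out = scale_pssm(_pssm(np.ones((2, 20))), scaler)
        np.testing.assert_allclose(out.scores, 0.5)

    def test_fit_on_parts_equals_fit_on_concatenation(self, rng):
        a, b = rng.normal(size=(5, 20)), rng.normal(size=(7, 20))
        separate = fit_pssm_scaler([_pssm(a), _pssm(b)])
        pooled = fit_pssm_scaler([_pssm(np.vstack([a, b]))])
        np.testing.assert_allclose(separate.mins, pooled.mins)
        np.testing.assert_allclose(separate.maxs, pooled.maxs)

    def test_extremes_and_clamping(self, rng):
        train = rng.normal(size=(10, 20))
        scaler = fit_pssm_scaler([_pssm(train)])
        out = scale_pssm(_pssm(np.vstack([train.min(0), train.max(0), train.max(0) + 5])), scaler)
        np.testing.assert_allclose(out.scores[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.scores[1], 1.0, atol=1e-12)
        np.testing.assert_allclose(out.scores[2], 1.0)  # unseen values clamp

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_pssm_scaler([])


class TestMutability:
    def test_output_length_is_20_per_window_position(self, rng):
        prof = _pssm(rng.uniform(size=(40, 20)))
        for pos in (1, 7, 20, 40):
            assert mutability_features(prof, pos).shape == (300,)

    def test_terminal_positions_zero_padded(self, rng):
        prof = _pssm(rng.uniform(size=(40, 20)))
        v = mutability_features(prof, 1)
        assert np.all(v[: 7 * 20] == 0) and np.any(v[7 * 20 :] != 0)

    def test_interior_window_concatenates_rows(self, rng):
        scores = rng.uniform(size=(40, 20))
        v = mutability_features(_pssm(scores), 20)
        np.testing.assert_allclose(v, scores[12:27].ravel())


class TestConservation:
    def test_constant_info_preserved(self):
        prof = _pssm(np.zeros((30, 20)), np.full(30, 0.7))
        assert conservation_feature(prof, 15) == pytest.approx(0.7)

    def test_single_spike_averages_to_one(self):
        info = np.zeros(30)
        info[14] = 15.0
        assert conservation_feature(_pssm(np.zeros((30, 20)), info), 15) == pytest.approx(1.0)

    def test_terminus_divides_by_in_sequence_count(self):
        prof = _pssm(np.zeros((8, 20)), np.arange(8, dtype=float))
        # window truncates to all 8 residues at position 1
        assert conservation_feature(prof, 1) == pytest.approx(np.arange(8).mean())


class TestComposition:
    def test_homopolymer(self):
        v = composition_features("A" * 31, 16)
        assert v[AA_ORDER.index("A")] == 1.0 and v.sum() == 1.0

    def test_distinct_residues_each_one_fifteenth(self):
        seq = AA_ORDER  # 20 distinct residues
        v = composition_features(seq, 10)
        present = v[v > 0]
        np.testing.assert_allclose(present, 1 / 15)
        assert len(present) == 15

    def test_ambiguity_codes_excluded_from_divisor(self):
        v = composition_features("AAAXXAA", 4, window=15)
        assert v[AA_ORDER.index("A")] == 1.0  # 5 of 5 standard residues
        assert v.sum() == pytest.approx(1.0)


class TestProperties:
    def test_poly_lysine(self):
        v = property_features("K" * 21, 11)
        nonpolar, polar, acidic, basic, pos, neg, neu, kd, mass = v
        assert (basic, pos) == (1.0, 1.0)
        assert (nonpolar, polar, acidic, neg, neu) == (0, 0, 0, 0, 0)
        assert kd == pytest.approx(-3.9)
        assert mass == pytest.approx(128.1741)

    def test_fractions_sum_to_one(self, rng):
        seq = "".join(rng.choice(list(AA_ORDER), size=50))
        v = property_features(seq, 25)
        assert v[:4].sum() == pytest.approx(1.0)  # polarity classes
        assert v[4:7].sum() == pytest.approx(1.0)  # charge classes

    def test_poly_isoleucine_hydropathy(self):
        assert property_features("I" * 21, 11)[7] == pytest.approx(4.5)


class TestSsFeatures:
    def test_constant_rows_preserved(self):
        probs = np.tile([0.2, 0.1, 0.7], (30, 1))
        prof = SecondaryStructureProfile(probs, "C" * 30)
        np.testing.assert_allclose(ss_features(prof, 15), [0.2, 0.1, 0.7])

    def test_hand_averaged_fixture(self):
        probs = np.array([[0.5, 0.2, 0.3], [0.1, 0.6, 0.3], [0.3, 0.3, 0.4]])
        prof = SecondaryStructureProfile(probs, "HEC")
        np.testing.assert_allclose(
            ss_features(prof, 2), probs.mean(axis=0), atol=1e-12
        )


def _toy_protein(rng, L=50):
    seq = "".join(rng.choice(list(AA_ORDER), size=L))
    pssm = _pssm(rng.uniform(size=(L, 20)), rng.uniform(size=L))
    probs = rng.dirichlet([4, 2, 8], size=L)
    ss = SecondaryStructureProfile(probs, "".join("HEC"[i] for i in probs.argmax(1)))
    diso = DisorderProfile(rng.uniform(size=L))
    return seq, pssm, ss, diso


class TestAssembly:
    def test_column_count_and_group_ranges(self, rng):
        seq, pssm, ss, diso = _toy_protein(rng)
        fm = assemble_features(seq, pssm, ss, diso)
        assert fm.values.shape == (50, 342)
        assert fm.group_index == GROUP_RANGES
        assert GROUP_RANGES == {
            1: (1, 300), 2: (301, 301), 3: (302, 321), 4: (322, 330),
            5: (331, 333), 6: (334, 340), 7: (341, 342),
        }
        # group ranges partition 1..342
        cols = sorted(c for g in GROUP_RANGES for c in group_columns({g}))
        assert cols == list(range(342))

    def test_all_zero_disorder_track(self, rng):
        seq, pssm, ss, _ = _toy_protein(rng)
        fm = assemble_features(seq, pssm, ss, DisorderProfile(np.zeros(50)))
        g6 = fm.values[:, 333:340]
        assert np.all(g6[:, 1:4] == 0)  # disordered triplet all zero
        assert np.all(g6[:, 4] == 50)  # ordered segment spans the protein

    def test_scaled_pssm_features_in_unit_interval(self, rng):
        seq, pssm, ss, diso = _toy_protein(rng)
        scaler = fit_pssm_scaler([pssm])
        fm = assemble_features(seq, scaler.transform(pssm), ss, diso)
        g1 = fm.values[:, :300]
        assert g1.min() >= 0.0 and g1.max() <= 1.0

    def test_track_length_mismatch_rejected(self, rng):
        seq, pssm, ss, _ = _toy_protein(rng)
        with pytest.raises(Exception, match="length"):
            assemble_features(seq, pssm, ss, DisorderProfile(np.zeros(49)))

    def test_narrow_window_keeps_342_columns(self, rng):
        seq, pssm, ss, diso = _toy_protein(rng)
        fm = assemble_features(seq, pssm, ss, diso, config=FeatureConfig(window_size=9))
        assert fm.values.shape == (50, 342)
        # outer offsets are structurally zero for a 9-residue window
        assert np.all(fm.values[:, : 3 * 20] == 0)

    def test_even_or_out_of_range_window_rejected(self):
        with pytest.raises(ValueError):
            FeatureConfig(window_size=14)
        with pytest.raises(ValueError):
            FeatureConfig(window_size=23)

    def test_feature_names_align_with_ranges(self):
        names = feature_names()
        assert len(names) == 342
        assert names[300] == "conservation"
        assert names[341] == "topo:run_length"
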