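"""Propensity, secondary-structure content and Altscore analyses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteus._aa_tables import AA_ORDER
from proteus.consensus_analysis import (
    AltscoreResult,
    altscore,
    altscore_distribution,
    count_residues,
    pooled_ss_content,
    propensity,
    segment_altscores,
    ss_content,
)

counts_strategy = st.dictionaries(
    st.sampled_from(list(AA_ORDER)), st.integers(1, 500), min_size=3
)


class TestPropensity:
    def test_matching_composition_is_baseline(self):
        counts = {aa: 10 * (i + 1) for i, aa in enumerate(AA_ORDER)}
        table = propensity(counts, {aa: 3 * c for aa, c in counts.items()})
        assert all(v == pytest.approx(1.0) for v in table.propensities.values())

    def test_pure_class_against_five_percent_background(self):
        full = {aa: 5 for aa in AA_ORDER}  # every amino acid at 5%
        table = propensity({"A": 100}, full)
        assert table["A"] == pytest.approx(20.0)
        assert all(table[aa] == 0.0 for aa in AA_ORDER if aa != "A")

    def test_near_total_class_propensities_near_one(self, corpus200):
        """A class covering ~98% of residues has all propensities pinned near 1.

        For a class with corpus share s, Pr is confined to [0, 1/s]; with
        s ~ 0.98 every baseline propensity sits within ~2% of 1.
        """
        from collections import Counter

        full, non_protean = Counter(), Counter()
        for p in corpus200.proteins:
            lab = p.labels.labels.astype(bool)
            full.update(count_residues(p.sequence))
            non_protean.update(count_residues(p.sequence, ~lab))
        table = propensity(non_protean, full, "non_protean")
        share = sum(non_protean.values()) / sum(full.values())
        assert share > 0.97
        # Pr = 1/(share + (1-share)*r) with r the protean:non-protean
        # frequency ratio of the amino acid, so deviations from 1 scale with
        # (1-share) ~ 2% times (r-1); r stays below ~3.5 in this corpus.
        for aa, v in table.propensities.items():
            assert 0.94 <= v <= 1 / share + 1e-9, (aa, v)

    @given(counts_strategy, counts_strategy)
    @settings(max_examples=50, deadline=None)
    def test_background_weighted_normalization(self, class_counts, full_counts):
        """Sum over amino acids of f_full(X) * Pr(X) is identically 1."""
        # full support must cover the class for the identity to hold
        full_counts = {aa: 1 for aa in AA_ORDER} | full_counts
        table = propensity(class_counts, full_counts)
        full_total = sum(full_counts.values())
        acc = sum(
            (full_counts[aa] / full_total) * table[aa]
            for aa in table.propensities
        )
        assert acc == pytest.approx(1.0, abs=1e-12)

    def test_printed_denominator_variant_scales_by_class_share(self):
        full = {aa: 10 for aa in AA_ORDER}  # 200 residues
        cls = {"A": 5, "C": 5}  # 10 residues, 5% of the corpus
        corrected = propensity(cls, full, denominator="corrected")
        printed = propensity(cls, full, denominator="printed")
        assert printed["A"] == pytest.approx(corrected["A"] * 10 / 200)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            propensity({}, {aa: 1 for aa in AA_ORDER})


class TestSsContent:
    def test_all_coil_region(self):
        assert ss_content("CCCC") == {"H": 0.0, "E": 0.0, "C": 1.0}

    def test_fractions_sum_to_one(self, rng):
        calls = "".join(rng.choice(list("HEC"), size=200))
        assert sum(ss_content(calls).values()) == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ss_content("HEC", np.zeros(3, dtype=bool))

    def test_union_is_count_weighted_mean(self, rng):
        calls = "".join(rng.choice(list("HEC"), size=300))
        mask_a = np.zeros(300, dtype=bool)
        mask_a[:120] = True
        a = ss_content(calls, mask_a)
        b = ss_content(calls, ~mask_a)
        union = ss_content(calls)
        for k in "HEC":
            assert union[k] == pytest.approx((120 * a[k] + 180 * b[k]) / 300)

    def test_pooled_across_proteins(self):
        frac = pooled_ss_content(
            [("HHCC", np.ones(4, bool)), ("CC", np.ones(2, bool))]
        )
        assert frac == {"H": 2 / 6, "E": 0.0, "C": 4 / 6}


class TestAltscore:
    @pytest.mark.parametrize(
        "calls,expected",
        [("HHHH", 0.0), ("HCHC", 0.75), ("C", 0.0), ("HEC", 2 / 3)],
    )
    def test_transitions_per_residue(self, calls, expected):
        assert altscore(calls) == pytest.approx(expected)

    def test_length_minus_one_denominator(self):
        assert altscore("HCHC", denominator="length-1") == pytest.approx(1.0)
        assert altscore("C", denominator="length-1") == 0.0

    @given(st.text(alphabet="HEC", min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_reversal_invariance(self, calls):
        assert altscore(calls) == pytest.approx(altscore(calls[::-1]))


class TestAltscoreDistribution:
    def _results(self, specs):
        return segment_altscores(
            (f"s{i}", label, calls) for i, (label, calls) in enumerate(specs)
        )

    def test_all_constant_corpus_rejected(self):
        res = self._results([("protean", "HHH"), ("non_protean", "EEE")])
        with pytest.raises(ValueError):
            altscore_distribution(res)

    def test_filters_drop_zero_and_pure_coil(self):
        res = self._results(
            [
                ("protean", "HHHH"),  # zero altscore: dropped
                ("protean", "CCCC"),  # pure coil (also zero): dropped
                ("protean", "CHCC"),  # has coil but not pure: kept
                ("protean", "HEHE"),  # kept
            ]
        )
        dist = altscore_distribution(res)
        assert dist["protean"]["n_segments"] == 2

    def test_higher_transition_class_peaks_higher(self, corpus200):
        segs = []
        for p in corpus200.proteins:
            lab = p.labels.labels.astype(bool)
            for j, (s, e) in enumerate(p.labels.intervals):
                segs.append((f"{p.id}:{j}", "protean", p.ss.calls[s - 1 : e]))
            idx = np.flatnonzero(~lab)
            if idx.size:
                breaks = np.flatnonzero(np.diff(idx) > 1)
                starts = np.concatenate([[0], breaks + 1])
                stops = np.concatenate([breaks, [idx.size - 1]])
                for j, (a, b) in enumerate(zip(idx[starts], idx[stops])):
                    segs.append((f"{p.id}:n{j}", "non_protean", p.ss.calls[a : b + 1]))
        dist = altscore_distribution(segment_altscores(segs))
        assert dist["protean"]["peak"] > dist["non_protean"]["peak"]
        assert dist["protean"]["mean"] > dist["non_protean"]["mean"]
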