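"""Cysteine flanking-window extraction, enrichment, and chi-square."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thiolox.seqcontext import (
    AA_TYPE,
    TYPE_ORDER,
    aa_type,
    cluster_chisq,
    combine_clusters,
    enrichment,
    extract_window,
    position_frequency_table,
    type_counts,
)
from thiolox.synthetic import AMINO_ACIDS, gen_peptide_library


def pearson_chisq(obs):
    """Independent brute-force Pearson statistic: sum (O-E)^2 / E."""
    obs = np.asarray(obs, dtype=float)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    return float(((obs - expected) ** 2 / expected).sum())


class TestWindows:
    def test_full_eleven_mer(self):
        w = extract_window("ACDEFCHIKLM", 6)
        assert w.seq == "ACDEFCHIKLM" and w.length == 11 and w.center == 5

    def test_terminal_truncation(self):
        w = extract_window("ACDEF", 2)
        assert w.seq == "ACDEF" and w.length == 5 and w.center == 1

    def test_non_cysteine_position_rejected(self):
        with pytest.raises(ValueError, match="not C"):
            extract_window("ACDEF", 3)
        with pytest.raises(ValueError, match="out of range"):
            extract_window("ACDEF", 9)

    def test_matches_string_slice_oracle(self):
        lib = gen_peptide_library(40, seed=17, planted_cys_boost=2.0)
        for pid, seq in lib.sequences.items():
            pos = lib.sites[pid]
            w = extract_window(seq, pos, flank=5)
            assert w.seq == seq[max(0, pos - 6): pos + 5]

    def test_central_residue_excluded_from_counts(self):
        w = extract_window("AAAAACAAAAA", 6)
        counts = type_counts([w])
        assert counts["cysteine"] == 0 and counts["nonpolar"] == 10


class TestAaTypes:
    def test_every_residue_maps_to_exactly_one_type(self):
        assert sorted(AA_TYPE) == sorted(AMINO_ACIDS)
        assert set(AA_TYPE.values()) == set(TYPE_ORDER)

    @pytest.mark.parametrize("res, expected", [("C", "cysteine"), ("D", "negative"),
                                               ("K", "positive"), ("W", "aromatic"),
                                               ("S", "polar"), ("G", "nonpolar")])
    def test_examples(self, res, expected):
        assert aa_type(res) == expected

    def test_nonstandard_residue(self):
        with pytest.raises(ValueError):
            aa_type("X")
        assert aa_type("X", strict=False) is None


class TestEnrichment:
    def _library(self, n=60, boost=1.0, seed=3):
        lib = gen_peptide_library(n, seed=seed, planted_cys_boost=boost)
        return [
            extract_window(lib.sequences[p], lib.sites[p], peptide_id=p, label=lib.labels[p])
            for p in lib.sequences
        ]

    def test_self_normalization(self):
        windows = self._library()
        ratios = enrichment(windows, windows)
        for t, r in ratios.items():
            if r is not None:
                assert r == pytest.approx(1.0, abs=1e-12)

    def test_empty_cluster_rejected(self):
        windows = self._library()
        with pytest.raises(ValueError):
            enrichment([], windows)

    def test_weighted_mean_of_ratios_is_one(self):
        """sum_t ratio(t) * library_freq(t) = 1 for any cluster."""
        windows = self._library(n=140, boost=3.0, seed=9)
        groups = combine_clusters(windows)
        lc = type_counts(windows)
        n_l = sum(lc.values())
        for group in groups.values():
            ratios = enrichment(group, windows)
            total = sum(
                ratios[t] * lc[t] / n_l for t in TYPE_ORDER if ratios[t] is not None
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_planted_cysteine_signal_localized_to_boosted_groups(self):
        windows = self._library(n=280, boost=3.0, seed=1)
        groups = combine_clusters(windows)
        assert enrichment(groups["DE"], windows)["cysteine"] > 1.0
        assert enrichment(groups["AB"], windows)["cysteine"] == pytest.approx(1.0, abs=0.5)


class TestChisq:
    def _two_groups(self, seed=5):
        windows = self._lib_windows(seed)
        groups = combine_clusters(windows)
        return groups["DE"], groups["AB"]

    @staticmethod
    def _lib_windows(seed):
        lib = gen_peptide_library(140, seed=seed, planted_cys_boost=3.0)
        return [
            extract_window(lib.sequences[p], lib.sites[p], peptide_id=p, label=lib.labels[p])
            for p in lib.sequences
        ]

    def test_identical_groups_give_zero_statistic(self):
        a, _ = self._two_groups()
        r = cluster_chisq(a, a)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_degrees_of_freedom(self):
        a, b = self._two_groups()
        assert cluster_chisq(a, b, include_cys=True).df == 5
        assert cluster_chisq(a, b, include_cys=False).df == 4

    def test_matches_brute_force_pearson(self):
        """Statistic agrees with an independently coded sum (O-E)^2/E."""
        a, b = self._two_groups()
        ca = type_counts(a)
        cb = type_counts(b)
        obs = [[ca[t] for t in TYPE_ORDER], [cb[t] for t in TYPE_ORDER]]
        r = cluster_chisq(a, b)
        assert r.statistic == pytest.approx(pearson_chisq(obs), abs=1e-9)

    def test_fixed_table_oracle(self):
        obs = [[10, 20, 30, 40, 50, 60], [60, 50, 40, 30, 20, 10]]
        from scipy.stats import chi2_contingency

        stat, _, df, _ = chi2_contingency(obs, correction=False)
        assert stat == pytest.approx(pearson_chisq(obs), abs=1e-9)
        assert df == 5

    def test_symmetry(self):
        a, b = self._two_groups()
        assert cluster_chisq(a, b).statistic == pytest.approx(
            cluster_chisq(b, a).statistic, abs=1e-9
        )

    def test_empty_group_rejected(self):
        a, _ = self._two_groups()
        with pytest.raises(ValueError):
            cluster_chisq(a, [])


class TestCombine:
    def test_ab_pooling(self):
        lib = gen_peptide_library(35, seed=2, labels_cycle=("A", "B", "C", "D", "E", "F", "G"))
        windows = [
            extract_window(lib.sequences[p], lib.sites[p], peptide_id=p, label=lib.labels[p])
            for p in lib.sequences
        ]
        groups = combine_clusters(windows)
        n_a = sum(1 for w in windows if w.label == "A")
        n_b = sum(1 for w in windows if w.label == "B")
        assert len(groups["AB"]) == n_a + n_b
        assert set(groups) == {"AB", "DE", "C", "F", "G"}

    def test_pooled_counts_are_additive(self):
        lib = gen_peptide_library(70, seed=8)
        windows = [
            extract_window(lib.sequences[p], lib.sites[p], peptide_id=p, label=lib.labels[p])
            for p in lib.sequences
        ]
        groups = combine_clusters(windows)
        d = [w for w in windows if w.label == "D"]
        e = [w for w in windows if w.label == "E"]
        cd, ce, cde = type_counts(d), type_counts(e), type_counts(groups["DE"])
        assert all(cde[t] == cd[t] + ce[t] for t in TYPE_ORDER)

    def test_empty_component(self):
        lib = gen_peptide_library(10, seed=3, labels_cycle=("D",))
        windows = [
            extract_window(lib.sequences[p], lib.sites[p], peptide_id=p, label=lib.labels[p])
            for p in lib.sequences
        ]
        groups = combine_clusters(windows)
        assert len(groups["DE"]) == 10  # empty E: DE = D


def test_position_frequency_table_rows_sum_to_one():
    lib = gen_peptide_library(50, seed=4)
    windows = [
        extract_window(lib.sequences[p], lib.sites[p], peptide_id=p, label=lib.labels[p])
        for p in lib.sequences
    ]
    table = position_frequency_table(windows)
    sums = table.sum(axis=1).to_numpy()
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)
    assert table.loc[0, "C"] == pytest.approx(1.0)  # the identified cysteine itself
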