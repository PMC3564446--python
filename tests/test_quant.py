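"""Light/heavy envelope-pair quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thiolox.quant import (
    Aggregate,
    LabelConfig,
    PeptideSpec,
    Spectrum,
    aggregate_replicates,
    build_matrix,
    combine_replicate_matrices,
    label_mass_shift,
    locate_envelope,
    quantify_oxidation,
    QuantResult,
)
from thiolox.synthetic import SimConfig, gen_spectrum, gen_trajectories

GAPDH = PeptideSpec("GapDH_144_160", "TDH", (150, 154), 2161.13, 1)


@pytest.mark.parametrize(
    "n_cys, delta, expected",
    [
        (2, 9.0, 18.0),  # the nominal 18 Da two-cysteine shift
        (0, 9.0302, 0.0),
        (3, 9.0302, 27.0906),
    ],
)
def test_label_mass_shift(n_cys, delta, expected):
    assert label_mass_shift(n_cys, LabelConfig(per_label_delta=delta)) == pytest.approx(
        expected, abs=1e-9
    )


def test_label_mass_shift_rejects_negative_count():
    with pytest.raises(ValueError):
        label_mass_shift(-1)


class TestLocateEnvelope:
    def test_single_peak_at_target(self):
        s = Spectrum([500.0], [123.0])
        env = locate_envelope(s, 500.0)
        assert env.intensity == 123.0 and not env.missing

    def test_empty_spectrum_is_flagged_zero(self):
        env = locate_envelope(Spectrum([], []), 500.0)
        assert env.intensity == 0.0 and env.missing

    def test_generated_envelope_total_recovered(self):
        """Envelope sum equals the generator's per-state total exactly."""
        cfg = LabelConfig()
        f = 0.3
        s = gen_spectrum(GAPDH, f, cfg, noise=0.0, total_intensity=1e5)
        light = locate_envelope(s, GAPDH.reduced_mz, cfg)
        heavy = locate_envelope(s, GAPDH.reduced_mz + 2 * cfg.per_label_delta, cfg)
        # the two states share the same envelope shape, so the ratio is exact
        assert heavy.intensity / (light.intensity + heavy.intensity) == pytest.approx(
            f, abs=1e-12
        )
        assert light.intensity + heavy.intensity == pytest.approx(
            s.intensity.sum(), rel=1e-9
        )


class TestQuantify:
    def test_two_state_seventy_percent(self):
        """30:70 light:heavy intensity on a 2-Cys peptide reads 70% oxidized."""
        cfg = LabelConfig()
        mz = [GAPDH.reduced_mz, GAPDH.reduced_mz + 2 * cfg.per_label_delta]
        r = quantify_oxidation(Spectrum(mz, [30.0, 70.0]), GAPDH, cfg)
        assert r.percent_oxidized == pytest.approx(70.0)

    def test_all_light_is_zero(self):
        r = quantify_oxidation(Spectrum([GAPDH.reduced_mz], [100.0]), GAPDH)
        assert r.percent_oxidized == pytest.approx(0.0)

    def test_full_state_formula(self):
        """I = (50, 50, 0) on 2 cysteines -> sum(k I_k)/(n sum I_k) = 25%."""
        cfg = LabelConfig()
        mz = [GAPDH.reduced_mz + k * cfg.per_label_delta for k in (0, 1)]
        r = quantify_oxidation(Spectrum(mz, [50.0, 50.0]), GAPDH, cfg, mode="full")
        assert r.percent_oxidized == pytest.approx(25.0)

    def test_no_signal_is_unquantifiable(self):
        r = quantify_oxidation(Spectrum([100.0], [5.0]), GAPDH)
        assert r.percent_oxidized is None and "unquantifiable" in r.flags

    def test_modes_agree_without_mixed_states(self):
        s = gen_spectrum(GAPDH, 0.4, noise=0.0)
        two = quantify_oxidation(s, GAPDH, mode="two_state")
        full = quantify_oxidation(s, GAPDH, mode="full")
        assert two.percent_oxidized == pytest.approx(full.percent_oxidized, abs=1e-9)

    @given(
        f=st.floats(0.0, 1.0),
        c=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_and_bounds(self, f, c):
        s = gen_spectrum(GAPDH, f, noise=0.0)
        r1 = quantify_oxidation(s, GAPDH)
        r2 = quantify_oxidation(s.scaled(c), GAPDH)
        assert r1.percent_oxidized == pytest.approx(r2.percent_oxidized, abs=1e-6)
        assert 0.0 <= r1.percent_oxidized <= 100.0

    def test_round_trip_exact_at_zero_noise(self):
        for f in np.linspace(0.0, 1.0, 11):
            s = gen_spectrum(GAPDH, float(f), noise=0.0)
            r = quantify_oxidation(s, GAPDH)
            assert abs(r.percent_oxidized / 100.0 - f) <= 0.01

    def test_recovery_under_peak_noise(self):
        """|f_hat - f| <= 2 points for >= 95% of 200 spectra at 5% peak noise."""
        rng = np.random.default_rng(42)
        errors = []
        for i in range(200):
            f = float(rng.uniform(0.05, 0.95))
            s = gen_spectrum(GAPDH, f, noise=0.05, seed=2000 + i)
            r = quantify_oxidation(s, GAPDH)
            errors.append(abs(r.percent_oxidized - 100.0 * f))
        assert np.mean(np.asarray(errors) <= 2.0) >= 0.95


class TestAggregate:
    @staticmethod
    def _results(values, day=0.0, pid="p1"):
        return [
            QuantResult(pid, v, {}, frozenset(), day=day, replicate=i)
            for i, v in enumerate(values)
        ]

    def test_identical_replicates(self):
        (agg,) = aggregate_replicates(self._results([70.0, 70.0, 70.0]))
        assert (agg.mean, agg.sd, agg.n) == (70.0, 0.0, 3)

    def test_below_min_replicates_is_masked(self):
        (agg,) = aggregate_replicates(self._results([60.0, 80.0]))
        assert agg.masked and agg.n == 2

    def test_sample_sd(self):
        (agg,) = aggregate_replicates(self._results([26.0, 22.0, 28.0, 24.0]))
        assert agg.mean == pytest.approx(25.0)
        assert agg.sd == pytest.approx(2.581988897, abs=1e-6)
        assert agg.n == 4

    def test_empty_input(self):
        assert aggregate_replicates([]) == []


class TestBuildMatrix:
    def test_duplicate_entries_rejected(self):
        aggs = [Aggregate("p", 0.0, 10.0, None, 4), Aggregate("p", 0.0, 12.0, None, 4)]
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix(aggs, [0, 1], "standard")

    def test_strict_filter_drops_partial_rows(self):
        aggs = [
            Aggregate("full", 0.0, 10.0, None, 4),
            Aggregate("full", 1.0, 20.0, None, 4),
            Aggregate("partial", 0.0, 10.0, None, 4),
            Aggregate("partial", 1.0, None, None, 1),  # masked day
        ]
        strict = build_matrix(aggs, [0, 1], "standard", strict=True)
        assert strict.peptides == ["full"]
        loose = build_matrix(aggs, [0, 1], "standard")
        assert set(loose.peptides) == {"full", "partial"}

    def test_strict_size_matches_replicate_scan(self):
        """Strict-set size equals a direct recount over replicate coverage."""
        cfg = SimConfig(n_peptides=60, seed=9, noise_sd=5.0, missing_rate=0.1)
        replicates, _ = gen_trajectories(cfg)
        combined = combine_replicate_matrices(replicates, min_replicates=3)
        strict = combined.strict_subset()
        # independent scan: a row survives iff every day has >= 3 finite replicates
        survivors = 0
        for pid in replicates[0].peptides:
            counts = sum(r.mean.loc[pid].notna().astype(int) for r in replicates)
            survivors += int((counts >= 3).all())
        assert len(strict.peptides) == survivors
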