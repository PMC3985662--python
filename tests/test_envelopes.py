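"""Centroiding, uptake normalization, back-exchange, EX1 detection,
charge merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hdxpipe.chemistry import ExchangeConditions
from hdxpipe.envelopes import (
    UptakePoint,
    analyze_envelopes,
    centroid,
    dataset_backexchange,
    detect_bimodal,
    deuterons_corrected,
    estimate_backexchange,
    mass_shift,
    measurable_amides,
    merge_charge_states,
    mixture_average_shift,
    percent_exchange,
)
from hdxpipe.spectra import DELTA_MASS_D, IsotopicEnvelope
from hdxpipe.synthetic import generate_state, simulate_envelope
from hdxpipe.synthetic import H3_SEQ

from conftest import make_peptide


def env_of(mz, intensity, **kw):
    defaults = dict(
        peptide_id="p", chain="X", start=1, end=9, sequence="IRRYQKSTE",
        charge=1, time_s=10.0,
    )
    defaults.update(kw)
    return IsotopicEnvelope(mz=np.asarray(mz, float), intensity=np.asarray(intensity, float), **defaults)


class TestCentroid:
    def test_single_peak(self):
        assert centroid(env_of([500.0], [3.0])) == 500.0

    def test_symmetric_pair(self):
        assert centroid(env_of([500.0, 501.0], [2.0, 2.0])) == 500.5

    @settings(deadline=None, max_examples=50)
    @given(
        mzs=st.lists(st.floats(100, 2000), min_size=5, max_size=5, unique=True),
        intens=st.lists(st.floats(0.01, 1e6), min_size=5, max_size=5),
    )
    def test_matches_weighted_mean(self, mzs, intens):
        mzs = sorted(mzs)
        brute = sum(m * i for m, i in zip(mzs, intens)) / sum(intens)
        assert centroid(env_of(mzs, intens)) == pytest.approx(brute, abs=1e-9)

    def test_within_range_and_rejects_zero(self):
        e = env_of([400.0, 402.0, 404.0], [1.0, 5.0, 1.0])
        assert 400.0 <= centroid(e) <= 404.0
        e.intensity = np.zeros(3)
        with pytest.raises(ValueError):
            centroid(e)


class TestMeasurableAmides:
    @pytest.mark.parametrize(
        "seq,expected",
        [("IRRYQKSTE", 7), ("AAPA", 1), ("APA", 1), ("AAAPPA", 2)],
    )
    def test_formula(self, seq, expected):
        assert measurable_amides(seq) == expected


class TestShiftAndPercent:
    def test_identical_envelopes_zero_shift(self):
        e = env_of([500.0, 501.0], [1.0, 2.0])
        assert mass_shift(e, e) == 0.0

    def test_charge_scaling(self, toy_state, cond):
        p = make_peptide(toy_state.chains["X"], "X", 10, 20)
        shifts = []
        for z in (1, 2):
            und = simulate_envelope(p, z, toy_state, "undeut", cond)
            env = simulate_envelope(p, z, toy_state, 1e3, cond)
            shifts.append(mass_shift(env, und))
        assert shifts[0] == pytest.approx(shifts[1], abs=1e-9)

    def test_key_mismatch_rejected(self):
        a = env_of([500.0], [1.0])
        b = env_of([500.0], [1.0], peptide_id="q")
        with pytest.raises(ValueError, match="mismatch"):
            mass_shift(a, b)

    def test_fd_self_normalization(self):
        assert percent_exchange(3.7, 3.7) == 100.0
        assert percent_exchange(0.0, 3.7) == 0.0

    def test_unusable_fd(self):
        with pytest.raises(ValueError):
            percent_exchange(1.0, 0.0)

    def test_simulated_plateau_reaches_100(self, toy_state, cond):
        p = make_peptide(toy_state.chains["X"], "X", 10, 20)
        und = simulate_envelope(p, 2, toy_state, "undeut", cond)
        fd = simulate_envelope(p, 2, toy_state, "FD", cond, backexchange_fraction=0.18)
        late = simulate_envelope(p, 2, toy_state, 1e12, cond, backexchange_fraction=0.18)
        pct = percent_exchange(mass_shift(late, und), mass_shift(fd, und))
        assert pct == pytest.approx(100.0, abs=1e-6)


class TestDeuterons:
    def test_paper_peptide_maximum(self, cond):
        assert deuterons_corrected(100.0, "IRRYQKSTE", cond) == pytest.approx(5.25)

    def test_zero(self, cond):
        assert deuterons_corrected(0.0, "IRRYQKSTE", cond) == 0.0

    def test_single_amide_half(self, cond):
        assert deuterons_corrected(50.0, "AAPA", cond) == pytest.approx(0.375)

    def test_plateau_corrected_convention(self, cond):
        assert deuterons_corrected(100.0, "IRRYQKSTE", cond, plateau_corrected=True) == 7.0


class TestBackexchange:
    def test_theoretical_max_gives_zero(self, cond):
        n = measurable_amides("IRRYQKSTE")
        assert estimate_backexchange(n * 0.75 * DELTA_MASS_D, "IRRYQKSTE", cond) == 0.0

    def test_noiseless_inversion(self, toy_state, cond):
        p = make_peptide(toy_state.chains["X"], "X", 8, 21)
        und = simulate_envelope(p, 2, toy_state, "undeut", cond)
        fd = simulate_envelope(p, 2, toy_state, "FD", cond, backexchange_fraction=0.18)
        est = estimate_backexchange(mass_shift(fd, und), p.sequence, cond)
        assert est == pytest.approx(0.18, abs=1e-6)

    def test_negative_estimate_clipped(self, cond):
        n = measurable_amides("IRRYQKSTE")
        too_big = 1.2 * n * 0.75 * DELTA_MASS_D
        assert estimate_backexchange(too_big, "IRRYQKSTE", cond) == 0.0

    def test_dataset_mean_recovers_generator(self, toy_dataset_noisy, cond):
        df = dataset_backexchange(toy_dataset_noisy.envelopes, cond)
        assert len(df) == len(toy_dataset_noisy.pool)
        truth = np.mean(list(toy_dataset_noisy.true_backexchange.values()))
        assert df["backexchange"].mean() == pytest.approx(truth, abs=0.02)


def ex1_state(k_open, start=5, end=20, seq=H3_SEQ[:30]):
    return generate_state(
        {
            "chains": {"X": seq},
            "default_class": "C6",
            "ex1_regions": [{"chain": "X", "start": start, "end": end, "k_open": k_open}],
        },
        seed=0,
    )


class TestBimodalDetection:
    def test_pure_ex2_is_unimodal(self, toy_state, cond):
        rng = np.random.default_rng(1)
        p = make_peptide(toy_state.chains["X"], "X", 10, 22)
        und = simulate_envelope(p, 2, toy_state, "undeut", cond)
        env = simulate_envelope(
            p, 2, toy_state, 1e3, cond, backexchange_fraction=0.18,
            noise_sd=0.02, rng=rng, intensity_floor=1e-3,
        )
        assert detect_bimodal(env, und, p.sequence, cond).modality == "unimodal"

    def test_half_open_ex1_recovers_weights(self, cond):
        st_ = ex1_state(np.log(2) / 1e4)
        p = make_peptide(st_.chains["X"], "X", 5, 20, pid="ex1")
        und = simulate_envelope(p, 2, st_, "undeut", cond)
        env = simulate_envelope(p, 2, st_, 1e4, cond)
        fit = detect_bimodal(env, und, p.sequence, cond)
        assert fit.modality == "bimodal"
        weights = sorted(w for w, _, _ in fit.components)
        assert weights[0] == pytest.approx(0.5, abs=0.1)
        sep = abs(fit.components[1][1] - fit.components[0][1]) * 2
        assert sep > 3.0  # Da

    def test_ex1_flags_concentrated_at_intermediate_times(self, cond):
        """Bimodality shows at intermediate times and clears at full
        exchange, mirroring observed EX1 time courses."""
        st_ = ex1_state(1e-4)
        p = make_peptide(st_.chains["X"], "X", 5, 20, pid="ex1")
        und = simulate_envelope(p, 2, st_, "undeut", cond)
        modality = {}
        for t in (1e1, 1e3, 1e4, 1e6):
            env = simulate_envelope(p, 2, st_, t, cond)
            modality[t] = detect_bimodal(env, und, p.sequence, cond).modality
        assert modality[1e3] == "bimodal" and modality[1e4] == "bimodal"
        assert modality[1e1] == "unimodal" and modality[1e6] == "unimodal"

    def test_mixture_average_equals_centroid_shift(self, cond):
        st_ = ex1_state(1e-4)
        p = make_peptide(st_.chains["X"], "X", 5, 20, pid="ex1")
        und = simulate_envelope(p, 2, st_, "undeut", cond)
        env = simulate_envelope(p, 2, st_, 1e4, cond)
        fit = detect_bimodal(env, und, p.sequence, cond)
        assert mixture_average_shift(fit, und, 2) == pytest.approx(
            mass_shift(env, und), abs=0.05
        )


def make_point(pct, intensity=1.0, z=1, **kw):
    d = dict(
        peptide_id="p", chain="X", start=1, end=9, sequence="IRRYQKSTE",
        time_s=10.0, mass_shift_da=pct / 100 * 5.25 * DELTA_MASS_D,
        percent=pct, deuterons=pct / 100 * 5.25, charge=z, total_intensity=intensity,
    )
    d.update(kw)
    return UptakePoint(**d)


class TestChargeMerging:
    def test_single_state_identity(self):
        m = merge_charge_states([make_point(42.0)])
        assert m.percent == 42.0 and m.charge is None

    def test_equal_intensity_mean(self):
        m = merge_charge_states([make_point(40.0, z=1), make_point(60.0, z=2)])
        assert m.percent == pytest.approx(50.0)

    def test_disagreement_flagged_not_dropped(self):
        m = merge_charge_states([make_point(30.0, z=1), make_point(70.0, z=2)], tolerance=10.0)
        assert "charge_disagreement" in m.qc_flags

    def test_cannot_merge_across_times(self):
        with pytest.raises(ValueError):
            merge_charge_states([make_point(40.0), make_point(60.0, time_s=100.0)])

    def test_multicharge_dataset_merges_close_to_truth(self, toy_state, cond):
        """Merged uptake within one percentage point of the noiseless
        ground-truth value."""
        from hdxpipe.synthetic import PeptidePool, simulate_dataset
        from conftest import make_peptide as mp

        p = mp(toy_state.chains["X"], "X", 8, 21, charges=(1, 2, 3), pid="mc")
        pool = PeptidePool([p])
        noisy = simulate_dataset(toy_state, pool, cond, seed=8)
        clean = simulate_dataset(
            toy_state, pool, cond, noise_sd=0.0, intensity_floor=0.0,
            backexchange_sd=0.0, seed=8,
        )
        up_noisy = analyze_envelopes(noisy.envelopes, cond, detect_ex1=False)
        up_clean = analyze_envelopes(clean.envelopes, cond, detect_ex1=False)
        joined = up_noisy.merge(
            up_clean, on=["peptide_id", "time_s"], suffixes=("", "_true")
        )
        assert (
            (joined["percent_exchange"] - joined["percent_exchange_true"]).abs() < 1.0
        ).all()
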