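"""Paired-recording pipeline: QC, detection, failure rates, deconvolution,
matrix arithmetic, nonparametric statistics."""

import numpy as np
import pandas as pd
import pytest

from spwnet.connectivity import (Cell, PairRecording, PairScreen, qc_filter,
                                 measure_connection, failure_rate,
                                 deconvolve_stp, rate_matrix, strength_matrix,
                                 synaptic_product, compare_groups,
                                 dunn_posthoc, measure_screen)
from spwnet.synthetic import psp_kernel

FS = 20.0                       # kHz
AP = np.array([20.0, 70.0, 120.0, 170.0])
T = np.arange(int(250 * FS)) / FS


def make_sweeps(amp=1.0, lat=1.5, n=40, noise=0.0, depression=1.0,
                release=None, rng=None, vm=-65.0):
    rng = rng or np.random.default_rng(0)
    sweeps = np.full((n, len(T)), vm)
    for s in range(n):
        for k, a in enumerate(AP):
            if release is not None and rng.random() >= release:
                continue
            sweeps[s] += amp * depression ** k * psp_kernel(T - a - lat)
    if noise:
        sweeps += rng.normal(0, noise, sweeps.shape)
    return sweeps


def make_screen(pair_specs, cells=None):
    cells = cells or [Cell(0, "A", -65, 15), Cell(1, "T", -66, 12)]
    pairs = [PairRecording(pre, post, sw, np.full((len(sw), 4), 30.0))
             for pre, post, sw in pair_specs]
    return PairScreen(cells=cells, pairs=pairs, ap_times=AP, fs_khz=FS)


class TestQC:
    def test_depolarized_cell_removed_with_pairs(self):
        cells = [Cell(0, "A", -45.0, 15), Cell(1, "T", -66, 12)]
        scr = make_screen([(0, 1, make_sweeps())], cells)
        out = qc_filter(scr)
        assert [c.id for c in out.cells] == [1]
        assert out.pairs == []

    def test_high_series_resistance_removed(self):
        cells = [Cell(0, "A", -65.0, 35.0), Cell(1, "T", -66, 12)]
        out = qc_filter(make_screen([(0, 1, make_sweeps())], cells))
        assert [c.id for c in out.cells] == [1]

    def test_failed_ap_sweep_removed(self):
        scr = make_screen([(0, 1, make_sweeps(n=12))])
        scr.pairs[0].ap_peaks[3, 1] = -5.0
        out = qc_filter(scr)
        assert len(out.pairs[0].sweeps) == 11

    def test_drifting_sweep_removed(self):
        sweeps = make_sweeps(n=12)
        sweeps[5] += 10.0  # ~15% baseline shift on -65 mV
        out = qc_filter(make_screen([(0, 1, sweeps)]))
        assert len(out.pairs[0].sweeps) == 11

    def test_compliant_screen_is_identity(self):
        scr = make_screen([(0, 1, make_sweeps(n=15))])
        out = qc_filter(scr)
        assert len(out.cells) == 2
        assert len(out.pairs[0].sweeps) == 15


class TestMeasureConnection:
    def test_pure_noise_not_connected(self):
        sweeps = make_sweeps(amp=0.0, noise=0.2)
        assert not measure_connection(sweeps, AP, FS).connected

    def test_noiseless_epsp_exact_amplitude(self):
        m = measure_connection(make_sweeps(amp=0.8), AP, FS)
        assert m.connected
        assert m.amplitude == pytest.approx(0.8, rel=0.02)

    def test_noisy_recovery_within_tolerances(self):
        m = measure_connection(make_sweeps(amp=1.0, lat=1.5, noise=0.2), AP, FS)
        assert m.connected
        assert m.amplitude == pytest.approx(1.0, abs=0.1)
        # 20%-of-peak onset sits ~0.35 ms after the true kernel onset
        assert m.latency == pytest.approx(1.85, abs=0.3)
        assert m.monosynaptic

    def test_long_latency_flagged_polysynaptic(self):
        m = measure_connection(make_sweeps(amp=1.0, lat=4.0), AP, FS)
        assert m.connected and not m.monosynaptic


class TestFailureRate:
    def test_always_present_zero(self):
        assert failure_rate(make_sweeps(amp=1.5), AP, FS) == 0.0

    def test_all_failures_hundred(self):
        assert failure_rate(make_sweeps(amp=0.0, noise=0.05), AP, FS) == 100.0

    def test_release_probability_recovered(self):
        rng = np.random.default_rng(3)
        sweeps = make_sweeps(amp=2.5, noise=0.15, release=0.7, rng=rng)
        f = failure_rate(sweeps, AP, FS)
        # binomial sd on 160 occasions ~ 3.6%
        assert f == pytest.approx(30.0, abs=8.0)


class TestDeconvolution:
    def test_single_exponential_becomes_impulse(self):
        # d(t) = tau*dV/dt + V annihilates a tau-decaying PSP: impulse at
        # onset, then ~zero (temporal summation removed)
        v = 2.0 * np.exp(-np.maximum(T - 21.5, 0) / 55.0)
        v[T < 21.5] = 0.0
        d = 55.0 * np.gradient(v) * FS + v   # FS in kHz -> dV/dt in mV/ms
        assert np.abs(d[int(30 * FS):]).max() < 0.02 * v.max()

    def test_two_identical_pulses_normalize_to_one(self):
        v = psp_kernel(T - 20 - 1.5) + psp_kernel(T - 170 - 1.5)
        norm, ratio = deconvolve_stp(v, np.array([20.0, 170.0]), FS)
        assert norm == pytest.approx([1.0, 1.0], abs=0.05)

    def test_depression_ratio_recovered(self):
        avg = make_sweeps(amp=1.0, depression=0.8, n=1)[0]
        norm, ratio = deconvolve_stp(avg, AP, FS)
        assert ratio == pytest.approx(0.8 ** 3, abs=0.05)
        assert norm[1] == pytest.approx(0.8, abs=0.05)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError):
            deconvolve_stp(np.zeros_like(T), AP, FS)


class TestMatrices:
    def _measurements(self, tested, connected):
        """Synthetic measurement table with given per-type counts."""
        rows = []
        uid = 0
        for (post, pre), n in tested.items():
            k = connected.get((post, pre), 0)
            for i in range(n):
                rows.append({"pre_id": uid, "post_id": uid + 1,
                             "pre_type": pre, "post_type": post,
                             "connected": i < k, "amplitude_mv": 1.0,
                             "latency_ms": 1.5})
                uid += 2
        return pd.DataFrame(rows)

    def test_published_overall_rate_arithmetic(self):
        # 65 connections out of 734 ordered pairs -> 8.9%
        m = self._measurements({("A", "A"): 92, ("A", "T"): 200,
                                ("T", "T"): 362, ("T", "A"): 80},
                               {("A", "A"): 14, ("A", "T"): 22,
                                ("T", "T"): 26, ("T", "A"): 3})
        r = rate_matrix(m)
        assert r["overall_tested"] == 734
        assert r["overall_connected"] == 65
        assert round(r["overall_rate_pct"], 1) == 8.9

    def test_rates_recompute_from_counts(self):
        m = self._measurements({("A", "A"): 100}, {("A", "A"): 15})
        r = rate_matrix(m)
        assert r["rates_pct"].loc["A", "A"] == pytest.approx(
            100.0 * r["connected"].loc["A", "A"] / r["tested"].loc["A", "A"])

    def test_reciprocal_counting(self):
        rows = []
        for pre, post, conn in [(0, 1, True), (1, 0, True),
                                (2, 3, True), (3, 2, False)]:
            rows.append({"pre_id": pre, "post_id": post, "pre_type": "A",
                         "post_type": "A", "connected": conn,
                         "amplitude_mv": 1.0, "latency_ms": 1.0})
        r = rate_matrix(pd.DataFrame(rows))
        assert r["reciprocal_connections"].get("AA", 0) == 2  # one pair, both ways

    def test_empty_screen_empty_matrix(self):
        r = rate_matrix(pd.DataFrame(columns=["pre_id", "post_id", "pre_type",
                                              "post_type", "connected"]))
        assert r["overall_tested"] == 0
        assert np.isnan(r["overall_rate_pct"])


class TestSynapticProduct:
    def _rates(self):
        return pd.DataFrame([[15.0, 11.0], [4.0, 8.0]],
                            index=["A", "T"], columns=["A", "T"])

    def _strengths(self):
        return pd.DataFrame([[1.08, 0.88], [0.66, 0.57]],
                            index=["A", "T"], columns=["A", "T"])

    def test_published_ordering(self):
        prod = synaptic_product(self._rates(), self._strengths())
        assert prod.loc["A", "T"] == pytest.approx(0.11 * 0.88 * 0.66, abs=1e-9)
        assert prod.loc["A", "A"] == pytest.approx(0.15 * 1.08 * 0.34, abs=1e-9)
        # thorny->athorny pathway dominates, then athorny->athorny
        flat = prod.stack().sort_values(ascending=False)
        assert flat.index[0] == ("A", "T")
        assert flat.index[1] == ("A", "A")

    def test_zero_rate_zero_product(self):
        r = self._rates()
        r.loc["T", "A"] = 0.0
        assert synaptic_product(r, self._strengths()).loc["T", "A"] == 0.0

    def test_identity_strengths_equal_fractions_proportional_to_rates(self):
        ones = self._strengths() * 0 + 1.0
        prod = synaptic_product(self._rates(), ones,
                                pre_fractions={"A": 0.5, "T": 0.5})
        assert np.allclose(prod.values, self._rates().values / 100.0 * 0.5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            synaptic_product(self._rates() * -1, self._strengths())


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        x = np.linspace(0, 1, 30)
        res = compare_groups({"a": x, "b": x.copy()})
        assert res["p_value"] > 0.5
        assert not res["significant"]

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        res = compare_groups({"a": a, "b": b})
        assert res["test"] == "mann-whitney-u"
        assert res["p_value"] < 1e-3

    def test_four_group_omnibus_and_posthoc(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(0, 1, 25) for g in "abc"}
        groups["d"] = rng.normal(3, 1, 25)
        res = compare_groups(groups)
        assert res["test"] == "kruskal-wallis"
        assert res["significant"]
        ph = res["posthoc"]
        sig_pairs = set(map(tuple, ph[ph.significant][["group1", "group2"]].values))
        assert all("d" in pair for pair in sig_pairs)
        assert len(sig_pairs) == 3

    def test_small_group_reported_insufficient(self):
        res = compare_groups({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        assert res["insufficient_data"] == ["a"]

    def test_dunn_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(0, 1, 10) for g in "abcd"}
        ph = dunn_posthoc(groups)
        assert (ph.p_adj <= 1.0).all()
        assert len(ph) == 6
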