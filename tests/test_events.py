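"""Event detection, morphology and threshold machinery.

The reference for the detector is a brute-force sample scan implemented here
with explicit python loops (independent of the vectorized implementation).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betaburst.data import BetaSeries
from betaburst.events import (EventConfig, detect_events, empirical_threshold,
                              event_duration, extract_metrics,
                              summarize_trial, threshold_value)
from betaburst.synth import simulate_power_series

FS = 1000.0
WINDOW = (-1.0, -0.05)
N_T = int(round((WINDOW[1] - WINDOW[0]) * FS)) + 1
TIMES = WINDOW[0] + np.arange(N_T) / FS


def hann_power(peak_time, fwhm, peak=1.0, times=TIMES):
    """Hann-squared power profile with the given half-max width."""
    T = fwhm / (2 * math.acos(2.0 ** -0.25) / math.pi)
    out = np.zeros_like(times)
    m = np.abs(times - peak_time) <= T / 2
    out[m] = peak * np.cos(math.pi * (times[m] - peak_time) / T) ** 4
    return out


def oracle_detect(power, times, threshold, ibf, min_cycles=1.5):
    """Sample-by-sample scan + run grouping; returns (i0, i1, peak) tuples."""
    dt = times[1] - times[0]
    runs, cur = [], None
    for i, v in enumerate(power):
        if v > threshold:
            cur = [i, i] if cur is None else [cur[0], i]
        elif cur is not None:
            runs.append(cur)
            cur = None
    if cur is not None:
        runs.append(cur)
    out = []
    for i0, i1 in runs:
        if (i1 - i0 + 1) * dt < min_cycles / ibf - 1e-12:
            continue
        pk = i0
        for j in range(i0, i1 + 1):
            if power[j] > power[pk]:
                pk = j
        if i1 == len(power) - 1 and pk == i1:
            continue
        if i0 == 0 and pk == i0:
            continue
        out.append((i0, i1, pk))
    return out


def series_from_power(power, subjects=None, ibf=20.0):
    power = np.atleast_2d(power)
    if subjects is None:
        subjects = np.array(["S01"] * len(power), dtype=object)
    subj = np.asarray(subjects, dtype=object)
    return BetaSeries(power=power, times=TIMES, fs=FS, subjects=subj,
                      trial_ids=np.arange(len(power)),
                      ibf={s: ibf for s in set(subj)},
                      norm_constant={s: 1.0 for s in set(subj)})


class TestThresholdValue:
    def test_constant_pool(self):
        bs = series_from_power(np.full((3, N_T), 2.5))
        assert threshold_value(bs, 75)["S01"] == 2.5
        assert threshold_value(bs, 98)["S01"] == 2.5

    def test_linear_interpolation_convention(self):
        assert threshold_value(np.arange(1.0, 101.0), 75) == 75.25

    def test_monotone_in_percentile(self, rng):
        pool = rng.exponential(size=5000)
        t75, t82 = threshold_value(pool, 75), threshold_value(pool, 82)
        assert t82 >= t75

    def test_empty_pool(self):
        with pytest.raises(ValueError):
            threshold_value(np.array([]), 75)


class TestDetect:
    def test_subthreshold_series_gives_no_events(self):
        assert detect_events(np.full(N_T, 0.2), TIMES, 1.0, 20.0) == []

    def test_two_bursts_detected_at_their_peaks(self):
        p = 0.1 + hann_power(-0.7, 0.15, 3.0) + hann_power(-0.3, 0.15, 3.0)
        ev = detect_events(p, TIMES, 1.0, 20.0)
        assert len(ev) == 2
        assert abs(ev[0].peak_time_s - (-0.7)) <= 0.010
        assert abs(ev[1].peak_time_s - (-0.3)) <= 0.010
        assert not ev[0].is_edge and not ev[1].is_edge
        for e in ev:
            assert e.max_amplitude > 1.0
            assert e.onset_s < e.peak_time_s < e.offset_s
            assert e.duration_s <= e.offset_s - e.onset_s + 1e-12

    def test_run_shorter_than_min_cycles_discarded(self):
        # 60 ms supra-threshold run < 1.5 cycles at 20 Hz (75 ms)
        p = np.full(N_T, 0.1)
        m = (TIMES >= -0.53) & (TIMES < -0.47)
        p[m] = 2.0
        assert detect_events(p, TIMES, 1.0, 20.0) == []
        m = (TIMES >= -0.54) & (TIMES < -0.46)
        p[m] = 2.0
        assert len(detect_events(p, TIMES, 1.0, 20.0)) == 1

    def test_non_finite_power_is_an_error(self):
        p = np.full(N_T, 0.1)
        p[10] = np.nan
        with pytest.raises(ValueError):
            detect_events(p, TIMES, 1.0, 20.0)

    def test_matches_brute_force_oracle_on_random_series(self, rng):
        for _ in range(100):
            p = rng.exponential(size=200)
            thr = float(np.percentile(p, rng.uniform(50, 98)))
            ev = detect_events(p, TIMES[:200], thr, 20.0)
            assert [(e.i0, e.i1) for e in ev] == \
                [(i0, i1) for i0, i1, _ in
                 oracle_detect(p, TIMES[:200], thr, 20.0)]

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, seed):
        r = np.random.default_rng(seed)
        p = r.gamma(r.uniform(0.5, 3.0), size=300)
        thr = float(np.percentile(p, r.uniform(50, 98)))
        ibf = float(r.uniform(15, 30))
        ev = detect_events(p, TIMES[:300], thr, ibf)
        orc = oracle_detect(p, TIMES[:300], thr, ibf)
        assert [(e.i0, e.i1) for e in ev] == [(i0, i1) for i0, i1, _ in orc]
        for e, (_, _, pk) in zip(ev, orc):
            assert e.peak_time_s == TIMES[pk]
            assert e.max_amplitude == p[pk]


class TestEdgeEvents:
    def test_declining_edge_run_is_an_event_with_doubled_duration(self):
        p = hann_power(-0.1, 0.12, 3.0)  # truncated at -0.05
        ev = detect_events(p, TIMES, 1.0, 20.0)
        assert len(ev) == 1 and ev[0].is_edge
        # symmetric profile: doubling the pre-peak half-max time must
        # reproduce the full half-max width
        assert ev[0].duration_s == pytest.approx(0.12, abs=2 / FS)

    def test_rising_run_at_pulse_edge_is_not_an_event(self):
        p = 0.1 + np.linspace(0, 3.0, N_T) ** 2
        assert detect_events(p, TIMES, 1.0, 20.0) == []

    def test_falling_run_at_window_start_is_not_an_event(self):
        p = 0.1 + np.linspace(3.0, 0, N_T) ** 2
        assert detect_events(p, TIMES, 1.0, 20.0) == []

    def test_window_start_edge_uses_post_peak_doubling(self):
        p = hann_power(-0.97, 0.12, 3.0)  # truncated at -1.0
        ev = detect_events(p, TIMES, 1.0, 20.0)
        assert len(ev) == 1 and ev[0].is_edge
        assert ev[0].duration_s == pytest.approx(0.12, abs=2 / FS)


class TestDuration:
    dt = 1e-3

    def test_rectangular_pulse(self):
        k = 80
        profile = np.r_[np.zeros(10), np.ones(k), np.zeros(10)]
        assert event_duration(profile, self.dt) == pytest.approx(k * self.dt)

    def test_symmetric_triangle(self):
        m = 100
        profile = np.r_[np.linspace(0, 1, m + 1), np.linspace(1, 0, m + 1)[1:]]
        base = 2 * m * self.dt
        assert event_duration(profile, self.dt) == pytest.approx(base / 2)

    def test_gaussian_fwhm(self):
        sigma = 0.05
        t = np.arange(-0.5, 0.5, self.dt)
        profile = np.exp(-0.5 * (t / sigma) ** 2)
        expect = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert abs(event_duration(profile, self.dt) - expect) <= self.dt


class TestSummarize:
    def test_no_events(self):
        p = np.full(N_T, 0.4)
        row = summarize_trial([], p, TIMES)
        assert row["event_present"] == 0 and row["n_events"] == 0
        assert np.isnan(row["last_timing_s"])
        assert row["mean_power"] == pytest.approx(0.4)

    def test_last_event_selected_by_peak_time(self):
        p = 0.1 + hann_power(-0.6, 0.12, 2.0) + hann_power(-0.2, 0.12, 5.0)
        ev = detect_events(p, TIMES, 1.0, 20.0)
        row = summarize_trial(ev, p, TIMES)
        assert row["n_events"] == 2
        assert row["last_timing_s"] == pytest.approx(0.2, abs=0.01)
        assert row["last_amplitude"] == pytest.approx(5.1, abs=0.1)

    def test_whole_window_run(self):
        p = 0.1 + hann_power(-0.5, 1.2, 5.0)
        ev = detect_events(p, TIMES, 1.0, 20.0)
        assert len(ev) == 1 and ev[0].is_edge


class TestMonotonicity:
    def test_kept_supra_threshold_time_non_increasing(self, rng):
        power, times, _ = simulate_power_series(5, seed=3, fs=FS)
        for p in power:
            kept = []
            for pct in range(50, 99, 4):
                thr = np.percentile(p, pct)
                ev = detect_events(p, times, thr, 20.0)
                kept.append(sum(e.i1 - e.i0 + 1 for e in ev))
            assert all(a >= b for a, b in zip(kept, kept[1:]))


class TestEmpiricalThreshold:
    def _series(self):
        pa, _, _ = simulate_power_series(8, seed=21, fs=FS)
        pb, _, _ = simulate_power_series(8, seed=22, fs=FS)
        power = np.vstack([pa, pb])
        return series_from_power(
            power, subjects=np.array(["A"] * 8 + ["B"] * 8, dtype=object))

    def test_matches_exhaustive_curve_evaluation(self):
        bs = self._series()
        pcts = np.arange(50.0, 99.0, 2.0)
        best, curve = empirical_threshold(bs, percentiles=pcts)
        # independent evaluation of the same curve (zero-variance subjects
        # drop out of the mean at that percentile)
        means = []
        for pct in pcts:
            rs = []
            for subj in ("A", "B"):
                rows = bs.subject_rows(subj)
                thr = np.percentile(bs.power[rows].ravel(), pct)
                frac, mp = [], []
                for i in rows:
                    ev = oracle_detect(bs.power[i], bs.times, thr, 20.0)
                    frac.append(sum(i1 - i0 + 1 for i0, i1, _ in ev)
                                / bs.power.shape[1])
                    mp.append(bs.power[i].mean())
                if np.std(frac) == 0 or np.std(mp) == 0:
                    rs.append(np.nan)
                else:
                    rs.append(np.corrcoef(frac, mp)[0, 1])
            means.append(np.nanmean(rs) if not np.isnan(rs).all() else np.nan)
        assert best == pcts[int(np.nanargmax(means))]
        assert np.allclose(curve["mean"].to_numpy(), means, equal_nan=True)

    def test_degenerate_subject_excluded_with_warning(self):
        power = np.vstack([np.full((3, N_T), 1.0),
                           simulate_power_series(3, seed=23, fs=FS)[0]])
        bs = series_from_power(
            power, subjects=np.array(["A"] * 3 + ["B"] * 3, dtype=object))
        with pytest.warns(UserWarning, match="zero variance"):
            best, curve = empirical_threshold(
                bs, percentiles=np.arange(50.0, 99.0, 8.0))
        assert curve["A"].isna().all()
        assert 50 <= best <= 98


def test_extract_metrics_table_schema():
    power, _, _ = simulate_power_series(6, seed=9, fs=FS)
    bs = series_from_power(power)
    table = extract_metrics(bs, EventConfig(75.0))
    assert list(table.columns) == [
        "subject", "trial", "event_present", "n_events", "last_duration_s",
        "last_amplitude", "last_timing_s", "mean_power"]
    present = table["event_present"] == 1
    assert (table.loc[present, "last_timing_s"].between(0.05, 1.0)).all()
    assert table.loc[~present, "last_timing_s"].isna().all()
    assert (table["n_events"] >= table["event_present"]).all()


def test_event_config_validation():
    with pytest.raises(ValueError):
        EventConfig(threshold_percentile=40).validate()
    with pytest.raises(ValueError):
        EventConfig(min_cycles=0).validate()
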