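"""Metric identities and the ranking rules."""

import numpy as np
import pytest

from esgkit.metrics import (MetricReport, inpsr,
                            rank_methods, residual_intensity, sep_snr,
                            single_trial_cov)
from esgkit.recording import EpochSet, EventList, Recording


def _paired_recordings(scale=1.0, n_ch=3, srate=1000.0, seed=0):
    rng = np.random.default_rng(seed)
    n = 60000
    peaks = np.arange(1000, n - 1000, 850)
    data = rng.standard_normal((n_ch, n)) + 50 * np.sin(
        2 * np.pi * 1.2 * np.arange(n) / srate)[None, :]
    ev = EventList.from_arrays(peaks, "r_peak")
    labels = ["S6", "SC6", "S14"]
    unc = Recording(data, srate, labels, ["esg_cervical"] * 3, ev)
    cln = Recording(scale * data, srate, labels, ["esg_cervical"] * 3, ev)
    return cln, unc


class TestResidualIntensity:
    def test_identical_recordings_give_100_percent(self):
        cln, unc = _paired_recordings(scale=1.0)
        coi = ("S6", "SC6", "S14")
        assert residual_intensity(cln, unc, coi) == pytest.approx(100.0)

    def test_zeroed_recording_gives_0_percent(self):
        cln, unc = _paired_recordings(scale=0.0)
        assert residual_intensity(cln, unc, ("S6", "SC6", "S14")) == 0.0

    def test_halved_recording_gives_50_percent(self):
        cln, unc = _paired_recordings(scale=0.5)
        assert residual_intensity(cln, unc, ("S6", "SC6", "S14")) == \
            pytest.approx(50.0)

    def test_mismatched_r_peaks_rejected(self):
        cln, unc = _paired_recordings()
        cln.events = EventList.from_arrays([1000, 2000], "r_peak")
        with pytest.raises(ValueError, match="R-peaks"):
            residual_intensity(cln, unc, ("S6", "SC6", "S14"))


class TestInpsr:
    def test_identity_gives_zero_log_ratio(self):
        cln, unc = _paired_recordings(scale=1.0)
        v = inpsr(cln, unc, ("S6", "SC6", "S14"))
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_halved_fundamental_tone_gives_0_602(self):
        srate, n = 1000.0, 120000
        f0 = 1.2
        t = np.arange(n) / srate
        x = np.sin(2 * np.pi * f0 * t)[None, :]
        labels, roles = ["SC6"], ["esg_cervical"]
        unc = Recording(x, srate, labels, roles, EventList())
        cln = Recording(0.5 * x, srate, labels, roles, EventList())
        v = inpsr(cln, unc, ("SC6",), mean_hr=f0)
        assert v == pytest.approx(np.log10(4.0), abs=1e-6)   # 0.602

    def test_band_power_ratio_matches_analytic_oracle(self):
        # tones at f0..5 f0 plus one out-of-band tone; cleaning attenuates the
        # in-band tones by 0.3, so the analytic power ratio is 1 / 0.3^2
        srate, n, f0 = 1000.0, 240000, 1.3
        t = np.arange(n) / srate
        rng = np.random.default_rng(0)
        inband = sum(np.sin(2 * np.pi * m * f0 * t + rng.uniform(0, 6))
                     for m in range(1, 6))
        outband = 2.0 * np.sin(2 * np.pi * 20.0 * t)
        unc = Recording((inband + outband)[None, :], srate, ["SC6"],
                        ["esg_cervical"], EventList())
        cln = Recording((0.3 * inband + outband)[None, :], srate, ["SC6"],
                        ["esg_cervical"], EventList())
        v = inpsr(cln, unc, ("SC6",), mean_hr=f0)
        expected = np.log10(1 / 0.3 ** 2)
        assert abs(10 ** v - 10 ** expected) / 10 ** expected < 0.05

    def test_band_above_nyquist_dropped(self):
        srate = 100.0
        x = np.random.default_rng(0).standard_normal((1, 12000))
        unc = Recording(x, srate, ["SC6"], ["esg_cervical"], EventList())
        v = inpsr(unc, unc, ("SC6",), mean_hr=15.0)  # harmonics 30,45 > 50 Hz
        assert v == pytest.approx(0.0)


def _epochset_from_average(avg, tmin=-0.2, srate=1000.0, n_trials=3,
                           labels=None):
    data = np.tile(avg[None, :, :], (n_trials, 1, 1))
    labels = labels or [f"ch{i}" for i in range(avg.shape[0])]
    n_t = avg.shape[1]
    return EpochSet(data, tmin, tmin + (n_t - 1) / srate, srate, labels,
                    baseline=(-0.1, -0.01))


class TestSepSnr:
    def _avg_with_peak(self, peak_uv, latency=0.013, baseline_pattern=None):
        srate, tmin = 1000.0, -0.2
        n_t = 901
        avg = np.zeros((1, n_t))
        if baseline_pattern is not None:
            b0 = int(round((-0.1 - tmin) * srate))
            avg[0, b0:b0 + len(baseline_pattern)] = baseline_pattern
        avg[0, int(round((latency - tmin) * srate))] = peak_uv
        return avg

    def test_definition_peak_over_baseline_std(self):
        # 91 samples cover the full (-0.1, -0.01) baseline window at 1000 Hz
        pattern = np.append(np.tile([1.0, -1.0], 45), 1.0)
        avg = self._avg_with_peak(-5.0, baseline_pattern=pattern)
        ep = _epochset_from_average(avg)
        expected = 5.0 / pattern.std(ddof=1)
        assert sep_snr(ep, "median") == pytest.approx(expected)

    def test_scale_invariance(self):
        pattern = np.sin(np.arange(90))
        avg = self._avg_with_peak(-4.0, baseline_pattern=pattern)
        s1 = sep_snr(_epochset_from_average(avg), "median")
        s2 = sep_snr(_epochset_from_average(7.5 * avg), "median")
        assert s1 == pytest.approx(s2)

    def test_deepest_channel_wins(self):
        # channels with -3 and -4 uV peaks: the -4 channel's baseline is used
        srate, tmin = 1000.0, -0.2
        avg = np.zeros((2, 901))
        rng = np.random.default_rng(5)
        b0, b1 = int(0.1 * srate), int(0.19 * srate)
        avg[0, b0:b1] = rng.normal(0, 1.0, b1 - b0)
        avg[1, b0:b1] = rng.normal(0, 2.0, b1 - b0)
        i13 = int(round((0.013 - tmin) * srate))
        avg[0, i13] = -3.0
        avg[1, i13 + 2] = -4.0
        ep = _epochset_from_average(avg)
        # exhaustive oracle over channels x window samples
        w0 = int(round((0.008 - tmin) * srate))
        w1 = int(round((0.018 - tmin) * srate)) + 1
        seg = avg[:, w0:w1]
        ch = np.unravel_index(np.argmin(seg), seg.shape)[0]
        base = avg[ch, int(round((-0.1 - tmin) * srate)):
                   int(round((-0.01 - tmin) * srate)) + 1]
        expected = abs(seg.min()) / base.std(ddof=1)
        assert ch == 1
        assert sep_snr(ep, "median") == pytest.approx(expected)


class TestCov:
    def test_identical_trials_give_zero(self):
        trials = np.tile(np.sin(np.arange(100) / 5.0), (8, 1))
        assert single_trial_cov(trials, "median", tmin=0.0, srate=1000.0) == 0.0

    def test_joint_scaling_invariance(self, rng):
        trials = rng.standard_normal((20, 100)) + 5
        c1 = single_trial_cov(trials, "median", tmin=0.0, srate=1000.0)
        c2 = single_trial_cov(3.7 * trials, "median", tmin=0.0, srate=1000.0)
        assert c1 == pytest.approx(c2)

    def test_two_point_formula(self):
        # peak-to-peak amplitudes {1, 3}: mean 2, sample std sqrt(2)
        trials = np.zeros((2, 100))
        trials[0, 10], trials[0, 12] = 0.5, -0.5
        trials[1, 10], trials[1, 12] = 1.5, -1.5
        c = single_trial_cov(trials, "median", tmin=0.0, srate=1000.0)
        assert c == pytest.approx(np.sqrt(2.0) / 2.0)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="trials"):
            single_trial_cov(np.ones((1, 100)), "median", tmin=0.0, srate=1000.0)


class TestRanking:
    def _reports(self, metrics):
        return [MetricReport(method=m, condition="median", ri=ri,
                             inpsr_log=ip, snr=snr)
                for m, (ri, ip, snr) in metrics.items()]

    def test_best_on_everything_scores_one(self):
        reports = self._reports({"a": (1.0, 3.0, 10.0), "b": (2.0, 2.0, 5.0),
                                 "c": (3.0, 1.0, 1.0)})
        rt = rank_methods(reports)
        assert rt.table.loc["a", "overall"] == 1.0
        assert rt.best() == "a"

    def test_weighted_formula(self):
        # ranks ri=3, inpsr=2, snr=1 -> (1.5 + 1 + 1)/2 = 1.75
        reports = self._reports({"a": (3.0, 2.0, 9.0), "b": (1.0, 3.0, 5.0),
                                 "c": (2.0, 1.0, 7.0)})
        rt = rank_methods(reports)
        assert rt.table.loc["a", ["rank_ri", "rank_inpsr", "rank_snr"]
                            ].tolist() == [3.0, 2.0, 1.0]
        assert rt.table.loc["a", "overall"] == pytest.approx(1.75)

    def test_ties_share_mean_rank(self):
        reports = self._reports({"a": (1.0, 2.57, 5.0), "b": (2.0, 2.57, 5.0),
                                 "c": (3.0, 1.0, 9.0)})
        rt = rank_methods(reports)
        assert rt.table.loc["a", "rank_inpsr"] == 1.5
        assert rt.table.loc["b", "rank_inpsr"] == 1.5

    def test_invariant_to_monotone_metric_transforms(self):
        vals = {"a": (1.0, 3.0, 10.0), "b": (2.5, 2.0, 5.0), "c": (3.0, 1.5, 1.0)}
        rt1 = rank_methods(self._reports(vals))
        warped = {m: (ri ** 3, np.exp(ip), np.log(snr))
                  for m, (ri, ip, snr) in vals.items()}
        rt2 = rank_methods(self._reports(warped))
        cols = ["rank_ri", "rank_inpsr", "rank_snr", "overall"]
        assert rt1.table[cols].equals(rt2.table[cols])

    def test_missing_metric_raises_with_method_name(self):
        reports = self._reports({"a": (1.0, 3.0, 10.0)})
        reports.append(MetricReport(method="broken", condition="median",
                                    ri=1.0, inpsr_log=None, snr=2.0))
        with pytest.raises(ValueError, match="broken"):
            rank_methods(reports)
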