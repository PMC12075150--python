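"""THI, THI load, focal-day selection, TSS, and hair phenotype derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boagwas.synthetic import EnvProfile, sim_temperature_logs
from boagwas.thermo import (
    NoEligibleDayError,
    ShortDeploymentError,
    ThermoError,
    compute_thi,
    compute_tss,
    derive_tss,
    filter_hair_outliers,
    hair_phenotype,
    hourly_average,
    pixels_to_mm,
    select_focal_day,
    thi_load,
    trim_deployment_days,
)


class TestThi:
    @pytest.mark.parametrize(
        "t,rh,expected",
        [
            (130.0 / 9.0, 0.0, 58.0),  # the (1.8T - 26) factor vanishes
            (130.0 / 9.0, 73.0, 58.0),
            (30.0, 100.0, 86.0),  # humidity correction vanishes: 1.8T + 32
            (35.0, 50.0, 84.825),
        ],
    )
    def test_closed_forms(self, t, rh, expected):
        assert compute_thi(t, rh) == pytest.approx(expected, abs=1e-9)

    def test_dry_bulb_line_at_full_humidity(self, rng):
        t = rng.uniform(-5, 45, size=50)
        np.testing.assert_allclose(compute_thi(t, 100.0), 1.8 * t + 32.0, atol=1e-9)

    def test_rh_out_of_range(self):
        with pytest.raises(ThermoError):
            compute_thi(25.0, 101.0)


def _series(days, per_day=96, animal="a1", start="2023-07-01"):
    t0 = pd.Timestamp(start)
    stamps = [t0 + pd.Timedelta(minutes=15 * k) for k in range(days * per_day)]
    return pd.DataFrame(
        {"animal_id": animal, "timestamp": stamps, "vaginal_temperature": 38.6}
    )


class TestTrimAndAverage:
    @pytest.mark.parametrize("days,remaining", [(5, 3), (3, 1)])
    def test_trim_keeps_interior_days(self, days, remaining):
        out = trim_deployment_days(_series(days))
        assert pd.to_datetime(out["timestamp"]).dt.date.nunique() == remaining

    def test_trim_two_days_rejected(self):
        with pytest.raises(ShortDeploymentError):
            trim_deployment_days(_series(2))

    def test_hourly_average_example(self):
        ts = pd.date_range("2023-07-01 10:00", periods=4, freq="15min")
        df = pd.DataFrame({"timestamp": ts, "v": [38.0, 38.2, 38.4, 38.6]})
        out = hourly_average(df, "v")
        assert len(out) == 1
        assert out["v"].iloc[0] == pytest.approx(38.3)

    def test_hourly_average_single_record(self):
        df = pd.DataFrame({"timestamp": [pd.Timestamp("2023-07-01 03:31")], "v": [39.1]})
        assert hourly_average(df, "v")["v"].iloc[0] == 39.1

    def test_hourly_average_against_bruteforce(self, rng):
        stamps = pd.Timestamp("2023-07-01") + pd.to_timedelta(
            np.sort(rng.choice(3 * 24 * 60, size=200, replace=False)), unit="min"
        )
        vals = rng.normal(38.5, 0.5, size=200)
        df = pd.DataFrame({"timestamp": stamps, "v": vals})
        out = hourly_average(df, "v").set_index("hour")["v"]
        # independent oracle: explicit loop over floor-hour bins
        bins: dict = {}
        for ts, v in zip(stamps, vals):
            key = ts.floor("h")
            bins.setdefault(key, []).append(v)
        for key, members in bins.items():
            assert out[key] == pytest.approx(np.mean(members), rel=1e-12)
        assert len(out) == len(bins)


class TestThiLoad:
    @pytest.mark.parametrize(
        "thi,expected",
        [([68, 70, 72, 75], 7.0), ([60, 65, 70], 0.0), ([71.5, 73.25], 4.75)],
    )
    def test_clamped_sum(self, thi, expected):
        assert thi_load(thi) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(40, 100), min_size=1, max_size=24),
        st.integers(0, 23),
        st.floats(0.01, 5),
    )
    def test_monotone_in_every_hour(self, thi, idx, bump):
        """Raising any hourly THI never lowers the load."""
        idx = idx % len(thi)
        bumped = list(thi)
        bumped[idx] += bump
        assert thi_load(bumped) >= thi_load(thi)


def _env(day_loads_rain, start="2023-07-01"):
    """Environment frame with one record per hour whose THI is baseline+load/24."""
    frames = []
    for d, (load, rain) in enumerate(day_loads_rain):
        ts = pd.date_range(pd.Timestamp(start) + pd.Timedelta(days=d), periods=24, freq="h")
        thi = np.full(24, 70.0 + load / 24.0)
        frames.append(pd.DataFrame({"timestamp": ts, "thi": thi, "rain": rain}))
    return pd.concat(frames, ignore_index=True)


class TestFocalDay:
    def test_rain_exclusion_then_max(self):
        env = _env([(30, False), (45, True), (40, False)])
        assert select_focal_day(env) == pd.Timestamp("2023-07-03").date()

    def test_tie_breaks_to_earliest(self):
        env = _env([(30, False), (30, False)])
        assert select_focal_day(env) == pd.Timestamp("2023-07-01").date()

    def test_all_rain_rejected(self):
        env = _env([(30, True), (40, True)])
        with pytest.raises(NoEligibleDayError):
            select_focal_day(env)


class TestTss:
    def _day(self, vt):
        ts = pd.date_range("2023-07-02", periods=len(vt), freq="15min")
        return pd.DataFrame({"animal_id": "a1", "timestamp": ts, "vaginal_temperature": vt})

    def test_constant_vt_gives_zero(self):
        rec = compute_tss(self._day(np.full(96, 38.6)), [72, 74, 76, 78])
        assert rec.tss == 0.0

    def test_direct_substitution(self):
        vt = np.full(96, 38.0)
        vt[40] = 39.2  # range 1.2
        rec = compute_tss(self._day(vt), [75, 75, 75, 75, 75, 75, 75, 75, 75, 75, 75, 75])
        assert rec.thi_load == pytest.approx(60.0)
        assert rec.tss == pytest.approx(2.0)

    def test_hand_computed_case(self):
        vt = np.full(96, 38.2)
        vt[50] = 39.4
        rec = compute_tss(self._day(vt), [72, 74, 76, 78])
        assert rec.vt_max == pytest.approx(39.4)
        assert rec.vt_min == pytest.approx(38.2)
        assert rec.thi_load == pytest.approx(20.0)
        assert rec.tss == pytest.approx(6.0)

    def test_zero_load_is_missing_not_zero(self):
        rec = compute_tss(self._day(np.linspace(38, 39, 96)), [65, 66, 67])
        assert np.isnan(rec.tss)

    def test_too_few_records_rejected(self):
        with pytest.raises(ThermoError):
            compute_tss(self._day(np.full(10, 38.6)), [75, 76])

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(-2, 2), st.floats(1.1, 4))
    def test_offset_invariance_and_linear_scaling(self, offset, scale):
        """TSS ignores a constant VT shift and scales with the diurnal range."""
        base = np.full(96, 38.0)
        base[10] = 39.0
        thi = [75.0] * 10
        r0 = compute_tss(self._day(base), thi)
        r_shift = compute_tss(self._day(base + offset), thi)
        assert r_shift.tss == pytest.approx(r0.tss, rel=1e-9)
        widened = np.full(96, 38.0)
        widened[10] = 38.0 + scale * 1.0
        r_scale = compute_tss(self._day(widened), thi)
        assert r_scale.tss == pytest.approx(scale * r0.tss, rel=1e-9)


class TestEndToEnd:
    def test_noise_free_tss_matches_analytic(self):
        """With a noise-free sinusoidal logger of amplitude A, the derived TSS
        equals 2A / (focal-day THI load) * 100."""
        amps = np.array([0.4, 0.6, 0.8])
        temp, env = sim_temperature_logs(amps, n_days=5, noise_sd=0.0, seed=1)
        out = derive_tss(temp, env).sort_values("animal_id").reset_index(drop=True)
        hourly = hourly_average(env[["timestamp", "thi"]], "thi")
        hourly["day"] = hourly["hour"].dt.date
        focal = out["focal_date"].iloc[0]
        load = thi_load(hourly[hourly["day"] == focal]["thi"])
        np.testing.assert_allclose(out["tss"], 2 * amps / load * 100.0, rtol=1e-9)

    def test_rainy_max_load_day_is_skipped(self):
        amps = np.array([0.5])
        temp, env = sim_temperature_logs(amps, n_days=5, noise_sd=0.0, seed=1,
                                         env=EnvProfile(rain_days=(1, 2)))
        out = derive_tss(temp, env)
        assert out["focal_date"].iloc[0] == pd.Timestamp("2023-07-13").date()


class TestHair:
    def test_pixels_to_mm(self):
        assert pixels_to_mm(1000) == pytest.approx(2.145)
        assert pixels_to_mm(0) == 0.0
        assert pixels_to_mm(2000) == pytest.approx(4.29)
        with pytest.raises(ThermoError):
            pixels_to_mm(-1)

    def test_all_equal_none_removed(self):
        assert filter_hair_outliers(np.full(10, 7.0)).all()

    def test_constructed_outlier_removed(self):
        """99 hairs of 10 mm and one of 100 mm: cohort mean 10.9, SD ~8.955,
        so only the 100 mm hair exceeds the 3-SD fence."""
        x = np.array([10.0] * 99 + [100.0])
        keep = filter_hair_outliers(x)
        assert keep.sum() == 99
        assert not keep[-1]

    def test_symmetric_tails(self):
        x = np.concatenate([np.full(50, 10.0), [100.0, -80.0]])
        keep = filter_hair_outliers(x)
        assert not keep[-1] and not keep[-2]
        assert keep[:-2].all()

    def test_hair_phenotype_means_and_missing(self):
        rows = []
        for aid, vals in [("a1", [5, 5, 5, 5, 5]), ("a2", [4, 6]), ("a3", [400.0])]:
            rows += [{"animal_id": aid, "hair_class": "short", "length_mm": v} for v in vals]
        # pad the cohort so a3's 400 mm is a clear 3-SD outlier
        rows += [{"animal_id": f"p{i}", "hair_class": "short", "length_mm": 5.0} for i in range(60)]
        out = hair_phenotype(pd.DataFrame(rows)).set_index("animal_id")["value"]
        assert out["a1"] == pytest.approx(5.0)
        assert out["a2"] == pytest.approx(5.0)
        assert np.isnan(out["a3"])
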