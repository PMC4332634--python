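"""Fire-weather index arithmetic.

The Canadian FWI-system code is checked three ways: against the classic
published start-up worked example (start codes 85/6/15, April, T=17 °C,
H=42%, wind 25 km/h, no rain), against an independent scalar transcription
of the published recursions kept in this file, and via structural
properties (drying monotonicity, fixed points, state sufficiency).
"""

import math

import numpy as np
import pandas as pd
import pytest

from fireniche.fire_indices import (
    DEFAULT_START_CODES,
    FWICodes,
    IndexState,
    angstroem_index,
    compute_indices,
    fwi_outputs,
    sharples_fmi,
    step_fwi,
)
from fireniche.weather_io import derive_variables

from conftest import make_series

# ---------------------------------------------------------------------------
# independent transcription of the FWI-system recursions (test oracle)

_EL = [6.5, 7.5, 9.0, 12.8, 13.9, 13.9, 12.4, 10.9, 9.4, 8.0, 7.0, 6.0]
_FL = [-1.6, -1.6, -1.6, 0.9, 3.8, 5.8, 6.4, 5.0, 2.4, 0.4, -1.6, -1.6]


def oracle_fwi_day(ffmc0, dmc0, dc0, t, h, w_kmh, r, month):
    """One FWI-system day, written independently of the package code."""
    # FFMC --------------------------------------------------------------
    wmo = 147.2 * (101.0 - ffmc0) / (59.5 + ffmc0)
    if r > 0.5:
        ra = r - 0.5
        extra = 0.0015 * (wmo - 150.0) ** 2 * ra**0.5 if wmo > 150.0 else 0.0
        wmo = min(
            wmo + 42.5 * ra * math.e ** (-100.0 / (251.0 - wmo)) * (1.0 - math.e ** (-6.93 / ra)) + extra,
            250.0,
        )
    ed = 0.942 * h**0.679 + 11.0 * math.e ** ((h - 100.0) / 10.0) \
        + 0.18 * (21.1 - t) * (1.0 - math.e ** (-0.115 * h))
    ew = 0.618 * h**0.753 + 10.0 * math.e ** ((h - 100.0) / 10.0) \
        + 0.18 * (21.1 - t) * (1.0 - math.e ** (-0.115 * h))
    if wmo > ed:
        z = 0.424 * (1.0 - (h / 100.0) ** 1.7) + 0.0694 * w_kmh**0.5 * (1.0 - (h / 100.0) ** 8)
        x = z * 0.581 * math.e ** (0.0365 * t)
        wm = ed + (wmo - ed) / 10.0**x
    elif wmo < ew:
        z = 0.424 * (1.0 - ((100.0 - h) / 100.0) ** 1.7) \
            + 0.0694 * w_kmh**0.5 * (1.0 - ((100.0 - h) / 100.0) ** 8)
        x = z * 0.581 * math.e ** (0.0365 * t)
        wm = ew - (ew - wmo) / 10.0**x
    else:
        wm = wmo
    ffmc = max(min(59.5 * (250.0 - wm) / (147.2 + wm), 101.0), 0.0)

    # DMC ---------------------------------------------------------------
    if r > 1.5:
        rw = 0.92 * r - 1.27
        wmi = 20.0 + 280.0 / math.e ** (0.023 * dmc0)
        if dmc0 <= 33.0:
            b = 100.0 / (0.5 + 0.3 * dmc0)
        elif dmc0 <= 65.0:
            b = 14.0 - 1.3 * math.log(dmc0)
        else:
            b = 6.2 * math.log(dmc0) - 17.2
        wmr = wmi + 1000.0 * rw / (48.77 + b * rw)
        pr = max(43.43 * (5.6348 - math.log(wmr - 20.0)), 0.0)
    else:
        pr = dmc0
    rk = 1.894 * (max(t, -1.1) + 1.1) * (100.0 - h) * _EL[month - 1] * 1e-6
    dmc = pr + 100.0 * rk

    # DC ----------------------------------------------------------------
    if r > 2.8:
        rw = 0.83 * r - 1.27
        smi = 800.0 * math.e ** (-dc0 / 400.0)
        dr = max(dc0 - 400.0 * math.log(1.0 + 3.937 * rw / smi), 0.0)
    else:
        dr = dc0
    pe = max(0.36 * (max(t, -2.8) + 2.8) + _FL[month - 1], 0.0) / 2.0
    dc = dr + pe

    # ISI / BUI / FWI ----------------------------------------------------
    fm = 147.2 * (101.0 - ffmc) / (59.5 + ffmc)
    sf = 19.115 * math.e ** (-0.1386 * fm) * (1.0 + fm**5.31 / 4.93e7)
    isi = sf * math.e ** (0.05039 * w_kmh)
    if dmc == 0 and dc == 0:
        bui = 0.0
    elif dmc <= 0.4 * dc:
        bui = 0.8 * dc * dmc / (dmc + 0.4 * dc)
    else:
        bui = dmc - (1.0 - 0.8 * dc / (dmc + 0.4 * dc)) * (0.92 + (0.0114 * dmc) ** 1.7)
    bui = max(bui, 0.0)
    if bui > 80.0:
        bb = 0.1 * isi * (1000.0 / (25.0 + 108.64 / math.e ** (0.023 * bui)))
    else:
        bb = 0.1 * isi * (0.626 * bui**0.809 + 2.0)
    fwi = math.e ** (2.72 * (0.434 * math.log(bb)) ** 0.647) if bb > 1.0 else bb
    return ffmc, dmc, dc, isi, bui, fwi


# ---------------------------------------------------------------------------


class TestFWISystem:
    def test_published_startup_example(self):
        """Start codes (85, 6, 15), April, T=17 °C, H=42%, wind 25 km/h,
        no rain: the classic worked example of the system's recursions."""
        codes = step_fwi(FWICodes(*DEFAULT_START_CODES), t=17.0, h=42.0, p=0.0,
                         u_ms=25.0 / 3.6, month=4)
        isi, bui, fwi = fwi_outputs(codes, 25.0)
        assert codes.ffmc == pytest.approx(87.7, abs=0.1)
        assert codes.dmc == pytest.approx(8.5, abs=0.1)
        assert codes.dc == pytest.approx(19.0, abs=0.1)
        assert isi == pytest.approx(10.9, abs=0.1)
        assert bui == pytest.approx(8.5, abs=0.1)
        assert fwi == pytest.approx(10.1, abs=0.1)

    def test_ffmc_fixed_point_at_equilibrium(self):
        """When the fuel moisture already sits between the wetting and
        drying equilibria, a rain-free day leaves the FFMC unchanged."""
        # T=20, H=100: Ed ~ 32.6, Ew ~ 30.0; FFMC 73.1 puts m ~ 31 between
        f0 = 59.5 * (250.0 - 31.0) / (147.2 + 31.0)
        codes = step_fwi(FWICodes(f0, 6.0, 15.0), t=20.0, h=100.0, p=0.0, u_ms=2.0, month=7)
        # the published code<->moisture conversion pair is not an exact
        # inverse (147.2*101 vs 59.5*250), which bounds the residual drift
        assert codes.ffmc == pytest.approx(f0, abs=0.05)

    def test_dry_spell_monotone_drying(self):
        """60 rain-free summer days: DMC and DC strictly increase."""
        codes = FWICodes(*DEFAULT_START_CODES)
        dmc_prev, dc_prev = codes.dmc, codes.dc
        for _ in range(60):
            codes = step_fwi(codes, t=25.0, h=40.0, p=0.0, u_ms=3.0, month=7)
            assert codes.dmc > dmc_prev
            assert codes.dc > dc_prev
            dmc_prev, dc_prev = codes.dmc, codes.dc

    def test_no_spread_without_wind_or_dry_fuel(self):
        isi, _, fwi = fwi_outputs(FWICodes(0.0, 6.0, 15.0), wind_kmh=0.0)
        assert isi == pytest.approx(0.0, abs=1e-3)
        assert fwi == pytest.approx(0.0, abs=1e-3)

    def test_fwi_monotone_in_isi_and_bui(self):
        """FWI is non-decreasing in each component over a grid."""
        ffmcs = np.linspace(50, 96, 8)
        dmcs = np.linspace(0, 120, 8)
        for dmc in dmcs:
            vals = [fwi_outputs(FWICodes(f, dmc, 2.5 * dmc + 10), 15.0)[2] for f in ffmcs]
            assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))
        for ffmc in ffmcs:
            vals = [fwi_outputs(FWICodes(ffmc, d, 2.5 * d + 10), 15.0)[2] for d in dmcs]
            assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_two_year_series_matches_oracle(self, two_year_series):
        """Daily agreement with the independent transcription within 0.1
        on every FWI-system output over a 2-year synthetic series."""
        idx = compute_indices(two_year_series)
        df = two_year_series.frame
        f0, d0, c0 = DEFAULT_START_CODES
        for i, (ts, row) in enumerate(df.iterrows()):
            f0, d0, c0, isi, bui, fwi = oracle_fwi_day(
                f0, d0, c0, row["t"], row["h"], row["u"] * 3.6, row["p"], ts.month
            )
            got = idx.iloc[i]
            assert got["ffmc"] == pytest.approx(f0, abs=0.1), ts
            assert got["dmc"] == pytest.approx(d0, abs=0.1), ts
            assert got["dc"] == pytest.approx(c0, abs=0.1), ts
            assert got["isi"] == pytest.approx(isi, abs=0.1), ts
            assert got["bui"] == pytest.approx(bui, abs=0.1), ts
            assert got["fwi"] == pytest.approx(fwi, abs=0.1), ts


class TestSimpleIndices:
    def test_angstroem_reference_point(self):
        assert angstroem_index(27.0, 20.0) == pytest.approx(1.0)

    def test_fmi_reference_point(self):
        assert sharples_fmi(30.0, 20.0) == pytest.approx(7.5)

    def test_nesterov_resets_on_heavy_rain(self, small_frame):
        small_frame.loc[small_frame.index[4], "p"] = 12.5  # > 3 mm reset
        idx = compute_indices(make_series(small_frame, site=_site()))
        assert idx["nesterov"].iloc[4] == 0.0
        assert idx["nesterov"].iloc[5] > 0.0

    def test_drought_indices_non_decreasing_when_dry(self, two_year_series):
        """DC, KBDI, Nesterov and Munger never fall on rain-free days."""
        idx = compute_indices(two_year_series)
        p = two_year_series.frame["p"].to_numpy()
        for col in ("dc", "kbdi", "nesterov", "munger"):
            v = idx[col].to_numpy()
            dry = p[1:] == 0.0
            deltas = v[1:] - v[:-1]
            assert (deltas[dry] >= -1e-9).all(), col

    def test_orieux_danger_classes(self, two_year_series):
        idx = compute_indices(two_year_series)
        assert set(np.unique(idx["orieux_danger"])) <= {1.0, 2.0, 3.0, 4.0}
        # the class is a deterministic function of reserve and wind
        r = idx["orieux_reserve"].to_numpy()
        cls = idx["orieux_danger"].to_numpy()
        assert ((r > 100) <= (cls == 1)).all()

    def test_baumgartner_window_is_previous_five_days(self, small_frame):
        idx = compute_indices(make_series(small_frame, site=_site()))
        # first value appears once 5 days of PET history exist
        assert np.isnan(idx["baumgartner"].iloc[:5]).all()
        assert np.isfinite(idx["baumgartner"].iloc[5:]).all()

    def test_site_parameters_required(self, small_frame):
        with pytest.raises(ValueError, match="site parameters"):
            compute_indices(make_series(small_frame, site=None))


class TestStateSufficiency:
    def test_replay_from_checkpoint(self, two_year_series):
        """Restarting from any day's saved state reproduces the rest of
        the series exactly."""
        derived = derive_variables(two_year_series)
        full = compute_indices(two_year_series, derived=derived)
        split = 400
        head_series = make_series(two_year_series.frame.iloc[:split], two_year_series.site)
        head = compute_indices(head_series, derived=derived.iloc[:split])
        state: IndexState = head.attrs["final_state"]
        tail_series = make_series(two_year_series.frame.iloc[split:], two_year_series.site)
        tail = compute_indices(tail_series, derived=derived.iloc[split:], start_state=state)
        cols = [c for c in full.columns if c not in ("burn_in", "baumgartner")]
        pd.testing.assert_frame_equal(full.iloc[split:][cols], tail[cols])


def _site():
    from fireniche.synthetic import default_site

    return default_site()
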