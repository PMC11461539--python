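import math

import numpy as np
import pytest

from pivotwdi.errors import DegenerateTrapezoidError, ValidationError
from pivotwdi.met import MetRecord
from pivotwdi.trapezoid import (SurfaceParams, corners_from_record,
                                temperature_limits, trapezoid_corners, wdi,
                                wind_sensitivity)

from conftest import sample_met_states


def corner_oracle(rec, params, clearness=1.0, rnl=None):
    """Independent scalar re-evaluation of the four energy-balance corners."""
    es = 0.6108 * math.exp(17.27 * rec.ta_c / (rec.ta_c + 237.3))
    ea = es * rec.rh_pct / 100.0
    vpd = es - ea
    delta = 4098.0 * es / (rec.ta_c + 237.3) ** 2
    gamma = 0.000665 * 101.3
    rho = 101.3 / (1.01 * (rec.ta_c + 273.0) * 0.287)
    cp = 1013.0
    hc = params.hc
    ra1 = (math.log((2 - 0.67 * hc) / (0.123 * hc))
           * math.log((2 - 0.67 * hc) / (0.0123 * hc)) / (0.41 ** 2 * rec.wind_ms))
    ra2 = math.log(2 / 0.01) * math.log(2 / 0.001) / (0.41 ** 2 * rec.wind_ms)
    if rnl is None:
        f = min(1.0, max(0.3, clearness))
        rnl = (5.67e-8 * (rec.ta_c + 273.16) ** 4
               * (0.34 - 0.14 * math.sqrt(ea)) * (1.35 * f - 0.35))
    rn = [(1 - a) * rec.rs_wm2 - rnl for a in params.albedo]
    g = [c * r for c, r in zip(params.c_g, rn)]
    x1 = gamma * (1 + params.rcp / ra1)
    x2 = gamma * (1 + params.rcx / ra1)
    wv = ra1 * (rn[0] - g[0]) / (rho * cp) * x1 / (delta + x1) - vpd / (delta + x1)
    dv = ra1 * (rn[1] - g[1]) / (rho * cp) * x2 / (delta + x2) - vpd / (delta + x2)
    ws = (ra2 * (rn[2] - g[2]) / (rho * cp) * gamma / (delta + gamma)
          - vpd / (delta + gamma))
    ds = ra2 * (rn[3] - g[3]) / (rho * cp)
    return wv, dv, ws, ds


class TestCorners:
    def test_no_energy_no_deficit_gives_zero_corners(self, surface_params):
        """With saturated air and zero available energy every corner is 0 degC."""
        c, _ = corners_from_record(MetRecord(25.0, 100.0, 0.0, 2.0),
                                   surface_params, rnl=0.0)
        for v in (c.wet_vegetation, c.dry_vegetation, c.wet_soil, c.dry_soil):
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_radiative_only_corners_positive_and_ordered(self, surface_params):
        """Saturated air but positive Rn-G: all corners heat above air temperature."""
        c, m = corners_from_record(MetRecord(30.0, 100.0, 600.0, 2.0),
                                   surface_params, rnl=0.0)
        assert min(c.wet_vegetation, c.dry_vegetation, c.wet_soil, c.dry_soil) > 0
        rn, g = m.rn_by_surface, m.g_by_surface
        if m.ra2 * (rn[3] - g[3]) >= m.ra1 * (rn[1] - g[1]):
            assert c.dry_soil == max(c.wet_vegetation, c.dry_vegetation,
                                     c.wet_soil, c.dry_soil)

    def test_matches_independent_oracle(self, midday_record, surface_params):
        c, _ = corners_from_record(midday_record, surface_params, rnl=0.0)
        wv, dv, ws, ds = corner_oracle(midday_record, surface_params, rnl=0.0)
        assert c.wet_vegetation == pytest.approx(wv, abs=1e-9)
        assert c.dry_vegetation == pytest.approx(dv, abs=1e-9)
        assert c.wet_soil == pytest.approx(ws, abs=1e-9)
        assert c.dry_soil == pytest.approx(ds, abs=1e-9)

    def test_equal_canopy_resistances_collapse_vegetation_corners(self):
        """With rcp = rcx (and matching albedo/cG) wet and dry vegetation agree."""
        params = SurfaceParams(rcp=80.0, rcx=80.0)
        c, _ = corners_from_record(MetRecord(32.0, 30.0, 650.0, 3.0), params, rnl=0.0)
        assert c.wet_vegetation == pytest.approx(c.dry_vegetation, abs=1e-12)

    def test_printed_dry_vegetation_form_differs(self, midday_record):
        default = SurfaceParams()
        printed = SurfaceParams(printed_dry_vegetation=True)
        c0, _ = corners_from_record(midday_record, default, rnl=0.0)
        c1, _ = corners_from_record(midday_record, printed, rnl=0.0)
        assert c0.dry_vegetation != pytest.approx(c1.dry_vegetation, abs=1e-6)
        assert c0.wet_vegetation == pytest.approx(c1.wet_vegetation, abs=1e-12)

    def test_requires_surface_terms(self, midday_record, surface_params):
        from pivotwdi.met import derive_met_state
        with pytest.raises(ValidationError):
            trapezoid_corners(derive_met_state(midday_record), surface_params)


class TestLimits:
    @pytest.fixture
    def corners(self, midday_record, surface_params):
        c, _ = corners_from_record(midday_record, surface_params, rnl=0.0)
        return c

    def test_full_cover_endpoint(self, corners):
        assert temperature_limits(corners, 1.0) == \
            (corners.wet_vegetation, corners.dry_vegetation)

    def test_bare_soil_endpoint(self, corners):
        assert temperature_limits(corners, 0.0) == (corners.wet_soil, corners.dry_soil)

    def test_half_cover_is_arithmetic_mean(self, corners):
        lo, up = temperature_limits(corners, 0.5)
        assert lo == pytest.approx((corners.wet_vegetation + corners.wet_soil) / 2)
        assert up == pytest.approx((corners.dry_vegetation + corners.dry_soil) / 2)

    def test_fc_out_of_range(self, corners):
        with pytest.raises(ValidationError):
            temperature_limits(corners, 1.2)


class TestWdi:
    def test_boundary_exactness(self):
        assert wdi(-2.0, -2.0, 8.0).wdi == pytest.approx(0.0, abs=1e-12)
        assert wdi(8.0, -2.0, 8.0).wdi == pytest.approx(1.0, abs=1e-12)
        assert wdi(3.0, -2.0, 8.0).wdi == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_measured_temperature(self):
        vals = [wdi(x, -2.0, 8.0).wdi for x in np.linspace(-2, 8, 21)]
        assert np.all(np.diff(vals) > 0)

    def test_out_of_trapezoid_clamped_and_flagged(self):
        low = wdi(-5.0, -2.0, 8.0)
        high = wdi(9.0, -2.0, 8.0)
        assert (low.wdi, low.clamped) == (0.0, True)
        assert (high.wdi, high.clamped) == (1.0, True)
        assert not wdi(3.0, -2.0, 8.0).clamped

    def test_unclamped_raw_value(self):
        assert wdi(9.0, -2.0, 8.0, clamp=False).wdi == pytest.approx(1.1)

    def test_degenerate_trapezoid_names_timestep(self):
        with pytest.raises(DegenerateTrapezoidError, match="plot 3"):
            wdi(1.0, 2.0, 2.0, label="plot 3 at 12:30")


class TestWindSensitivity:
    def test_unit_factor_is_exact_zero(self, midday_record, surface_params):
        tab = wind_sensitivity(midday_record, surface_params, dt_measured=2.0,
                               fc=0.7, factors=[1.0], rnl=0.0)
        assert tab["pct_change"].iloc[0] == 0.0

    def test_stronger_wind_raises_wdi_monotonically(self, midday_record, surface_params):
        """A stressed mid-season state: faster wind lowers r_a, narrows the
        trapezoid, and pushes the same measured dT to a higher WDI."""
        tab = wind_sensitivity(midday_record, surface_params, dt_measured=3.0,
                               fc=0.7, factors=[1.0, 1.1, 1.5, 2.0], rnl=0.0)
        base = wdi(3.0, *temperature_limits(
            corners_from_record(midday_record, surface_params, rnl=0.0)[0], 0.7)).wdi
        assert 0.3 < base < 0.7  # genuinely mid-trapezoid baseline
        assert tab["pct_change"].iloc[0] == 0.0
        assert np.all(np.diff(tab["pct_change"].to_numpy()) > 0)
        assert np.all(tab["pct_change"].to_numpy()[1:] > 0)

    def test_nonpositive_factor_rejected(self, midday_record, surface_params):
        with pytest.raises(ValidationError):
            wind_sensitivity(midday_record, surface_params, 2.0, 0.7, [0.0])


def test_ordering_property_over_sampled_states(surface_params):
    """wet <= dry for both surfaces, hence lower <= upper for every Fc,
    across 1,000 sampled midday states."""
    for rec, clearness in sample_met_states(1000, seed=42):
        c, _ = corners_from_record(rec, surface_params, clearness=clearness)
        assert c.wet_vegetation <= c.dry_vegetation
        assert c.wet_soil <= c.dry_soil
        for fc in (0.0, 0.25, 0.5, 0.75, 1.0):
            lo, up = temperature_limits(c, fc)
            assert lo <= up
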