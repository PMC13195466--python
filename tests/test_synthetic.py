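"""Generator behaviour: determinism, degradation rules, forward-model physics."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from pfsmoke.errors import ConfigurationError, InputError
from pfsmoke.fields import SPECIES, TOTAL, make_dates
from pfsmoke.grid import GridDefinition
from pfsmoke.records import make_events
from pfsmoke.seasons import DEFAULT_SEASONS
from pfsmoke.synthetic import (
    DEFAULT_MODEL_BIASES,
    DEFAULT_SEASONAL_WEIGHTS,
    KernelParams,
    bias_model_fields,
    degrade_to_satellite,
    generate_burn_truth,
    generate_observations,
    generate_sites,
    sample_permits,
    simulate_concentration_fields,
)


@pytest.fixture
def grid():
    return GridDefinition(10, 10, 12.0)


class TestBurnTruth:
    def test_zero_rate_yields_no_events(self, grid):
        events = generate_burn_truth(grid, n_days=30, mean_daily_events=0.0, seed=1)
        assert len(events) == 0

    def test_same_seed_is_bit_reproducible(self, grid):
        a = generate_burn_truth(grid, n_days=200, seed=7)
        b = generate_burn_truth(grid, n_days=200, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_seasonal_area_shares_converge_to_weights(self, grid):
        """Over a 3-year period the per-season burned-area shares land
        within 2 percentage points of the configured weights."""
        events = generate_burn_truth(grid, n_days=1095, start="2013-01-01", seed=0)
        labels = DEFAULT_SEASONS.of_dates(events["date"])
        total = events["area_acres"].sum()
        for season, weight in DEFAULT_SEASONAL_WEIGHTS.items():
            share = events.loc[labels == season, "area_acres"].sum() / total
            assert share == pytest.approx(weight, abs=0.02)

    def test_events_stay_on_grid_and_in_period(self, grid):
        events = generate_burn_truth(grid, n_days=60, seed=3)
        assert grid.contains(events["row"].to_numpy(), events["col"].to_numpy()).all()
        dates = make_dates("2020-09-15", 60)
        assert events["date"].isin(dates).all()
        assert (events["area_acres"] > 0).all()

    def test_malformed_weights_rejected(self, grid):
        with pytest.raises(ConfigurationError):
            generate_burn_truth(grid, n_days=10, seasonal_weights={"JFMA": 0.8}, seed=0)
        with pytest.raises(ConfigurationError):
            generate_burn_truth(grid, n_days=10, mean_daily_events=-1, seed=0)


class TestSatelliteDegradation:
    def test_small_fires_below_detection_limit_dropped(self, grid):
        truth = make_events(["2021-01-01", "2021-01-01"], [0, 0], [0, 1], [0.5, 5.0], "truth")
        sat = degrade_to_satellite(truth, min_detectable_area=1.18, miss_probability=0.0, seed=0)
        assert len(sat) == 1
        assert sat["col"].iloc[0] == 1

    def test_identity_configuration_returns_input_areas(self, grid):
        truth = generate_burn_truth(grid, n_days=30, seed=5)
        sat = degrade_to_satellite(
            truth, min_detectable_area=0.0, overreport_factor=1.0, miss_probability=0.0, seed=0
        )
        assert np.allclose(sat["area_acres"], truth["area_acres"])
        assert (sat["source"] == "satellite").all()

    def test_overreport_inflates_area(self):
        truth = make_events(["2021-01-01"], [0], [0], [6.6], "truth")
        sat = degrade_to_satellite(truth, min_detectable_area=0, overreport_factor=0.66,
                                   miss_probability=0.0, seed=0)
        assert sat["area_acres"].iloc[0] == pytest.approx(10.0)

    def test_satellite_is_subset_of_truth(self, grid):
        """Degradation never invents events: every satellite record maps to
        a truth record with the same cell/date and a 0.66x-scaled area."""
        truth = generate_burn_truth(grid, n_days=90, seed=11)
        sat = degrade_to_satellite(truth, seed=12)
        truth_keys = set(zip(truth["date"], truth["row"], truth["col"],
                             truth["area_acres"].round(9)))
        for _, e in sat.iterrows():
            key = (e["date"], e["row"], e["col"], round(e["area_acres"] * 0.66, 9))
            assert key in truth_keys


class TestPermits:
    def test_full_coverage_returns_everything(self, grid):
        truth = generate_burn_truth(grid, n_days=30, seed=5)
        permits = sample_permits(truth, coverage_probability=1.0, seed=0)
        assert len(permits) == len(truth)
        assert np.allclose(permits["area_acres"], truth["area_acres"])

    def test_half_coverage_within_binomial_bounds(self, grid):
        truth = generate_burn_truth(grid, n_days=1000, seed=1).head(10000)
        permits = sample_permits(truth, coverage_probability=0.5, seed=2)
        sd = np.sqrt(10000 * 0.25)
        assert abs(len(permits) - 5000) < 3 * sd

    def test_empty_input_gives_empty_output(self, grid):
        truth = generate_burn_truth(grid, n_days=5, mean_daily_events=0, seed=0)
        assert len(sample_permits(truth, 0.5, seed=0)) == 0


class TestForwardModel:
    def _unit_emissions(self, grid, n_days=3, row=5, col=5, tons=1.0):
        dates = make_dates("2021-01-01", n_days)
        data = {}
        for sp in SPECIES:
            arr = np.zeros((n_days, grid.n_rows, grid.n_cols))
            if sp == "OC":
                arr[:, row, col] = tons
            data[sp] = xr.DataArray(arr, dims=("time", "row", "col"), coords={"time": dates})
        return xr.Dataset(data)

    def test_zero_emissions_gives_background_everywhere(self, grid):
        emis = self._unit_emissions(grid, tons=0.0)
        pair = simulate_concentration_fields(grid, emis, background={sp: 1.0 for sp in SPECIES})
        for ds in (pair.all_emissions, pair.no_pf):
            for sp in SPECIES:
                assert np.allclose(ds[sp].values, 1.0)
            assert np.allclose(ds[TOTAL].values, float(len(SPECIES)))

    def test_emitted_mass_is_conserved_on_domain(self, grid):
        """Summing concentration x cell volume over the grid recovers the
        emitted mass exactly: the kernel is normalized over the domain."""
        kernel = KernelParams(scale_km=15.0, wind_sd_km=5.0, mixing_height_m=1000.0)
        emis = self._unit_emissions(grid, tons=2.5)
        pair = simulate_concentration_fields(grid, emis, background={sp: 0.0 for sp in SPECIES},
                                             kernel=kernel, seed=3)
        conc = pair.all_emissions["OC"].values  # ug/m3, (t, r, c)
        cell_volume_m3 = grid.cell_area_km2 * 1e6 * kernel.mixing_height_m
        mass_tons = conc.sum(axis=(1, 2)) * cell_volume_m3 / 1e12
        assert np.allclose(mass_tons, 2.5, rtol=1e-9)

    def test_linear_in_emissions(self, grid):
        emis = self._unit_emissions(grid, tons=1.0)
        pair1 = simulate_concentration_fields(grid, emis, seed=9)
        pair2 = simulate_concentration_fields(grid, emis * 2.0, seed=9)
        d1 = pair1.all_emissions["OC"].values - pair1.no_pf["OC"].values
        d2 = pair2.all_emissions["OC"].values - pair2.no_pf["OC"].values
        assert np.allclose(d2, 2.0 * d1, rtol=1e-12)

    def test_delta_equals_pf_only_simulation(self, grid):
        """Linearity oracle: the member difference equals the field
        simulated from the prescribed-fire inventory alone."""
        emis = self._unit_emissions(grid, tons=3.0)
        bg = {sp: 0.7 for sp in SPECIES}
        pair = simulate_concentration_fields(grid, emis, background=bg, seed=21)
        alone = simulate_concentration_fields(grid, emis,
                                              background={sp: 0.0 for sp in SPECIES}, seed=21)
        delta = pair.all_emissions["OC"].values - pair.no_pf["OC"].values
        assert np.allclose(delta, alone.all_emissions["OC"].values, atol=1e-12)

    def test_bad_kernel_scale_rejected(self):
        with pytest.raises(ConfigurationError):
            KernelParams(scale_km=0.0)


class TestModelFields:
    def test_mean_bias_matches_configuration(self, study):
        """Network-wide NMB of model vs truth tracks the configured species
        biases (total PM2.5 ~ -20%)."""
        for sp, bias in DEFAULT_MODEL_BIASES.items():
            m = study.model_pair.all_emissions[sp].values
            t = study.truth_pair.all_emissions[sp].values
            nmb = m.sum() / t.sum() - 1.0
            assert nmb == pytest.approx(bias - 1.0, abs=0.03)

    def test_model_error_is_shared_between_members(self, study):
        """Both scenario members are degraded by the same multiplicative
        error, as paired runs share meteorology; their ratio to truth is
        identical wherever truth is positive."""
        m, t = study.model_pair, study.truth_pair
        r_all = m.all_emissions["EC"].values / t.all_emissions["EC"].values
        r_no = m.no_pf["EC"].values / t.no_pf["EC"].values
        assert np.allclose(r_all, r_no, rtol=1e-9)


class TestObservations:
    def test_noise_free_observations_equal_truth_on_schedule(self, study):
        obs = generate_observations(study.truth_pair.all_emissions, study.sites,
                                    noise_sd=0.0, seed=0)
        site = study.sites.iloc[0]
        sub = obs[(obs["site"] == site["id"]) & (obs["species"] == TOTAL)]
        truth = study.truth_pair.all_emissions[TOTAL].values[:, site["row"], site["col"]]
        assert np.allclose(sub["value"].to_numpy(), truth)

    def test_one_in_three_schedule_arithmetic(self, grid):
        dates = make_dates("2021-01-01", 9)
        bg = {sp: 1.0 for sp in SPECIES}
        emis = xr.Dataset({sp: xr.DataArray(np.zeros((9, 10, 10)), dims=("time", "row", "col"),
                                            coords={"time": dates}) for sp in SPECIES})
        pair = simulate_concentration_fields(grid, emis, background=bg)
        sites = generate_sites(grid, n_total_pm=0, n_speciation=1, seed=4)
        obs = generate_observations(pair.all_emissions, sites, noise_sd=0.0, seed=0)
        per_species = obs.groupby("species")["date"].nunique()
        assert (per_species == 3).all()

    def test_network_nmb_reflects_total_bias(self, study):
        """Model vs observations network-wide NMB ~ -20% for total PM2.5."""
        obs = study.observations
        tot = obs[obs["species"] == TOTAL].merge(
            study.sites[["id", "row", "col"]], left_on="site", right_on="id"
        )
        dates = pd.DatetimeIndex(study.truth_pair.dates)
        pos = pd.Series(np.arange(len(dates)), index=dates)
        sim = study.model_pair.all_emissions[TOTAL].values[
            pos.loc[tot["date"]].to_numpy(), tot["row"], tot["col"]
        ]
        nmb = 100.0 * (sim - tot["value"]).sum() / tot["value"].sum()
        assert nmb == pytest.approx(-20.0, abs=4.0)

    def test_off_grid_site_rejected(self, study):
        bad = study.sites.copy()
        bad.loc[bad.index[0], "row"] = 999
        with pytest.raises(InputError):
            generate_observations(study.truth_pair.all_emissions, bad, seed=0)
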