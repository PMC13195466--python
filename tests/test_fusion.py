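"""Data fusion: bias removal, mass balance, impact scaling, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfsmoke.errors import DegenerateInputError, InputError
from pfsmoke.fields import SPECIES, TOTAL, make_field
from pfsmoke.fusion import (
    FusionConfig,
    exclude_near_road,
    fuse_pf_species,
    fuse_pf_total,
    fuse_species_ratios,
    fuse_total,
    run_fusion,
)
from pfsmoke.evaluation import count_impact_exceeding_observation
from pfsmoke.synthetic import generate_observations, generate_sites


class TestExcludeNearRoad:
    def test_no_flags_is_identity(self, study):
        sites = study.sites.assign(near_road=False)
        out = exclude_near_road(study.observations, sites)
        assert len(out) == len(study.observations)

    def test_all_flagged_empties_the_table(self, study):
        sites = study.sites.assign(near_road=True)
        assert len(exclude_near_road(study.observations, sites)) == 0

    def test_mixed_flags_keep_only_clean_sites(self, study):
        out = exclude_near_road(study.observations, study.sites)
        clean = set(study.sites.loc[~study.sites["near_road"], "id"])
        expected = study.observations["site"].isin(clean).sum()
        assert len(out) == expected
        assert set(out["site"]) <= clean

    def test_unknown_site_rejected(self, study):
        obs = study.observations.copy()
        obs.loc[obs.index[0], "site"] = "NOPE"
        with pytest.raises(InputError):
            exclude_near_road(obs, study.sites)


class TestFuseTotal:
    def test_observations_equal_sim_is_a_fixed_point(self, study):
        """When observations exactly equal the simulation at every site,
        the fusion has nothing to correct and returns the sim field."""
        sim = study.model_pair.all_emissions[TOTAL]
        sites = generate_sites(study.grid, n_total_pm=40, n_speciation=0,
                               near_road_fraction=0.0, seed=2)
        obs = generate_observations(study.model_pair.all_emissions, sites,
                                    noise_sd=0.0, seed=0)
        fused = fuse_total(sim, obs, sites, study.grid)
        assert np.allclose(fused.values, np.maximum(sim.values, 0.01), rtol=1e-3)

    def test_removes_uniform_model_bias(self, study):
        """sim = 0.8 x truth with noise-free dense observations: the fused
        field recovers truth at monitored cells almost exactly."""
        truth = study.truth_pair.all_emissions
        sim = make_field(truth[TOTAL].values * 0.8, study.dates, TOTAL, "all")
        sites = generate_sites(study.grid, n_total_pm=80, n_speciation=0,
                               near_road_fraction=0.0, seed=3)
        obs = generate_observations(truth, sites, noise_sd=0.0, seed=4)
        fused = fuse_total(sim, obs, sites, study.grid)
        at = fused.values[:, sites["row"], sites["col"]]
        tr = truth[TOTAL].values[:, sites["row"], sites["col"]]
        assert np.abs(at / tr - 1).max() < 1e-3

    def test_bias_removal_under_observation_noise(self, study):
        """With 2% observation noise the monitored-cell error of the fused
        field stays within the noise floor (median < 2%, p95 < 5%)."""
        truth = study.truth_pair.all_emissions
        sim = make_field(truth[TOTAL].values * 0.8, study.dates, TOTAL, "all")
        sites = generate_sites(study.grid, n_total_pm=80, n_speciation=0,
                               near_road_fraction=0.0, seed=3)
        obs = generate_observations(truth, sites, noise_sd=0.02, seed=4)
        fused = fuse_total(sim, obs, sites, study.grid)
        rel = np.abs(fused.values[:, sites["row"], sites["col"]]
                     / truth[TOTAL].values[:, sites["row"], sites["col"]] - 1)
        assert np.median(rel) < 0.02
        assert np.percentile(rel, 95) < 0.05

    def test_fused_never_below_floor(self, fused):
        config = FusionConfig()
        assert fused["fused_total"].values.min() >= config.concentration_floor

    def test_no_observations_is_degenerate(self, study):
        sim = study.model_pair.all_emissions[TOTAL]
        empty = study.observations.iloc[0:0]
        with pytest.raises(DegenerateInputError):
            fuse_total(sim, empty, study.sites, study.grid)

    def test_full_grid_rmse_vs_truth_improves(self, study, fused):
        """Fusion moves the model toward the truth over the whole domain,
        not just at monitors."""
        truth = study.truth_pair.all_emissions[TOTAL].values
        sim = study.model_pair.all_emissions[TOTAL].values
        rmse_sim = np.sqrt(np.mean((sim - truth) ** 2))
        rmse_fused = np.sqrt(np.mean((fused["fused_total"].values - truth) ** 2))
        assert rmse_fused < rmse_sim


class TestFusePFTotal:
    def test_unit_ratio_is_identity(self, study):
        sim = study.model_pair.all_emissions[TOTAL]
        delta = make_field(sim.values * 0.1, study.dates, TOTAL, "delta_pf")
        fused_tot = make_field(sim.values, study.dates, TOTAL, "fused")
        out = fuse_pf_total(delta, sim, fused_tot)
        assert np.allclose(out.values, delta.values)

    def test_scaling_arithmetic(self, study):
        shape = (1, 1, 1)
        dates = study.dates[:1]
        delta = make_field(np.full(shape, 2.0), dates, TOTAL, "delta_pf")
        sim = make_field(np.full(shape, 10.0), dates, TOTAL, "all")
        fused_tot = make_field(np.full(shape, 12.0), dates, TOTAL, "fused")
        assert fuse_pf_total(delta, sim, fused_tot).values[0, 0, 0] == pytest.approx(2.4)

    def test_pf_fraction_is_preserved(self, study, fused):
        """Wherever the denominator floor and the cap are inactive the
        fused PF fraction equals the simulated PF fraction exactly."""
        config = FusionConfig()
        sim = study.model_pair.all_emissions[TOTAL].values
        d_sim = fused["delta_sim"][TOTAL].values
        f_tot = fused["fused_total"].values
        d_f = fused["fused_delta_total"].values
        active = (sim > config.denom_floor) & (f_tot / sim < config.ratio_cap) & (f_tot > 0)
        assert active.mean() > 0.99
        lhs = d_f[active] / f_tot[active]
        rhs = d_sim[active] / sim[active]
        assert np.allclose(lhs, rhs, rtol=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        sim=st.floats(0.011, 100.0),
        delta_frac=st.floats(0.0, 1.0),
        fused_val=st.floats(0.0, 100.0),
    )
    def test_bounded_by_fused_total_in_uncapped_regime(self, sim, delta_frac, fused_val):
        """If 0 <= delta_sim <= sim_total then 0 <= delta_DF <= fused_total
        whenever the ratio cap is inactive — direct consequence of the
        ratio form of the adjustment."""
        config = FusionConfig()
        if fused_val / sim > config.ratio_cap:
            fused_val = sim * config.ratio_cap
        delta = delta_frac * sim
        out = delta * min(fused_val / max(sim, config.denom_floor), config.ratio_cap)
        assert -1e-9 <= out <= fused_val + 1e-9

    def test_monotone_in_fused_total(self, study):
        dates = study.dates[:1]
        delta = make_field(np.full((1, 1, 1), 1.5), dates, TOTAL, "delta_pf")
        sim = make_field(np.full((1, 1, 1), 8.0), dates, TOTAL, "all")
        lo = fuse_pf_total(delta, sim, make_field(np.full((1, 1, 1), 6.0), dates, TOTAL, "fused"))
        hi = fuse_pf_total(delta, sim, make_field(np.full((1, 1, 1), 9.0), dates, TOTAL, "fused"))
        assert hi.values[0, 0, 0] > lo.values[0, 0, 0]


class TestFuseSpeciesRatios:
    def test_mass_balance_closure(self, fused):
        """Fused component concentrations sum to the fused total at every
        cell-day to 1e-9 relative."""
        total = fused["fused_total"].values
        summed = sum(fused["fused_species"][sp].values for sp in SPECIES)
        assert np.abs(summed - total).max() <= 1e-9 * total.max()
        ratios = sum(fused["ratio_fields"][sp].values for sp in SPECIES)
        assert np.abs(ratios - 1.0).max() <= 1e-9

    def test_unit_correction_when_obs_match_sim(self, study):
        """Observed ratios equal simulated ratios: fused species are just
        the simulated ratios times the fused total."""
        truth = study.truth_pair  # use truth as the 'model': unbiased ratios
        sites = study.sites
        obs = generate_observations(truth.all_emissions, sites, noise_sd=0.0, seed=1)
        fused_tot = fuse_total(truth.all_emissions[TOTAL], obs, sites, study.grid)
        ratios, conc = fuse_species_ratios(
            truth.all_emissions, obs, sites, fused_tot, study.grid
        )
        r_sim = truth.all_emissions["OC"].values / truth.all_emissions[TOTAL].values
        assert np.allclose(ratios["OC"].values, r_sim, atol=2e-3)
        assert np.allclose(conc["OC"].values, r_sim * fused_tot.values, atol=2e-2)

    def test_oc_ratio_bias_corrected_at_monitors(self, study, fused):
        """The model's +42% OC-ratio bias is largely removed at speciation
        monitors on their sampling days (median error < 10%, against a
        simulated median error several times larger)."""
        truth = study.truth_pair.all_emissions
        r_truth = truth["OC"].values / truth[TOTAL].values
        model = study.model_pair.all_emissions
        r_sim = model["OC"].values / np.maximum(model[TOTAL].values, 0.01)
        r_fused = fused["ratio_fields"]["OC"].values
        spec = study.sites[study.sites["kind"] == "speciation"]
        n_days = len(study.dates)
        errs_fused, errs_sim = [], []
        for _, site in spec.iterrows():
            days = np.nonzero((np.arange(n_days) % 3) == site["schedule_offset"] % 3)[0]
            rt = r_truth[days, site["row"], site["col"]]
            errs_fused.append(np.abs(r_fused[days, site["row"], site["col"]] / rt - 1))
            errs_sim.append(np.abs(r_sim[days, site["row"], site["col"]] / rt - 1))
        errs_fused = np.concatenate(errs_fused)
        errs_sim = np.concatenate(errs_sim)
        assert np.median(errs_fused) < 0.10
        assert np.median(errs_fused) < 0.5 * np.median(errs_sim)

    def test_no_speciation_observations_is_degenerate(self, study, fused):
        obs = study.observations
        only_total = obs[obs["species"] == TOTAL]
        with pytest.raises(DegenerateInputError):
            fuse_species_ratios(
                study.model_pair.all_emissions, only_total, study.sites,
                fused["fused_total"], study.grid,
            )


class TestFusePFSpecies:
    def test_identity_and_arithmetic(self, study):
        dates = study.dates[:1]
        delta = make_field(np.full((1, 1, 1), 0.05), dates, "EC", "delta_pf")
        sim = make_field(np.full((1, 1, 1), 0.2), dates, "EC", "all")
        fused_same = make_field(np.full((1, 1, 1), 0.2), dates, "EC", "fused")
        assert fuse_pf_species(delta, sim, fused_same).values[0, 0, 0] == pytest.approx(0.05)
        fused_up = make_field(np.full((1, 1, 1), 0.3), dates, "EC", "fused")
        assert fuse_pf_species(delta, sim, fused_up).values[0, 0, 0] == pytest.approx(0.075)

    def test_species_impact_closure_on_unbiased_fixture(self, study):
        """With an unbiased model and noise-free observations, component PF
        impacts sum to the total PF impact."""
        truth = study.truth_pair
        obs = generate_observations(truth.all_emissions, study.sites, noise_sd=0.0, seed=1)
        out = run_fusion(truth, obs, study.sites)
        summed = sum(out["fused_delta_species"][sp].values for sp in SPECIES)
        total = out["fused_delta_total"].values
        assert np.abs(summed - total).max() <= 0.02 * max(np.abs(total).max(), 1.0)


class TestPhysicalConsistencyDiagnostic:
    def test_fusion_reduces_impact_over_observation_cases(self, study, fused):
        """Across all species, fusion strictly shrinks the number of
        monitor-days where the estimated fire impact exceeds the observed
        concentration (a physical impossibility)."""
        obs = exclude_near_road(study.observations, study.sites)
        n_sim = n_fused = 0
        for sp in list(SPECIES) + [TOTAL]:
            d_fused = (fused["fused_delta_total"] if sp == TOTAL
                       else fused["fused_delta_species"][sp])
            n_sim += count_impact_exceeding_observation(
                fused["delta_sim"][sp], obs, study.sites, sp)
            n_fused += count_impact_exceeding_observation(d_fused, obs, study.sites, sp)
        assert n_sim > 0
        assert n_fused < n_sim
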