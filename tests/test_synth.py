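"""Synthetic generator: determinism, planted thermal events, latent structure."""

import numpy as np
import pandas as pd
import pytest

from reefkrige.geostat import VariogramModel, empirical_variogram
from reefkrige.synth import (
    EventSpec,
    SynthConfig,
    event_patch,
    generate_dataset,
    make_reef_grid,
    sample_reports,
    simulate_latent_field,
    simulate_sst,
)
from reefkrige.thermal import annual_max_matrix, dhw_matrix

from conftest import small_synth_config


class TestMakeReefGrid:
    def test_single_cell_grid(self):
        cfg = small_synth_config(n_reef_cells=1, clusters=[("indian", -5.0, 72.0, 1.0, 1.0)])
        grid = make_reef_grid(cfg)
        assert len(grid.cells) == 1
        assert (grid.cells["reef_area"] > 0).all()

    def test_same_seed_is_identical(self):
        a = make_reef_grid(small_synth_config())
        b = make_reef_grid(small_synth_config())
        pd.testing.assert_frame_equal(a.cells, b.cells)
        assert a.land_cells == b.land_cells

    def test_requested_cell_count_and_area_additivity(self):
        grid = make_reef_grid(small_synth_config())
        assert len(grid.cells) == 250
        assert grid.reef_area_of(grid.reef_cell_ids) == pytest.approx(
            grid.cells["reef_area"].sum()
        )

    def test_cells_carry_region_labels(self):
        grid = make_reef_grid(small_synth_config())
        assert grid.cells["region"].notna().all()
        assert set(grid.cells["region"]) <= {
            "caribbean", "indian", "east_pacific", "pacific_west", "pacific_central", "pacific_east",
        }


class TestSimulateSst:
    def test_no_events_means_no_thermal_stress_anywhere(self):
        cfg = small_synth_config(events={})
        grid = make_reef_grid(cfg)
        times, sst, mmm = simulate_sst(grid, cfg)
        am = annual_max_matrix(times, dhw_matrix(times, sst, mmm), [1997, 1998, 1999])
        assert (am.to_numpy() == 0.0).all()

    def test_event_dhw_closed_form(self):
        cfg = small_synth_config(events={1998: EventSpec(0.1, amplitude_c=2.0, duration_days=84.0)})
        grid = make_reef_grid(cfg)
        times, sst, mmm = simulate_sst(grid, cfg)
        am = annual_max_matrix(times, dhw_matrix(times, sst, mmm), [1998])
        patch = event_patch(grid, cfg, 1998)
        pos = np.isin(grid.reef_cell_ids, patch)
        # 2 degC for 84 days = 2 x 84/7 = 24 degC-weeks
        np.testing.assert_allclose(am.to_numpy()[pos, 0], 24.0, atol=1e-9)
        assert (am.to_numpy()[~pos, 0] == 0.0).all()

    def test_same_seed_is_identical(self):
        cfg = small_synth_config()
        grid = make_reef_grid(cfg)
        t1, s1, m1 = simulate_sst(grid, cfg)
        t2, s2, m2 = simulate_sst(grid, cfg)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(m1, m2)


class TestLatentField:
    def test_zero_partial_sill_gives_constant_field(self):
        cfg = small_synth_config(
            events={}, latent_partial_sill=0.0, latent_nugget=0.0, base_probability=0.4
        )
        grid = make_reef_grid(cfg)
        field = simulate_latent_field(grid, cfg, 1997)
        np.testing.assert_allclose(field.to_numpy(), 0.4, atol=1e-12)

    def test_same_seed_is_identical_and_years_differ(self):
        cfg = small_synth_config()
        grid = make_reef_grid(cfg)
        a = simulate_latent_field(grid, cfg, 1997)
        b = simulate_latent_field(grid, cfg, 1997)
        c = simulate_latent_field(grid, cfg, 1999)
        pd.testing.assert_series_equal(a, b, check_names=False)
        assert not np.allclose(a.to_numpy(), c.to_numpy())

    def test_realised_variogram_matches_configuration(self):
        # base level 0.5 and modest sill so clipping is inactive and the
        # realised field keeps the configured spatial structure
        cfg = small_synth_config(
            seed=3, n_reef_cells=400, events={},
            base_probability=0.5, latent_nugget=1e-3, latent_partial_sill=0.04,
            latent_range_km=500.0,
            clusters=[("indian", -5.0, 72.0, 6.0, 1.0)],
        )
        grid = make_reef_grid(cfg)
        field = simulate_latent_field(grid, cfg, 1997)
        emp = empirical_variogram(
            grid.cells["lat"].to_numpy(), grid.cells["lon"].to_numpy(), field.to_numpy(),
            n_bins=10,
        )
        model = VariogramModel("spherical", 1e-3, 0.04, 500.0)
        use = np.isfinite(emp.gamma) & (emp.pair_counts > 200)
        ratio = emp.gamma[use] / model.gamma(emp.lag_centres[use])
        # Monte-Carlo tolerance: one realisation, so allow a wide band
        assert 0.5 < float(np.median(ratio)) < 2.0


class TestSampleReports:
    def test_all_surveyed_certain_bleaching_all_severe(self):
        cfg = small_synth_config(
            events={}, base_probability=1.0, latent_partial_sill=0.0, latent_nugget=0.0,
            effort_fraction=1.0, effort_floor=1.0, severity_noise=0.0, qc_contamination=0.0,
            n_land_reports_per_year=0,
        )
        grid = make_reef_grid(cfg)
        field = simulate_latent_field(grid, cfg, 1998)
        reports = sample_reports(field, grid, cfg, 1998)
        assert len(reports) == len(grid.cells)
        assert (reports["severity_code"] >= 2).all()

    def test_zero_latent_field_yields_no_bleaching_reports(self):
        cfg = small_synth_config(
            events={}, base_probability=0.0, latent_partial_sill=0.0, latent_nugget=0.0,
            n_land_reports_per_year=0,
        )
        grid = make_reef_grid(cfg)
        field = simulate_latent_field(grid, cfg, 1998)
        reports = sample_reports(field, grid, cfg, 1998)
        assert (reports["severity_code"] == 0).all()

    def test_observed_bleaching_fraction_matches_latent_mean(self):
        p = 0.35
        cfg = small_synth_config(
            seed=4, n_reef_cells=600, events={}, base_probability=p,
            latent_partial_sill=0.0, latent_nugget=0.0,
            effort_fraction=1.0, effort_floor=1.0, severity_noise=0.0,
            qc_contamination=0.0, n_land_reports_per_year=0,
            clusters=[("indian", -5.0, 72.0, 6.0, 1.0)],
        )
        grid = make_reef_grid(cfg)
        field = simulate_latent_field(grid, cfg, 1998)
        reports = sample_reports(field, grid, cfg, 1998)
        frac = (reports["severity_code"] >= 1).mean()
        se = np.sqrt(p * (1 - p) / len(reports))
        assert abs(frac - p) < 3 * se

    def test_reports_carry_valid_schema_fields(self, small_dataset):
        r = small_dataset.reports
        assert r["latitude"].between(-90, 90).all()
        assert r["severity_code"].isin([-1, 0, 1, 2, 3]).all()
        assert r["database_code"].isin([1, 2]).all()


class TestEndToEndRecovery:
    def test_kriging_error_decreases_with_sampling_density(self):
        from reefkrige.pipeline import PipelineConfig, run_pipeline

        maes = []
        for floor, frac in [(0.05, 0.1), (0.2, 0.4), (0.6, 0.8)]:
            synth = SynthConfig(
                n_reef_cells=300, years=(1998, 1998),
                events={1998: EventSpec(0.2, amplitude_c=2.0)},
                effort_floor=floor, effort_fraction=frac,
                clusters=[("indian", -5.0, 72.0, 5.0, 1.0)],
            )
            res = run_pipeline(PipelineConfig(synth=synth, years=(1998, 1998), seed=5))
            probs = res.probabilities.set_index("cell_id")["probability"]
            maes.append(float((probs - res.latent[1998]).abs().mean()))
        assert maes[0] > maes[1] > maes[2]


class TestGenerateDataset:
    def test_same_seed_byte_identical(self):
        cfg = small_synth_config()
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        pd.testing.assert_frame_equal(a.reports, b.reports)
        pd.testing.assert_frame_equal(a.latent, b.latent)
        np.testing.assert_array_equal(a.sst, b.sst)

    def test_event_outside_span_rejected(self):
        cfg = small_synth_config(events={2015: EventSpec(0.1)})
        with pytest.raises(ValueError, match="2015"):
            generate_dataset(cfg)
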