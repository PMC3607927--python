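"""Synthetic-data generator: time courses, geometry, rendering, events."""

import math

import numpy as np
import pytest

from endoquant import synthetic as syn
from endoquant.kinetics import fit_logistic
from endoquant.synthetic import (
    CellGeometryParams,
    EventSimConfig,
    ImagingNoiseSpec,
    ImagingSimConfig,
    KineticsSpec,
    generate_cell,
    generate_event_dataset,
    generate_image_dataset,
    interior_fraction_timecourse,
    render_field,
)


class TestTimecourse:
    def test_midpoint(self):
        spec = KineticsSpec(0.1, 0.9, 20.0, 2.0)
        assert interior_fraction_timecourse(spec, 20.0) == pytest.approx(0.5)

    def test_time_zero_is_baseline(self):
        spec = KineticsSpec(0.17, 0.96, 37.0, 0.8)
        assert interior_fraction_timecourse(spec, 0.0) == 0.17

    def test_hand_evaluated(self):
        spec = KineticsSpec(0.1, 0.9, 20.0, 2.0)
        assert interior_fraction_timecourse(spec, 60.0) == pytest.approx(0.82)

    def test_nondecreasing(self):
        spec = KineticsSpec(0.05, 0.95, 15.0, 1.3)
        f = interior_fraction_timecourse(spec, np.linspace(0, 300, 400))
        assert np.all(np.diff(f) >= -1e-12)

    @pytest.mark.parametrize("bad", [(0.5, 0.4, 10, 2), (0.1, 0.9, -1, 2), (0.1, 0.9, 10, 0)])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            KineticsSpec(*bad)

    def test_refit_recovers_generator_parameters(self):
        """Dense noiseless sampling refit by the kinetics module."""
        spec = KineticsSpec(0.1, 0.9, 20.0, 2.0)
        t = np.linspace(0, 150, 40)
        fit = fit_logistic(t, interior_fraction_timecourse(spec, t), family="log_logistic")
        for got, want in [(fit.a1, 0.1), (fit.a2, 0.9), (fit.x0, 20.0), (fit.p, 2.0)]:
            assert got == pytest.approx(want, rel=1e-4)


class TestGenerateCell:
    def test_seeded_determinism(self):
        a = generate_cell(CellGeometryParams(), seed=9)
        b = generate_cell(CellGeometryParams(), seed=9)
        assert a.center == b.center
        assert np.array_equal(a.radii, b.radii)
        assert a.expression_level == b.expression_level

    def test_zero_irregularity_zero_eccentricity_is_circle(self):
        params = CellGeometryParams(eccentricity_range=(0, 0), irregularity_range=(0, 0))
        cell = generate_cell(params, seed=1)
        assert np.allclose(cell.radii, cell.radii[0])

    def test_radii_within_requested_range(self):
        params = CellGeometryParams(radius_range=(15, 25),
                                    eccentricity_range=(0, 0), irregularity_range=(0, 0))
        for seed in range(100):
            cell = generate_cell(params, seed=seed)
            assert 15.0 <= cell.radii.max() <= 25.0

    def test_oversized_cell_rejected(self):
        with pytest.raises(ValueError):
            generate_cell(CellGeometryParams(radius_range=(40, 50)), seed=0, field_shape=(64, 64))


class TestRenderField:
    def test_all_membrane_when_fraction_zero(self):
        cells = [generate_cell(CellGeometryParams(), seed=s, field_shape=(160, 160),
                               cell_id=f"c{s}", center=(80, 80)) for s in (3,)]
        _, truth = render_field(cells, [0.0], ImagingNoiseSpec(), (160, 160), seed=1)
        assert truth["n_puncta_interior"].iloc[0] == 0
        assert truth["flux_interior"].iloc[0] == 0.0

    def test_flux_conservation_without_noise(self):
        noise = ImagingNoiseSpec(background_level=0.0, read_noise_sd=0.0, shot_noise=False)
        cells = [generate_cell(CellGeometryParams(), seed=s, field_shape=(256, 256), cell_id=f"c{s}")
                 for s in (1, 2)]
        fov, truth = render_field(cells, [0.4, 0.7], noise, (256, 256), seed=5)
        total_flux = (truth["flux_interior"] + truth["flux_membrane"]).sum()
        assert fov.qd.sum() == pytest.approx(total_flux, rel=0.01)  # blur-truncation < 1%

    def test_seeded_determinism_bit_exact(self):
        cells = [generate_cell(CellGeometryParams(), seed=2, field_shape=(128, 128), cell_id="c")]
        a, _ = render_field(cells, [0.5], ImagingNoiseSpec(), (128, 128), seed=8)
        b, _ = render_field(cells, [0.5], ImagingNoiseSpec(), (128, 128), seed=8)
        assert np.array_equal(a.receptor, b.receptor)
        assert np.array_equal(a.qd, b.qd)

    def test_fraction_count_mismatch_rejected(self):
        cells = [generate_cell(CellGeometryParams(), seed=2, cell_id="c")]
        with pytest.raises(ValueError):
            render_field(cells, [0.5, 0.5], ImagingNoiseSpec(), (256, 256), seed=0)


class TestImageDataset:
    def _config(self, **kw):
        defaults = dict(
            ligands={"A": KineticsSpec(0.15, 0.95, 10.0, 2.0),
                     "B": KineticsSpec(0.05, 0.95, 30.0, 1.5)},
            times=(0.0, 10.0, 20.0, 150.0),
            fields_per_timepoint=1,
            cells_per_field=2,
            field_shape=(160, 160),
        )
        defaults.update(kw)
        return ImagingSimConfig(**defaults)

    def test_counts(self):
        fields, manifest = generate_image_dataset(self._config(fields_per_timepoint=3), master_seed=0)
        assert len(fields) == 2 * 4 * 3
        assert len(manifest) == 2 * 4 * 3 * 2  # one row per cell

    def test_faster_ligand_dominates_at_intermediate_times(self):
        _, manifest = generate_image_dataset(self._config(), master_seed=1)
        means = manifest.groupby(["ligand", "time_min"])["true_interior_fraction"].mean()
        for t in (10.0, 20.0):
            assert means["A", t] >= means["B", t]

    def test_master_seed_reproducibility(self):
        _, m1 = generate_image_dataset(self._config(), master_seed=42)
        _, m2 = generate_image_dataset(self._config(), master_seed=42)
        assert m1.equals(m2)

    def test_empty_times_rejected(self):
        with pytest.raises(ValueError):
            self._config(times=())


class TestEventDataset:
    def test_realized_transfection_fraction(self):
        cfg = EventSimConfig(n_events=10_000, transfected_fraction=0.4)
        tables, _, truth = generate_event_dataset(cfg, seed=7)
        p = truth["realized_transfected_fraction"].iloc[0]
        # binomial 99% interval around 0.4 at n = 10,000
        assert abs(p - 0.4) < 2.58 * math.sqrt(0.4 * 0.6 / 10_000)

    def test_intensities_strictly_positive(self, event_dataset):
        tables, control, _ = event_dataset
        for tab in list(tables.values()) + [control]:
            assert (tab["syfp"] > 0).all() and (tab["qd"] > 0).all()

    def test_transfected_events_have_elevated_syfp(self, event_dataset):
        tables, _, _ = event_dataset
        t0 = tables[0.0]
        assert (t0.loc[t0["transfected"], "syfp"].median()
                > 5 * t0.loc[~t0["transfected"], "syfp"].median())

    def test_zero_transfection_matches_control_distribution(self):
        cfg = EventSimConfig(n_events=5000, transfected_fraction=0.0)
        tables, control, _ = generate_event_dataset(cfg, seed=2)
        from scipy import stats

        ks = stats.ks_2samp(tables[0.0]["syfp"], control["syfp"])
        assert ks.pvalue > 0.01  # same generating distribution

    def test_flat_kinetics_gives_flat_marker_series(self):
        from endoquant.cytometry import gate_positive, marker_series, place_marker

        cfg = EventSimConfig(n_events=20_000,
                             kinetics=KineticsSpec(0.2, 0.2000001, 30.0, 2.0))
        tables, control, _ = generate_event_dataset(cfg, seed=4)
        gated = {t: gate_positive(tab, control)[1] for t, tab in tables.items()}
        thr = place_marker(gated[0.0])
        stat = marker_series(gated, thr)
        for v in stat.normalized.values():
            assert v == pytest.approx(1.0, abs=0.25)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            EventSimConfig(transfected_fraction=1.5)

    def test_seeded_determinism(self):
        a, _, _ = generate_event_dataset(EventSimConfig(n_events=500), seed=9)
        b, _, _ = generate_event_dataset(EventSimConfig(n_events=500), seed=9)
        for t in a:
            assert a[t].equals(b[t])
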