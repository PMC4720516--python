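"""Generator contracts: curves, noise structure, lattice geometry, rendering."""

import numpy as np
import pytest

from furrow.synthetic import (
    ConfigError,
    SyntheticConfig,
    generate_disc,
    generate_r8_lattice,
    render_image,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"column_spacing_px": 0.0},
            {"hours_per_column": -1.0},
            {"bleed_fraction": 1.5},
            {"hill_params": (0.1, 1.0, 8.0, 0.5)},  # Hill coefficient < 1
            {"copy_number_scale": 0.0},
            {"decay_params": {"R8": (0.1, 1.0, -2.0)}},  # tau <= 0
        ],
    )
    def test_invalid_configs_name_the_field(self, kwargs):
        with pytest.raises(ConfigError):
            SyntheticConfig(**kwargs)

    def test_error_message_names_field(self):
        with pytest.raises(ConfigError, match="bleed_fraction"):
            SyntheticConfig(bleed_fraction=2.0)


class TestMeanCurves:
    def test_zero_noise_progenitors_lie_on_curve(self, quiet_disc):
        cfg, sample, truth = quiet_disc
        prog = sample.cells[sample.cells.cell_type == "progenitor"]
        t = truth.for_cells(prog.cell_id)["true_time_hr"].to_numpy()
        expected = cfg.mean_level(t, "progenitor")
        np.testing.assert_allclose(
            prog["normalized_level"].to_numpy(), expected, rtol=1e-12
        )

    def test_curve_is_hill_before_changeover_decay_after(self):
        cfg = SyntheticConfig()
        a, b, k, n = cfg.hill_params
        t_rise = np.array([0.0, 4.0, 8.0, 12.0])
        np.testing.assert_allclose(
            cfg.mean_level(t_rise, "progenitor"),
            a + b * t_rise**n / (t_rise**n + k**n),
        )
        A, B, tau = cfg.decay_params["progenitor"]
        onset = cfg.onset_hours["progenitor"]
        t_fall = np.array([16.0, 20.0, 30.0])
        np.testing.assert_allclose(
            cfg.mean_level(t_fall, "progenitor"),
            A + B * np.exp(-(t_fall - onset) / tau),
        )

    def test_copy_number_doubles_level_everywhere_keeps_tau(self):
        base = SyntheticConfig(copy_number_scale=1.0)
        doubled = SyntheticConfig(copy_number_scale=2.0)
        t = np.linspace(0, 30, 200)
        for ct in ("progenitor", "R2R5"):
            np.testing.assert_allclose(
                doubled.mean_level(t, ct), 2.0 * base.mean_level(t, ct), rtol=1e-12
            )
        assert doubled.decay_params["progenitor"][2] == base.decay_params["progenitor"][2]

    def test_bleed_floor_when_reporter_absent(self):
        # no reporter at all: measured ratio equals the bleed fraction
        cfg = SyntheticConfig(
            seed=5,
            n_columns=4,
            rows_per_column=3,
            hill_params=(0.0, 0.0, 8.0, 4.0),
            decay_params={ct: (0.0, 0.0, 10.0) for ct in
                          ("progenitor", "R8", "R2R5", "R3R4", "R1R6", "R7", "C1C2", "C3C4")},
            baseline_cv=0.0,
            noise_spikes={},
            r8_distance_coeff=0.0,
        )
        sample, _ = generate_disc(cfg)
        np.testing.assert_allclose(
            sample.cells["normalized_level"].to_numpy(), cfg.bleed_fraction, rtol=1e-12
        )


class TestDeterminism:
    def test_same_seed_same_tables(self):
        cfg = SyntheticConfig(seed=123, n_columns=5, rows_per_column=3)
        s1, t1 = generate_disc(cfg)
        s2, t2 = generate_disc(SyntheticConfig(seed=123, n_columns=5, rows_per_column=3))
        assert s1.cells.equals(s2.cells)
        assert t1.table.equals(t2.table)

    def test_distinct_seeds_distinct_noise(self):
        s1, _ = generate_disc(SyntheticConfig(seed=1, n_columns=5, rows_per_column=3))
        s2, _ = generate_disc(SyntheticConfig(seed=2, n_columns=5, rows_per_column=3))
        assert not np.allclose(
            s1.cells["normalized_level"], s2.cells["normalized_level"]
        )


class TestNoiseSpikes:
    def test_spike_window_raises_group_cv(self):
        """Direct group-wise CV: inside the planted window exceeds outside."""
        cfg = SyntheticConfig(
            seed=9,
            n_columns=16,
            rows_per_column=6,
            noise_spikes={"progenitor": [(10.0, 17.0, 0.3)]},
            cells_per_column={"progenitor": 60},
        )
        sample, truth = generate_disc(cfg)
        prog = sample.cells[sample.cells.cell_type == "progenitor"]
        t = truth.for_cells(prog.cell_id)["true_time_hr"].to_numpy()
        lvl = prog["normalized_level"].to_numpy()
        mean = cfg.mean_level(t, "progenitor") + cfg.bleed_fraction
        ratio = lvl / mean  # detrended multiplicative factors
        inside = np.abs(t - 10.0) <= 8.5
        # restrict 'outside' to cells beyond the window on either side
        outside = ~inside
        cv_in = ratio[inside].std(ddof=1) / ratio[inside].mean()
        cv_out = ratio[outside].std(ddof=1) / ratio[outside].mean()
        assert cv_in > cv_out

    def test_sustained_spike_covers_all_later_times(self):
        cfg = SyntheticConfig(
            noise_spikes={"R2R5": [(12.0, float("inf"), 0.4)]}
        )
        t = np.array([0.0, 11.9, 12.0, 20.0, 40.0])
        cv = cfg.cv_at(t, "R2R5")
        np.testing.assert_allclose(cv, [0.15, 0.15, 0.55, 0.55, 0.55])


class TestLattice:
    def test_noiseless_spacing_exact(self):
        cfg = SyntheticConfig(
            n_columns=4, rows_per_column=3, column_spacing_px=20.0, lattice_jitter_px=0.0
        )
        pts = generate_r8_lattice(cfg)
        xs = np.unique(np.round(pts[:, 0], 9))
        np.testing.assert_allclose(np.diff(xs), 20.0)

    def test_counting(self):
        cfg = SyntheticConfig(n_columns=3, rows_per_column=4, lattice_jitter_px=0.0)
        assert len(generate_r8_lattice(cfg)) == 12

    def test_too_few_columns_error(self):
        with pytest.raises(ConfigError):
            generate_r8_lattice(SyntheticConfig(n_columns=1))

    def test_staggering_offsets_alternate_columns(self):
        cfg = SyntheticConfig(n_columns=4, rows_per_column=3, lattice_jitter_px=0.0)
        pts = generate_r8_lattice(cfg)
        col0_y = np.sort(pts[:3, 1])
        col1_y = np.sort(pts[3:6, 1])
        np.testing.assert_allclose(col1_y - col0_y, cfg.row_spacing_px / 2.0)

    def test_jittered_spacing_unbiased_monte_carlo(self):
        """Mean adjacent-column x-distance stays within 3 SE of the truth."""
        spacing, jitter, n_lat = 20.0, 2.0, 1000
        diffs = []
        for seed in range(n_lat):
            cfg = SyntheticConfig(
                n_columns=3,
                rows_per_column=2,
                column_spacing_px=spacing,
                lattice_jitter_px=jitter,
                seed=seed,
            )
            pts = generate_r8_lattice(cfg)
            col_x = pts[:, 0].reshape(3, 2).mean(axis=1)
            diffs.extend(np.diff(col_x))
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - spacing) < 3 * se


class TestRenderImage:
    def test_single_nucleus_argmax_at_centroid(self):
        import pandas as pd

        from furrow.core import DiscSample

        df = pd.DataFrame(
            [
                dict(
                    disc_id="one",
                    cell_id=0,
                    x_px=30.0,
                    y_px=25.0,
                    section=0,
                    cell_type="progenitor",
                    yfp_mean=50.0,
                    rfp_mean=100.0,
                    nuclear_size_px=120.0,
                )
            ]
        )
        img, mask, (x0, y0) = render_image(
            DiscSample("one", df),
            psf_sigma=1.5,
            background=0.0,
            noise=False,
            return_origin=True,
        )
        r, c = np.unravel_index(np.argmax(img[0]), img[0].shape)
        assert abs(c + x0 - 30.0) <= 1.0 and abs(r + y0 - 25.0) <= 1.0

    def test_every_nucleus_has_mask_pixels(self, sparse_grid_rendered):
        sample, img, mask, _ = sparse_grid_rendered
        ids, counts = np.unique(mask[mask > 0], return_counts=True)
        assert len(ids) == len(sample.cells)
        assert (counts > 0).all()

    def test_rendered_sum_proportional_to_intensity(self):
        import pandas as pd

        from furrow.core import DiscSample

        sums = []
        for amp in (50.0, 100.0, 150.0):
            df = pd.DataFrame(
                [
                    dict(
                        disc_id="p",
                        cell_id=0,
                        x_px=30.0,
                        y_px=30.0,
                        section=0,
                        cell_type="progenitor",
                        yfp_mean=amp,
                        rfp_mean=80.0,
                        nuclear_size_px=110.0,
                    )
                ]
            )
            img, mask = render_image(
                DiscSample("p", df), psf_sigma=1.0, background=0.0, noise=False
            )
            sums.append(img[1][mask == 1].sum())
        ratios = np.array(sums) / sums[0]
        np.testing.assert_allclose(ratios, [1.0, 2.0, 3.0], rtol=1e-6)
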