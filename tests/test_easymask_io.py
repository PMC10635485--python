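import numpy as np
import pytest

import sparsescan as sp
from sparsescan.easymask_io import (
    ScanMask,
    ScanPathError,
    SchemaError,
    coverage_stats,
    mask_from_image,
    mask_to_scan_path,
    read_csv,
    read_h5,
    upscale_mask,
    write_csv,
    write_h5,
)


class TestUpscaleMask:
    def test_integer_factor_gives_constant_blocks(self):
        coarse = ScanMask(np.array([[1, 0], [0, 1]], bool))
        fine = upscale_mask(coarse, 4, 4)
        expect = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], bool
        )
        assert np.array_equal(fine.grid, expect)
        assert fine.coverage_fraction == coarse.coverage_fraction

    def test_all_true_stays_all_true(self):
        fine = upscale_mask(ScanMask(np.ones((8, 8), bool)), 20, 24)
        assert fine.grid.all()

    def test_non_integer_factor_coverage_within_two_points(self):
        rng = np.random.default_rng(3)
        coarse = ScanMask(rng.random((64, 64)) < 0.4)
        fine = upscale_mask(coarse, 160, 160)
        delta = abs(fine.coverage_fraction - coarse.coverage_fraction)
        assert delta <= 0.02

    def test_downscale_refused(self):
        with pytest.raises(ValueError):
            upscale_mask(ScanMask(np.ones((8, 8), bool)), 4, 8)


class TestCoverageStats:
    def test_simple_fraction(self):
        grid = np.zeros(10, bool)
        grid[:3] = True
        assert coverage_stats(ScanMask(grid.reshape(2, 5)))["coverage_percent"] == 30.0

    def test_all_false_is_zero(self):
        assert coverage_stats(ScanMask(np.zeros((4, 4), bool)))["coverage_percent"] == 0.0

    def test_thirty_percent_mask_saves_seventy_when_xrf_dominates(self):
        # dwell-dominated regime: coverage 30% -> ~70% time saving
        rng = np.random.default_rng(1)
        grid = rng.random((100, 100)) < 0.3
        cfg = sp.ScanConfig(rows=100, cols=100, t_stxm=0.005, t_xrf=1.0)
        stats = coverage_stats(ScanMask(grid), cfg)
        assert abs(stats["coverage_percent"] - 30.0) < 2.0
        assert abs(stats["time_saving_percent"] - 70.0) < 2.5


class TestScanPath:
    def test_row_major_coordinates(self):
        cfg = sp.ScanConfig(rows=2, cols=2, step=1.0, origin=(0.0, 0.0))
        rows = mask_to_scan_path(ScanMask(np.ones((2, 2), bool)), cfg)
        assert [(r.x, r.y) for r in rows] == [(0, 0), (1, 0), (0, 1), (1, 1)]
        assert [r.index for r in rows] == [0, 1, 2, 3]

    def test_empty_mask_no_spares_all_zero_flags(self):
        cfg = sp.ScanConfig(rows=4, cols=4)
        rows = mask_to_scan_path(ScanMask(np.zeros((4, 4), bool)), cfg, 0.0)
        assert all(r.xrf_flag == 0 and r.t_xrf == 0.0 for r in rows)

    def test_path_length_always_full_grid(self):
        rng = np.random.default_rng(0)
        for rows_n, cols_n in [(3, 7), (8, 8), (5, 2)]:
            cfg = sp.ScanConfig(rows=rows_n, cols=cols_n)
            mask = ScanMask(rng.random((rows_n, cols_n)) < 0.5)
            assert len(mask_to_scan_path(mask, cfg)) == rows_n * cols_n

    def test_flags_reconstruct_mask_exactly(self):
        rng = np.random.default_rng(5)
        grid = rng.random((16, 16)) < 0.3
        cfg = sp.ScanConfig(rows=16, cols=16)
        rows = mask_to_scan_path(ScanMask(grid), cfg, spare_fraction=0.0)
        rebuilt = np.array([r.xrf_flag for r in rows], bool).reshape(16, 16)
        assert np.array_equal(rebuilt, grid)
        stats = coverage_stats(ScanMask(grid))
        assert stats["pixels_true"] == sum(r.xrf_flag for r in rows)


class TestCsvRoundTrip:
    def test_large_path_round_trips_exactly(self, tmp_path):
        rng = np.random.default_rng(2)
        cfg = sp.ScanConfig(rows=100, cols=100, step=0.5, origin=(-10.0, 3.0),
                            t_stxm=0.005, t_xrf=1.5)
        mask = ScanMask(rng.random((100, 100)) < 0.3)
        rows = mask_to_scan_path(mask, cfg, spare_fraction=0.02, seed=4)
        p = tmp_path / "path.csv"
        write_csv(rows, p)
        assert read_csv(p) == rows

    def test_flag_domain_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("index,x_um,y_um,stxm,xrf,t_stxm_s,t_xrf_s\n0,0.0,0.0,1,2,0.005,1.0\n")
        with pytest.raises(ScanPathError, match="flags"):
            read_csv(p)

    def test_empty_file_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ScanPathError, match="empty"):
            read_csv(p)

    def test_malformed_header_error(self, tmp_path):
        p = tmp_path / "hdr.csv"
        p.write_text("idx,x,y\n")
        with pytest.raises(ScanPathError, match="header"):
            read_csv(p)

    def test_non_monotone_index_error(self, tmp_path):
        p = tmp_path / "mono.csv"
        p.write_text(
            "index,x_um,y_um,stxm,xrf,t_stxm_s,t_xrf_s\n"
            "1,0.0,0.0,1,0,0.005,0.0\n0,1.0,0.0,1,0,0.005,0.0\n"
        )
        with pytest.raises(ScanPathError, match="monotone"):
            read_csv(p)


class TestH5RoundTrip:
    @pytest.fixture
    def record(self, leaf32, stable_beam):
        cfg = sp.ScanConfig(rows=32, cols=32, t_stxm=0.005, t_xrf=0.2,
                            elements=("C", "O"), noise_sigma=0.5)
        strat = sp.AbsorptionThresholdStrategy(threshold=45.0, normalizer="ring")
        return sp.run_scan(leaf32, stable_beam, cfg, strat, seed=8)

    def test_record_round_trip_is_lossless(self, tmp_path, record):
        p = tmp_path / "scan.h5"
        write_h5(record, p)
        back = read_h5(p)
        assert np.array_equal(back.stxm, record.stxm)
        for el in record.xrf:
            assert np.array_equal(back.xrf[el], record.xrf[el])
        assert np.array_equal(back.acquired_xrf_mask, record.acquired_xrf_mask)
        assert np.array_equal(back.ring_current_log, record.ring_current_log)
        assert np.array_equal(back.bpm_log, record.bpm_log)
        assert np.array_equal(back.value_compared, record.value_compared)
        assert back.elapsed_total == record.elapsed_total
        assert back.config == record.config
        assert back.strategy_name == record.strategy_name

    def test_sample_round_trip(self, tmp_path, leaf32):
        p = tmp_path / "gt.h5"
        write_h5(leaf32, p)
        back = read_h5(p)
        assert np.array_equal(back.transmission, leaf32.transmission)
        assert np.array_equal(back.support_mask, leaf32.support_mask)
        for el in leaf32.xrf_rate:
            assert np.array_equal(back.xrf_rate[el], leaf32.xrf_rate[el])

    def test_sentinel_marks_non_acquired_pixels(self, tmp_path, record):
        p = tmp_path / "scan.h5"
        write_h5(record, p)
        back = read_h5(p)
        for el in back.xrf:
            not_acq = back.xrf[el] == -1.0
            assert np.array_equal(not_acq, ~back.acquired_xrf_mask)
            assert (back.xrf[el][~not_acq] >= 0).all()

    def test_missing_diagnostics_is_schema_error(self, tmp_path, record):
        import h5py

        p = tmp_path / "scan.h5"
        write_h5(record, p)
        with h5py.File(p, "a") as f:
            del f["diagnostics"]
        with pytest.raises(SchemaError, match="diagnostics"):
            read_h5(p)


def test_mask_from_grayscale_image_thresholds_at_half_range(tmp_path):
    import imageio.v3 as iio

    img = np.zeros((16, 16), np.uint8)
    img[4:12, 4:12] = 255
    img[0, 0] = 120  # just below half range
    p = tmp_path / "mask.png"
    iio.imwrite(p, img)
    mask = mask_from_image(str(p))
    assert mask.grid[8, 8] and not mask.grid[0, 0]
    assert mask.grid.sum() == 64
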