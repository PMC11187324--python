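"""Four-stage tile QC: per-stage contracts, Otsu oracle, contamination recall."""

import dataclasses

import numpy as np
import pytest

from blscreen.qc import (
    QCThresholds,
    background_filter,
    otsu_threshold,
    otsu_tissue_filter,
    pen_mark_filter,
    purple_pink_filter,
    run_qc,
)
from blscreen.synthetic import generate_tile

from .conftest import hue_band_count


def brute_force_otsu(hist):
    """Exhaustive between-class-variance scan; ties to the lowest threshold."""
    total = hist.sum()
    best_t, best_var = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            var = 0.0
        else:
            mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / (w0 * total)
            mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / (w1 * total)
            var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


class TestBackgroundFilter:
    def test_constant_white_fails_with_zero_std(self):
        tile = np.full((64, 64, 3), 255, dtype=np.uint8)
        ok, std = background_filter(tile)
        assert (ok, std) == (False, 0.0)

    def test_two_point_distribution_std(self):
        tile = np.zeros((64, 64, 3), dtype=np.uint8)
        tile[:32] = 255
        ok, std = background_filter(tile)
        assert ok and std == pytest.approx(127.5)

    def test_clean_tile_std_matches_accumulation_oracle(self, clean_pos_tile):
        ok, std = background_filter(clean_pos_tile)
        # independent two-pass accumulation
        vals = clean_pos_tile.astype(np.float64).ravel()
        mean = vals.sum() / vals.size
        oracle = np.sqrt(((vals - mean) ** 2).sum() / vals.size)
        assert ok
        assert std == pytest.approx(oracle, rel=1e-12)

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            background_filter(np.zeros((64, 64), dtype=np.uint8))


class TestPenMarkFilter:
    def test_fully_green_tile_fails(self):
        tile = np.zeros((32, 32, 3), dtype=np.uint8)
        tile[..., 1] = 200  # saturated green, hue 120
        ok, frac = pen_mark_filter(tile)
        assert (ok, frac) == (False, 1.0)

    def test_penless_tile_passes_with_zero_fraction(self):
        tile = np.full((32, 32, 3), (230, 180, 200), dtype=np.uint8)  # pink-ish
        ok, frac = pen_mark_filter(tile)
        assert (ok, frac) == (True, 0.0)

    def test_green_patch_fraction_counted_exactly(self):
        tile = np.full((64, 64, 3), (230, 180, 200), dtype=np.uint8)
        tile[:16, :16] = (0, 200, 0)
        ok, frac = pen_mark_filter(tile)
        assert frac == pytest.approx(256 / 4096)
        assert not ok  # 0.0625 > default 0.05

    def test_degenerate_range_warns(self):
        ranges = {"green": ((200.0, 100.0), (0.0, 1.0), (0.0, 1.0))}
        tile = np.full((8, 8, 3), 128, dtype=np.uint8)
        with pytest.warns(UserWarning, match="degenerate"):
            pen_mark_filter(tile, ranges)


class TestPurplePinkFilter:
    def test_all_purple_passes_with_infinite_ratio(self):
        tile = np.full((32, 32, 3), (128, 0, 255), dtype=np.uint8)  # hue 270
        ok, ratio = purple_pink_filter(tile)
        assert ok and ratio == float("inf")

    def test_all_pink_fails(self):
        tile = np.full((32, 32, 3), (255, 0, 128), dtype=np.uint8)  # hue 330
        ok, ratio = purple_pink_filter(tile)
        assert (ok, ratio) == (False, 0.0)

    def test_no_stain_evidence_fails(self):
        tile = np.full((32, 32, 3), 240, dtype=np.uint8)  # unsaturated glass
        ok, ratio = purple_pink_filter(tile)
        assert (ok, ratio) == (False, 0.0)

    def test_constructed_ratio_counted_exactly(self):
        """300 purple + 600 pink qualifying pixels -> ratio 0.5, passing 0.3."""
        tile = np.full((30, 30, 3), 255, dtype=np.uint8)  # 900 px, sat 0: neither band
        flat = tile.reshape(-1, 3)
        flat[:300] = (128, 0, 255)  # purple, hue 270
        flat[300:900] = (255, 0, 128)  # pink, hue 330
        ok, ratio = purple_pink_filter(tile)
        assert ratio == pytest.approx(0.5)
        assert ok

    def test_band_counts_match_per_pixel_oracle(self, clean_neg_tile):
        _, ratio = purple_pink_filter(clean_neg_tile)
        purple = hue_band_count(clean_neg_tile, 250, 310, sat_floor=0.15)
        pink = hue_band_count(clean_neg_tile, 310, 360, sat_floor=0.15)
        assert ratio == pytest.approx(purple / pink)


class TestOtsuTissueFilter:
    def test_constant_tile_fails_degenerate_histogram(self):
        tile = np.full((32, 32, 3), 200, dtype=np.uint8)
        ok, frac, _ = otsu_tissue_filter(tile)
        assert (ok, frac) == (False, 0.0)

    def test_bimodal_tile_splits_between_modes(self):
        tile = np.full((64, 64, 3), 240, dtype=np.uint8)  # light background
        tile[:32] = 20  # dark tissue
        ok, frac, t = otsu_tissue_filter(tile)
        assert ok and frac == pytest.approx(0.5)
        assert 255 - 240 <= t < 255 - 20  # threshold lies between the complement modes

    def test_synthetic_low_tissue_fails_default(self):
        ok, frac, _ = otsu_tissue_filter(generate_tile(1, "low_tissue", 64, 3))
        assert not ok and frac <= 0.10

    def test_otsu_matches_exhaustive_scan_on_random_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_modes = rng.integers(1, 4)
            vals = np.concatenate([
                rng.normal(rng.uniform(0, 255), rng.uniform(1, 40), rng.integers(50, 500))
                for _ in range(n_modes)
            ])
            vals = np.clip(np.rint(vals), 0, 255).astype(np.uint8)
            hist = np.bincount(vals, minlength=256).astype(float)
            assert otsu_threshold(vals) == brute_force_otsu(hist)


class TestRunQC:
    def test_blank_fails_at_background_and_short_circuits(self):
        res = run_qc(generate_tile(1, "blank", 64, 0))
        assert not res.passed
        assert res.fail_stage == "background"
        assert res.stage_flags["pen"] is None
        assert "pen_fraction" not in res.scores

    def test_pen_tile_passes_background_fails_pen(self):
        res = run_qc(generate_tile(1, "pen_green", 64, 0))
        assert res.stage_flags["background"] is True
        assert res.fail_stage == "pen"
        assert res.stage_flags["purple_pink"] is None

    def test_clean_tile_passes_all_stages(self, clean_pos_tile):
        res = run_qc(clean_pos_tile)
        assert res.passed
        assert all(res.stage_flags[s] is True for s in res.stage_flags)

    def test_pure_function_of_inputs(self, clean_pos_tile, default_thresholds):
        a = run_qc(clean_pos_tile, default_thresholds)
        b = run_qc(clean_pos_tile, default_thresholds)
        assert a == b

    @pytest.mark.parametrize("artifact", ["clean", "low_tissue", "pen_blue"])
    def test_raising_thresholds_never_rescues_a_failing_tile(self, artifact):
        tile = generate_tile(0, artifact, 64, 5)
        base = QCThresholds()
        stricter = [
            dataclasses.replace(base, bg_std_min=base.bg_std_min + 10),
            dataclasses.replace(base, pen_fraction_max=base.pen_fraction_max / 2),
            dataclasses.replace(base, pp_ratio_min=base.pp_ratio_min * 2),
            dataclasses.replace(base, tissue_fraction_min=base.tissue_fraction_min * 2),
        ]
        base_pass = run_qc(tile, base).passed
        for th in stricter:
            assert not (run_qc(tile, th).passed and not base_pass)

    def test_band_overlap_rejected_in_thresholds(self):
        with pytest.raises(ValueError, match="disjoint"):
            QCThresholds(purple_band=(250.0, 320.0), pink_band=(310.0, 360.0))


def test_contamination_recall_sample():
    """Spot check (20 seeds/category) that artifacts are rejected at the
    stage that targets them and clean tiles are retained; the full 100-seed
    suite runs in the acceptance tests."""
    expected_stage = {
        "blank": "background",
        "pen_green": "pen",
        "pen_blue": "pen",
        "pen_gray": "pen",
        "low_tissue": "otsu",
    }
    for artifact, stage in expected_stage.items():
        results = [run_qc(generate_tile(s % 2, artifact, 64, s)) for s in range(20)]
        correct = sum(r.fail_stage == stage for r in results)
        assert correct >= 19, f"{artifact}: {correct}/20 rejected at {stage}"
    clean = [run_qc(generate_tile(s % 2, "clean", 64, s)) for s in range(20)]
    assert sum(r.passed for r in clean) >= 19
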