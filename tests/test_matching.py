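import numpy as np
import pytest

from angiotrack.contrast import ContrastWindow
from angiotrack.errors import BankError, DegenerateInputError, ValidationError
from angiotrack.matching import (
    match_frame,
    normalized_cross_correlation,
    track_sequence,
)
from angiotrack.segmentation import VesselContour, extract_contours
from angiotrack.templates import TemplateBank, TemplateFrame


def pearson_loop_oracle(a, b, region=None):
    """Independent scalar double-loop evaluation of the Pearson formula."""
    rows, cols = a.shape
    pts = [
        (i, j)
        for i in range(rows)
        for j in range(cols)
        if region is None or region[i, j]
    ]
    n = len(pts)
    ma = sum(a[p] for p in pts) / n
    mb = sum(b[p] for p in pts) / n
    num = sum((a[p] - ma) * (b[p] - mb) for p in pts)
    da = sum((a[p] - ma) ** 2 for p in pts)
    db = sum((b[p] - mb) ** 2 for p in pts)
    return num / (da**0.5 * db**0.5)


def _toy_template(frame_index, image, mask=None):
    if mask is None:
        mask = np.zeros(image.shape, dtype=bool)
        mask[2:5, 2:5] = True
    return TemplateFrame(
        frame_index=frame_index,
        image=image,
        mask=mask,
        contour=extract_contours(mask, frame_index=frame_index),
        background_mask=~mask,
    )


class TestNCC:
    def test_self_correlation_is_one(self, rng):
        a = rng.random((12, 12))
        assert normalized_cross_correlation(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_negation_is_minus_one(self, rng):
        a = rng.random((12, 12))
        assert normalized_cross_correlation(a, 1.0 - a) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            a = rng.random((8, 8))
            b = rng.random((8, 8))
            assert normalized_cross_correlation(a, b) == pytest.approx(
                pearson_loop_oracle(a, b), abs=1e-10
            )

    def test_matches_oracle_with_region_mask(self, rng):
        for _ in range(10):
            a = rng.random((8, 8))
            b = rng.random((8, 8))
            region = rng.random((8, 8)) > 0.4
            if region.sum() < 2:
                continue
            assert normalized_cross_correlation(a, b, region) == pytest.approx(
                pearson_loop_oracle(a, b, region), abs=1e-10
            )

    def test_affine_rescale_invariance(self, rng):
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        r0 = normalized_cross_correlation(a, b)
        assert normalized_cross_correlation(2.5 * a + 0.3, b) == pytest.approx(r0, abs=1e-12)
        assert normalized_cross_correlation(a, 0.01 * b - 7.0) == pytest.approx(r0, abs=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.random((10, 10)), rng.random((10, 10))
        assert normalized_cross_correlation(a, b) == normalized_cross_correlation(b, a)

    def test_bounds_on_random_pairs(self, rng):
        for _ in range(300):
            r = normalized_cross_correlation(rng.random((6, 6)), rng.random((6, 6)))
            assert -1.0 <= r <= 1.0

    def test_zero_variance_raises(self, rng):
        with pytest.raises(DegenerateInputError):
            normalized_cross_correlation(np.full((8, 8), 0.5), rng.random((8, 8)))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            normalized_cross_correlation(rng.random((8, 8)), rng.random((9, 8)))

    def test_too_small_region_rejected(self, rng):
        region = np.zeros((8, 8), dtype=bool)
        region[0, 0] = True
        with pytest.raises(ValidationError):
            normalized_cross_correlation(rng.random((8, 8)), rng.random((8, 8)), region)


class TestMatchFrame:
    def test_self_match_wins_with_score_one(self, rng):
        images = [rng.random((16, 16)) for _ in range(3)]
        bank = TemplateBank(
            templates=[_toy_template(i, img) for i, img in enumerate(images)],
            window=ContrastWindow(0, 2),
        )
        res = match_frame(images[1], bank, region_mode="full", query_frame_index=9)
        assert res.best_template_index == 1
        assert res.score == pytest.approx(1.0, abs=1e-12)
        assert res.score == max(res.all_scores)
        assert res.transferred_contour.source_frame_index == 9

    def test_tie_breaks_to_lowest_frame_index(self, rng):
        img = rng.random((16, 16))
        bank = TemplateBank(
            templates=[_toy_template(0, img), _toy_template(1, img.copy())],
            window=ContrastWindow(0, 1),
        )
        res = match_frame(img, bank, region_mode="full")
        assert res.best_template_index == 0

    def test_degenerate_query_scores_zero_everywhere(self, rng):
        bank = TemplateBank(
            templates=[_toy_template(0, rng.random((16, 16)))],
            window=ContrastWindow(0, 0),
        )
        res = match_frame(np.full((16, 16), 0.3), bank, region_mode="full")
        assert res.score == 0.0
        np.testing.assert_array_equal(res.all_scores, 0.0)

    def test_unknown_region_mode_rejected(self, rng):
        bank = TemplateBank(
            templates=[_toy_template(0, rng.random((8, 8)))],
            window=ContrastWindow(0, 0),
        )
        with pytest.raises(ValidationError):
            match_frame(rng.random((8, 8)), bank, region_mode="partial")

    def test_dimension_mismatch_rejected(self, rng):
        bank = TemplateBank(
            templates=[_toy_template(0, rng.random((8, 8)))],
            window=ContrastWindow(0, 0),
        )
        with pytest.raises(ValidationError):
            match_frame(rng.random((9, 9)), bank)


@pytest.fixture(scope="module")
def tracked(mini_phantom):
    from angiotrack.templates import build_template_bank

    seq, truth = mini_phantom
    bank = build_template_bank(seq, truth.true_bolus_window)
    dye_free = list(range(truth.true_bolus_window.start))
    return seq, truth, bank, track_sequence(seq, bank, dye_free)


class TestTrackSequence:
    def test_empty_indices_give_empty_results(self, tracked):
        seq, _, bank, _ = tracked
        assert track_sequence(seq, bank, []) == []

    def test_bank_frame_as_query_rejected(self, tracked):
        seq, truth, bank, _ = tracked
        with pytest.raises(ValidationError):
            track_sequence(seq, bank, [truth.true_bolus_window.start])

    def test_out_of_range_index_rejected(self, tracked):
        seq, _, bank, _ = tracked
        with pytest.raises(ValidationError):
            track_sequence(seq, bank, [len(seq)])

    def test_one_result_per_frame_in_order(self, tracked):
        _, truth, _, results = tracked
        assert [r.query_frame_index for r in results] == list(
            range(truth.true_bolus_window.start)
        )

    def test_results_carry_nonempty_contours(self, tracked):
        _, _, _, results = tracked
        for r in results:
            assert len(r.transferred_contour.polylines) > 0

    def test_phase_recovery_within_one_frame(self, tracked):
        _, truth, bank, results = tracked
        period = truth.period_frames
        for r in results:
            d = abs(
                int(truth.true_phase[r.best_template_index])
                - int(truth.true_phase[r.query_frame_index])
            ) % period
            assert min(d, period - d) <= 1

    def test_empty_bank_construction_rejected(self):
        with pytest.raises(BankError):
            TemplateBank(templates=[], window=ContrastWindow(0, 0))
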