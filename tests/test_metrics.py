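"""Tissue ratios and the confusion-matrix metric suite."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from epistroma.metrics import (
    ConfusionCounts,
    MetricSet,
    PatchTissueCounts,
    TissueRatios,
    compute_metrics,
    compute_ratios,
    confusion,
    count_patch,
    macro_average,
    metrics_from_rates,
)


class TestCounting:
    def test_empty_mask(self):
        c = count_patch(np.zeros((5, 5), dtype=np.uint8))
        assert (c.tissue, c.epithelium, c.stroma) == (0, 0, 0)

    def test_direct_count(self, rng):
        mask = np.zeros(100, dtype=np.uint8)
        mask[:30] = 1
        mask[30:50] = 2
        rng.shuffle(mask)
        c = count_patch(mask.reshape(10, 10))
        assert (c.tissue, c.epithelium, c.stroma) == (50, 30, 20)

    def test_counts_invariant_under_permutation(self, rng):
        mask = rng.integers(0, 3, 64).astype(np.uint8)
        c1 = count_patch(mask.reshape(8, 8))
        rng.shuffle(mask)
        c2 = count_patch(mask.reshape(8, 8))
        assert c1 == c2

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            PatchTissueCounts(tissue=10, epithelium=3, stroma=4)


class TestRatios:
    def test_pooled_arithmetic(self):
        counts = [PatchTissueCounts(100, 60, 40), PatchTissueCounts(50, 10, 40)]
        r = compute_ratios(counts)
        assert r.ratio_epi == pytest.approx(70 / 150)
        assert r.ratio_stro == pytest.approx(80 / 150)

    def test_single_pure_epithelium_patch(self):
        r = compute_ratios([PatchTissueCounts(25, 25, 0)])
        assert (r.ratio_epi, r.ratio_stro) == (1.0, 0.0)

    def test_no_tissue_is_an_error(self):
        with pytest.raises(ValueError):
            compute_ratios([])
        with pytest.raises(ValueError):
            compute_ratios([PatchTissueCounts(0, 0, 0)])

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=1, max_size=8))
    def test_ratio_conservation(self, pairs):
        counts = [PatchTissueCounts(e + s, e, s) for e, s in pairs]
        if sum(c.tissue for c in counts) == 0:
            return
        r = compute_ratios(counts)
        assert r.ratio_epi + r.ratio_stro == pytest.approx(1.0, abs=1e-12)


class TestConfusion:
    def test_perfect_prediction(self, rng):
        truth = rng.integers(0, 3, (6, 6)).astype(np.uint8)
        c = confusion(truth, truth, positive_label=1)
        assert c.fp == 0 and c.fn == 0

    def test_label_swap_inverts(self, rng):
        truth = rng.integers(1, 3, (6, 6)).astype(np.uint8)
        swapped = np.where(truth == 1, 2, 1).astype(np.uint8)
        c = confusion(swapped, truth, positive_label=1)
        assert c.tp == 0 and c.tn == 0

    def test_matches_exhaustive_tally(self):
        truth = np.array([[0, 1, 2, 1], [2, 2, 1, 0], [1, 0, 2, 2], [1, 1, 0, 2]], dtype=np.uint8)
        pred = np.array([[1, 1, 1, 2], [2, 1, 1, 0], [0, 2, 2, 2], [1, 2, 2, 2]], dtype=np.uint8)
        tp = fp = tn = fn = 0
        for t, p in zip(truth.ravel(), pred.ravel()):
            if t == 0:
                continue
            if t == 1 and p == 1:
                tp += 1
            elif t == 1:
                fn += 1
            elif p == 1:
                fp += 1
            else:
                tn += 1
        c = confusion(pred, truth, positive_label=1)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)), positive_label=1)


class TestMetricFormulas:
    def test_hand_computed_example(self):
        m = compute_metrics(ConfusionCounts(tp=90, fp=20, tn=80, fn=10))
        assert m.TPR == pytest.approx(0.90)
        assert m.TNR == pytest.approx(0.80)
        assert m.ACC == pytest.approx(0.85)
        assert m.F1 == pytest.approx(180 / 210)
        assert m.MCC == pytest.approx(7000 / math.sqrt(110 * 100 * 100 * 90))

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=40, fp=0, tn=60, fn=0))
        for k in ("TPR", "TNR", "PPV", "NPV", "ACC", "F1", "MCC"):
            assert getattr(m, k) == pytest.approx(1.0)
        for k in ("FPR", "FDR", "FNR"):
            assert getattr(m, k) == pytest.approx(0.0)

    def test_zero_denominator_flagged_not_silent(self):
        with pytest.warns(UserWarning):
            m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert math.isnan(m.TPR)

    @given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
    def test_complement_and_harmonic_identities(self, tp, fp, tn, fn):
        if tp + fn == 0 or fp + tn == 0 or tp + fp == 0:
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert m.FNR == pytest.approx(1 - m.TPR, abs=1e-12)
        assert m.FPR == pytest.approx(1 - m.TNR, abs=1e-12)
        assert m.FDR == pytest.approx(1 - m.PPV, abs=1e-12)
        if not math.isnan(m.F1) and m.PPV + m.TPR > 0:
            harm = 2 * m.PPV * m.TPR / (m.PPV + m.TPR)
            assert m.F1 == pytest.approx(harm, abs=1e-12)
        if not math.isnan(m.MCC):
            assert -1.0 - 1e-12 <= m.MCC <= 1.0 + 1e-12

    def test_published_rate_triple_reproduces_f1(self):
        # harmonic-mean consistency at rates printed to 4 significant figures
        f1 = 2 * 0.9071 * 0.9081 / (0.9071 + 0.9081)
        assert round(100 * f1, 2) == 90.76

    def test_reporting_scale(self):
        m = compute_metrics(ConfusionCounts(tp=90, fp=20, tn=80, fn=10))
        pct = m.as_percent()
        assert pct["ACC"] == 85.0
        assert pct["F1"] == round(100 * 180 / 210, 2)

    def test_metrics_from_rates_round_trip(self):
        base = compute_metrics(ConfusionCounts(tp=90, fp=20, tn=80, fn=10))
        rec = metrics_from_rates(base.TPR, base.TNR, base.PPV)
        for k in ("NPV", "ACC", "F1", "MCC", "FNR", "FDR", "FPR"):
            assert getattr(rec, k) == pytest.approx(getattr(base, k), abs=1e-12)

    def test_macro_average(self):
        a = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        b = compute_metrics(ConfusionCounts(tp=5, fp=5, tn=5, fn=5))
        m = macro_average([a, b])
        assert m.ACC == pytest.approx((a.ACC + b.ACC) / 2)


class TestQuantificationRecovery:
    def test_ground_truth_segmentation_recovers_planted_fraction(self, demo_slide):
        from epistroma.metrics import count_patch as cp
        from epistroma.pipeline import GroundTruthSegmenter, PipelineConfig, Slide, process_slide

        _, img, mask, achieved = demo_slide
        res = process_slide(Slide(img), GroundTruthSegmenter(mask),
                            PipelineConfig(patch_w=160, patch_h=160, seed=0))
        r = compute_ratios([cp(res.tissue_mask)])
        assert r.ratio_epi + r.ratio_stro == pytest.approx(1.0)
        assert abs(r.ratio_epi - achieved) <= 0.05
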