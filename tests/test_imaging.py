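"""Synthetic stacks, registration, segmentation, extraction, full pipeline."""

import numpy as np
import pytest

from seerfish import cellmap as cm
from seerfish import codebook as cb
from seerfish import fixtures, imaging
from seerfish.hybridization import SpecificityModel


@pytest.fixture(scope="module")
def ideal_bundle():
    return fixtures.make_fixtures("syncom12-ideal", seed=5)


@pytest.fixture(scope="module")
def ideal_run(ideal_bundle):
    return imaging.run_pipeline(ideal_bundle.stack, ideal_bundle.codebook)


class TestSynthesizeStack:
    def test_blank_stack_for_zero_cells(self, codebook12, diagonal_model):
        cfg = imaging.SynthConfig(model=diagonal_model, shape=(64, 64),
                                  n_cells=0, noise_sd=0.01, seed=0)
        stack, layout, truth = imaging.synthesize_stack(cfg, codebook12)
        assert len(layout.cells) == 0 and len(truth) == 0
        # fluorescence planes are pure noise around zero
        assert stack.images[:, 1:].mean() < 0.02

    def test_deterministic(self, codebook12, diagonal_model):
        cfg = imaging.SynthConfig(model=diagonal_model, shape=(96, 96),
                                  n_cells=6, seed=3)
        s1, _, _ = imaging.synthesize_stack(cfg, codebook12)
        s2, _, _ = imaging.synthesize_stack(cfg, codebook12)
        assert np.array_equal(s1.images, s2.images)

    def test_noiseless_roundtrip_amplitude(self, codebook12):
        # sigma=0, no blur/noise: mean in-cell intensity equals the planted
        # amplitude in the codeword channel
        model = SpecificityModel.diagonal(codebook12.taxa, class_sigma=0.0)
        cfg = imaging.SynthConfig(model=model, shape=(96, 96), n_cells=3,
                                  psf_sigma=0.0, noise_sd=0.0, seed=1)
        stack, layout, truth = imaging.synthesize_stack(cfg, codebook12)
        row = layout.cells.iloc[0]
        rr, cc = layout.cell_pixels(row)
        symbol = codebook12.barcode_of(row["taxon"])[0]
        vals = stack.channel(0, symbol - 1)[rr, cc]
        assert vals.min() >= 10 ** -0.3   # specific amplitude present everywhere

    def test_overcrowded_layout_raises(self, codebook12, diagonal_model):
        cfg = imaging.SynthConfig(model=diagonal_model, shape=(48, 48),
                                  n_cells=500, min_sep_um=3.0, seed=0)
        with pytest.raises(RuntimeError):
            imaging.synthesize_stack(cfg, codebook12)


class TestRegistration:
    def test_zero_drift_recovered_as_zero(self, ideal_bundle):
        shifts, _ = imaging.register_stack(ideal_bundle.stack)
        assert shifts == [(0, 0)] * ideal_bundle.stack.R

    def test_planted_drift_recovered_exactly(self):
        bundle = fixtures.make_fixtures("drifted-stack", seed=5)
        planted = [(0, 0), (3, -2), (-5, 4), (10, 0), (0, -10),
                   (7, 7), (-8, -3), (2, 9)]
        shifts, aligned = imaging.register_stack(bundle.stack)
        assert shifts == [(-dy, -dx) for dy, dx in planted]
        # aligned reference planes match round 1
        ref0 = aligned.reference(0)
        for r in range(1, aligned.R):
            assert np.corrcoef(ref0.ravel(), aligned.reference(r).ravel())[0, 1] > 0.98

    def test_shift_inverse_property(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        img = np.clip(img, 0.3, None)
        for dy, dx in [(5, -3), (-7, 2), (0, 9)]:
            shifted = np.roll(img, (dy, dx), axis=(0, 1))
            assert imaging.find_shift(img, shifted) == (-dy, -dx)

    def test_fft_equals_brute_force(self):
        rng = np.random.default_rng(1)
        ref = rng.random((16, 16))
        img = np.roll(ref, (3, -5), axis=(0, 1)) + rng.normal(0, 0.05, (16, 16))
        best, best_score = None, -np.inf
        a = ref - ref.mean()
        b = img - img.mean()
        for dy in range(16):
            for dx in range(16):
                score = float((a * np.roll(b, (dy, dx), axis=(0, 1))).sum())
                if score > best_score:
                    best, best_score = (dy, dx), score
        dy, dx = best
        expect = (dy - 16 if dy > 8 else dy, dx - 16 if dx > 8 else dx)
        assert imaging.find_shift(ref, img) == expect

    def test_flat_reference_rejected(self):
        flat = np.ones((32, 32))
        with pytest.raises(ValueError):
            imaging.find_shift(flat, flat)


class TestSegmentation:
    def test_blank_image_gives_no_labels(self):
        rng = np.random.default_rng(0)
        img = 0.8 + rng.normal(0, 0.01, size=(128, 128))
        labels = imaging.segment(img)
        assert labels.max() == 0

    def test_planted_separated_cells_counted(self, codebook12, diagonal_model):
        cfg = imaging.SynthConfig(model=diagonal_model, shape=(256, 256),
                                  n_cells=50, min_sep_um=3.0, seed=2)
        stack, layout, _ = imaging.synthesize_stack(cfg, codebook12)
        labels = imaging.segment(stack.reference(0))
        n = labels.max()
        assert abs(n - 50) <= 0.05 * 50
        # every planted centroid falls on some label
        px = stack.pixel_size
        hit = sum(labels[int(r["y_um"] / px), int(r["x_um"] / px)] > 0
                  for _, r in layout.cells.iterrows())
        assert hit >= 48

    def test_touching_pair_split_by_watershed(self):
        # two rod cells meeting tip-to-tip with a slight overlap (the
        # bacterial chain configuration): watershed must cut the waist
        img = np.full((64, 64), 0.8)
        from skimage.draw import ellipse
        for cx in (25, 40):
            rr, cc = ellipse(32, cx, 3.2, 8, shape=img.shape)
            img[rr, cc] = 0.2
        from scipy import ndimage as ndi
        img = ndi.gaussian_filter(img, 1.0)
        labels = imaging.segment(img)
        assert labels.max() == 2


class TestExtraction:
    def test_constant_channel_means(self, ideal_bundle, ideal_run):
        stack = ideal_bundle.stack
        labels = ideal_run.labels
        const = stack.images.copy()
        const[:, 1:, :, :] = 0.42
        table = imaging.extract_cell_table(
            imaging.ImageStack(const, stack.pixel_size), labels)
        assert np.allclose(table.means, 0.42)

    def test_row_count_matches_labels(self, ideal_run):
        assert len(ideal_run.table.cell_ids) == ideal_run.labels.max()
        assert ideal_run.table.means.shape[0] == ideal_run.labels.max()

    def test_planted_amplitude_recovered(self, codebook12):
        model = SpecificityModel.diagonal(codebook12.taxa, class_sigma=0.0)
        cfg = imaging.SynthConfig(model=model, shape=(128, 128), n_cells=5,
                                  psf_sigma=0.0, noise_sd=0.0, seed=4)
        stack, layout, _ = imaging.synthesize_stack(cfg, codebook12)
        labels = imaging.segment(stack.reference(0))
        table = imaging.extract_cell_table(stack, labels)
        px = stack.pixel_size
        for _, row in layout.cells.iterrows():
            lab = labels[int(row["y_um"] / px), int(row["x_um"] / px)]
            if lab == 0:
                continue
            i = table.cell_ids.index(lab)
            symbol = codebook12.barcode_of(row["taxon"])[0]
            # in-cell mean in the codeword channel is close to the planted
            # amplitude (segmentation may include a thin dimmer rim)
            assert table.means[i, 0, symbol - 1] >= 0.5 * 10 ** -0.3

    def test_mismatched_shapes_rejected(self, ideal_bundle):
        with pytest.raises(ValueError):
            imaging.extract_cell_table(ideal_bundle.stack, np.zeros((4, 4), int))


class TestPipeline:
    def test_ideal_identification_rate(self, ideal_bundle, ideal_run):
        matched = imaging.match_to_truth(ideal_run, ideal_bundle.cellmap,
                                         ideal_bundle.truth)
        rate = (matched["called_taxon"] == matched["taxon"]).mean()
        assert rate >= 0.95

    def test_single_round_dropout_corrected(self, ideal_bundle):
        stack = imaging.ImageStack(ideal_bundle.stack.images.copy(),
                                   ideal_bundle.stack.pixel_size)
        # silence all fluorescence in round 3 for one planted cell
        layout = ideal_bundle.cellmap
        row = layout.cells.iloc[0]
        rr, cc = layout.cell_pixels(row, dilate_px=2)
        stack.images[2, 1:, rr, cc] = 0.0
        result = imaging.run_pipeline(stack, ideal_bundle.codebook)
        matched = imaging.match_to_truth(result, layout, ideal_bundle.truth)
        rec = matched.iloc[0]
        assert rec["status"] == "identified"
        assert rec["called_taxon"] == rec["taxon"]
        lab = result.labels[int(row["y_um"] / stack.pixel_size),
                            int(row["x_um"] / stack.pixel_size)]
        i = result.table.cell_ids.index(lab)
        assert result.observed[i, 2] == 0           # dropout called in round 3
        assert result.decoded[i].corrected_bits == 1

    def test_five_zeroed_rounds_is_lost(self, ideal_bundle):
        stack = imaging.ImageStack(ideal_bundle.stack.images.copy(),
                                   ideal_bundle.stack.pixel_size)
        layout = ideal_bundle.cellmap
        row = layout.cells.iloc[1]
        rr, cc = layout.cell_pixels(row, dilate_px=2)
        for r in range(5):
            stack.images[r, 1:, rr, cc] = 0.0
        result = imaging.run_pipeline(stack, ideal_bundle.codebook)
        matched = imaging.match_to_truth(result, layout, ideal_bundle.truth)
        assert matched.iloc[1]["status"] == "lost"

    def test_pipeline_on_drifted_stack(self):
        bundle = fixtures.make_fixtures("drifted-stack", seed=5)
        result = imaging.run_pipeline(bundle.stack, bundle.codebook)
        matched = imaging.match_to_truth(result, bundle.cellmap, bundle.truth)
        rate = (matched["called_taxon"] == matched["taxon"]).mean()
        assert rate >= 0.95


class TestStackIO:
    def test_save_load_roundtrip(self, ideal_bundle, tmp_path):
        ideal_bundle.stack.save(tmp_path / "stack")
        loaded = imaging.ImageStack.load(tmp_path / "stack",
                                         pixel_size=ideal_bundle.stack.pixel_size)
        assert loaded.R == ideal_bundle.stack.R
        assert loaded.F == ideal_bundle.stack.F
        assert np.allclose(loaded.images,
                           ideal_bundle.stack.images.astype(np.float32))
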