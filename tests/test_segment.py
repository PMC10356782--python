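"""Nuclei detection, GMM marker classification, structure masks, phenotyping."""

import numpy as np
import pytest

from mxif3d import (
    MarkerCall,
    NucleusInstance,
    call_marker_on_nuclei,
    fit_gmm_two_class,
    multiscale_log,
    nuclei_from_labels,
    phenotype_cells,
    segment_nuclei,
    segment_structure_mask,
)
from mxif3d.preprocess import normalize_zmuv
from mxif3d.register import dice


def _gaussian_blob(shape, r0, c0, sigma, amp=1.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))


class TestMultiscaleLog:
    def test_constant_image_gives_zero_response(self):
        resp = multiscale_log(np.full((32, 32), 5.0), [2.0, 4.0])
        assert resp.shape == (2, 32, 32)
        # truncated Gaussian kernels leave a tiny residual on constants
        assert np.abs(resp).max() < 1e-2 * 5.0

    def test_strongest_response_at_matching_scale(self):
        img = _gaussian_blob((64, 64), 32, 32, sigma=4.0)
        resp = multiscale_log(img, [2.0, 4.0, 8.0])
        center = resp[:, 32, 32]
        assert np.argmax(center) == 1

    def test_linearity(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        a = 3.7
        assert np.allclose(
            multiscale_log(a * img, [3.0]), a * multiscale_log(img, [3.0])
        )

    def test_empty_scales_raise(self):
        with pytest.raises(ValueError, match="empty"):
            multiscale_log(np.zeros((8, 8)), [])


class TestSegmentNuclei:
    def test_blank_image_yields_no_nuclei(self):
        assert segment_nuclei(np.zeros((64, 64))) == []

    def test_recovers_separated_blobs_with_subpixel_centroids(self, rng):
        centers = []
        while len(centers) < 40:
            r, c = rng.uniform(15, 285, 2)
            if all((r - rr) ** 2 + (c - cc) ** 2 > 28**2 for rr, cc in centers):
                centers.append((r, c))
        img = np.zeros((300, 300))
        for r, c in centers:
            img += _gaussian_blob((300, 300), r, c, sigma=4.0)
        img += rng.normal(0, 0.03, img.shape)
        nuclei = segment_nuclei(normalize_zmuv(img))
        assert len(nuclei) == 40
        for r, c in centers:
            err = min(
                np.hypot(n.centroid_um[1] - r, n.centroid_um[0] - c) for n in nuclei
            )
            assert err < 1.0

    def test_split_flag_controls_overlapping_blob_count(self):
        img = (
            _gaussian_blob((64, 64), 32, 26, 4.0)
            + _gaussian_blob((64, 64), 32, 38, 4.0)
        )
        img = (img - img.mean()) / img.std()
        merged = segment_nuclei(img, split=False)
        split = segment_nuclei(img, split=True)
        assert len(merged) == 1
        assert len(split) == 2

    def test_area_gate_filters_instances(self):
        img = _gaussian_blob((64, 64), 32, 32, 4.0)
        img = (img - img.mean()) / img.std()
        assert segment_nuclei(img, min_area_px=1000) == []


class TestGMM:
    def test_recovers_known_mixture(self, rng):
        x = np.concatenate(
            [rng.normal(0, 1, 5000), rng.normal(6, 1, 5000)]
        ).reshape(100, 100)
        fit = fit_gmm_two_class(x, seed=1)
        assert abs(fit.means[0] - 0) < 0.2
        assert abs(fit.means[1] - 6) < 0.2
        # closed-form posterior for equal-weight N(0,1)/N(6,1) is logistic
        # with crossover at 3 and slope 6: p(3) = 0.5, p(3.5) ~ 0.95
        assert np.all(fit.prob_map[x > 3] > 0.5)
        assert np.all(fit.prob_map[x > 3.5] > 0.9)
        assert fit.is_monotone()

    def test_relabeling_symmetry(self, rng):
        x = np.concatenate(
            [rng.normal(0, 1, 2000), rng.normal(5, 1, 2000)]
        ).reshape(40, 100)
        f = fit_gmm_two_class(x, seed=1)
        fneg = fit_gmm_two_class(-x, seed=1)
        # EM from mirrored initializations converges to the mirrored optimum
        # up to the convergence tolerance
        assert np.allclose(fneg.prob_map, 1 - f.prob_map, atol=1e-3)

    def test_single_outlier_gets_positive_probability(self, rng):
        y = rng.normal(0, 1, (50, 50))
        y[10, 10] = 10 * np.abs(y).max()
        fit = fit_gmm_two_class(y, seed=2)
        assert fit.prob_map[10, 10] > 0.5

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            fit_gmm_two_class(np.full((10, 10), 1.0))

    def test_weights_sum_to_one_and_positive_class_has_larger_mean(self, rng):
        x = np.concatenate([rng.normal(0, 1, 3000), rng.normal(4, 1, 1000)])
        fit = fit_gmm_two_class(x.reshape(40, 100), seed=3)
        assert abs(fit.weights.sum() - 1) < 1e-9
        assert fit.means[1] > fit.means[0]


class TestMarkerCalling:
    def _nucleus(self, pixels):
        return NucleusInstance(
            id=0, retained_index=0, pixels=np.asarray(pixels),
            centroid_um=(0.0, 0.0), area_px=len(pixels),
        )

    def _fit_with_prob(self, prob):
        from mxif3d.segment import GMMFit

        return GMMFit(
            means=np.array([0.0, 1.0]), variances=np.array([1.0, 1.0]),
            weights=np.array([0.5, 0.5]), prob_map=prob, mask=None,
            log_likelihood=[0.0], converged=True, seed=0, _source=prob,
        )

    def test_uniform_probability_region(self):
        prob = np.full((20, 20), 0.95)
        nuc = self._nucleus([[r, c] for r in range(5, 10) for c in range(5, 10)])
        (call,) = call_marker_on_nuclei(self._fit_with_prob(prob), [nuc], "CD3")
        assert call.positive and call.overlap_fraction == 1.0
        assert call.p == pytest.approx(0.95)

    def test_low_overlap_rejects_regardless_of_mean(self):
        prob = np.zeros((20, 20))
        pixels = [[r, 5] for r in range(20)]
        prob[2, 5] = 1.0  # 1 of 20 pixels = 5% above threshold
        nuc = self._nucleus(pixels)
        (call,) = call_marker_on_nuclei(
            self._fit_with_prob(prob), [nuc], "CD3",
            prob_threshold=0.01, overlap_threshold=0.1,
        )
        assert not call.positive

    def test_out_of_bounds_nucleus_raises(self):
        prob = np.zeros((10, 10))
        nuc = self._nucleus([[9, 12]])
        with pytest.raises(ValueError, match="bounds"):
            call_marker_on_nuclei(self._fit_with_prob(prob), [nuc], "CD3")

    def test_phantom_sensitivity_specificity_at_snr6(self):
        from mxif3d import PhantomConfig, generate_phantom

        cfg = PhantomConfig(
            n_sections=1, image_shape=(512, 640), seed=5,
            cell_density_per_type={"Thelper": 120, "other": 180},
            vessel_count=0, affine_jitter=(0.0, 0.0), deform_max_px=0.0,
            marker_snr=6.0,
        )
        sections, truth = generate_phantom(cfg)
        img = normalize_zmuv(sections[0].channels["CD4"].astype(float))
        fit = fit_gmm_two_class(img, seed=5)
        nuclei = nuclei_from_labels(truth.footprint_labels(0), 1.0, 0)
        calls = call_marker_on_nuclei(fit, nuclei, "CD4")
        truth_pos = truth.marker_truth_for_section(0, "CD4")
        tp = sum(c.positive and truth_pos[c.nucleus_id] for c in calls)
        fn = sum(not c.positive and truth_pos[c.nucleus_id] for c in calls)
        tn = sum(not c.positive and not truth_pos[c.nucleus_id] for c in calls)
        fp = sum(c.positive and not truth_pos[c.nucleus_id] for c in calls)
        assert tp / (tp + fn) >= 0.93
        assert tn / (tn + fp) >= 0.85


class TestStructureMask:
    def test_bimodal_probabilities_threshold_exactly(self):
        from mxif3d.segment import GMMFit

        prob = np.full((40, 40), 0.05)
        prob[10:20, 10:30] = 0.9
        fit = GMMFit(
            means=np.array([0.0, 1.0]), variances=np.array([1.0, 1.0]),
            weights=np.array([0.5, 0.5]), prob_map=prob, mask=None,
            log_likelihood=[0.0], converged=True, seed=0, _source=prob,
        )
        mask = segment_structure_mask(fit)
        assert np.array_equal(mask, prob == 0.9)

    def test_background_guard_returns_empty_with_warning(self):
        from mxif3d.segment import GMMFit

        prob = np.random.default_rng(0).uniform(0, 0.15, (20, 20))
        fit = GMMFit(
            means=np.array([0.0, 1.0]), variances=np.array([1.0, 1.0]),
            weights=np.array([0.5, 0.5]), prob_map=prob, mask=None,
            log_likelihood=[0.0], converged=True, seed=0, _source=prob,
        )
        with pytest.warns(UserWarning, match="guard"):
            mask = segment_structure_mask(fit)
        assert not mask.any()

    def test_phantom_vessel_mask_dice(self):
        from mxif3d import PhantomConfig, generate_phantom
        from mxif3d.preprocess import compute_af_mask

        cfg = PhantomConfig(
            n_sections=2, seed=11, affine_jitter=(0, 0), deform_max_px=0,
            cell_density_per_type={"Thelper": 15, "epithelial": 10},
        )
        sections, truth = generate_phantom(cfg)
        sec = sections[0]
        mask = compute_af_mask(sec.channels["AF"].astype(float))
        img = normalize_zmuv(sec.channels["CD31"].astype(float), mask=mask)
        fit = fit_gmm_two_class(img, mask=mask, seed=0)
        smask = segment_structure_mask(fit)
        tube = np.zeros(cfg.image_shape, dtype=bool)
        vv = truth.vessel_voxels
        sel = vv[:, 0] == truth.section_map[0]
        tube[vv[sel, 1], vv[sel, 2]] = True
        assert dice(smask, tube) >= 0.8


class TestPhenotyping:
    def _records(self, positives, ps=None):
        ps = ps or {}
        markers = ["CD3", "CD4", "CD8", "FOXP3", "CD68", "CD31", "AE1"]
        nuc = NucleusInstance(
            id=0, retained_index=0, pixels=np.array([[0, 0]]),
            centroid_um=(0.0, 0.0), area_px=1,
        )
        calls = [
            MarkerCall(
                nucleus_id=0, marker=m, p=ps.get(m, 0.9 if m in positives else 0.1),
                overlap_fraction=1.0, positive=m in positives,
            )
            for m in markers
        ]
        return phenotype_cells([nuc], calls)

    @pytest.mark.parametrize(
        "positives,expected",
        [
            ({"CD3", "CD4", "FOXP3"}, "Treg"),
            ({"CD3", "CD4"}, "Thelper"),
            ({"CD3", "CD8"}, "Tkiller"),
            ({"CD68"}, "macrophage"),
            ({"CD31"}, "endothelial"),
            ({"CD31", "CD3", "CD4"}, "endothelial"),  # CD31 precedence
            ({"AE1"}, "epithelial"),
            (set(), "other"),
            ({"FOXP3"}, "other"),  # FOXP3 without CD3/CD4 is not a T reg
        ],
    )
    def test_phenotype_table(self, positives, expected):
        (rec,) = self._records(positives)
        assert rec.phenotype == expected
        assert not rec.ambiguous

    def test_double_positive_resolved_by_probability_with_flag(self):
        (rec,) = self._records(
            {"CD3", "CD4", "CD8"}, ps={"CD4": 0.6, "CD8": 0.9}
        )
        assert rec.phenotype == "Tkiller"
        assert rec.ambiguous
        (rec2,) = self._records(
            {"CD3", "CD4", "CD8"}, ps={"CD4": 0.9, "CD8": 0.6}
        )
        assert rec2.phenotype == "Thelper"
        assert rec2.ambiguous

    def test_missing_required_marker_raises(self):
        nuc = NucleusInstance(
            id=0, retained_index=0, pixels=np.array([[0, 0]]),
            centroid_um=(0.0, 0.0), area_px=1,
        )
        calls = [
            MarkerCall(nucleus_id=0, marker="CD3", p=0.9, overlap_fraction=1.0, positive=True)
        ]
        with pytest.raises(ValueError, match="missing"):
            phenotype_cells([nuc], calls)

    def test_phantom_tcell_proportions_recovered(self):
        """A stack configured with the reference 89/2/9 T-subset split
        recovers those proportions from truth marker calls."""
        from mxif3d import PhantomConfig, generate_phantom

        cfg = PhantomConfig(
            n_sections=6, image_shape=(320, 400), seed=17,
            cell_density_per_type={"Thelper": 89, "Tkiller": 2, "Treg": 9},
            vessel_count=0, affine_jitter=(0.0, 0.0), deform_max_px=0.0,
        )
        sections, truth = generate_phantom(cfg)
        counts = {"Thelper": 0, "Tkiller": 0, "Treg": 0}
        for sec in sections:
            ridx = sec.retained_index
            nuclei = nuclei_from_labels(truth.footprint_labels(ridx), 1.0, ridx)
            calls = []
            for marker in ("CD3", "CD4", "CD8", "FOXP3", "CD68", "CD31"):
                img = normalize_zmuv(sec.channels[marker].astype(float))
                fit = fit_gmm_two_class(img, seed=cfg.seed)
                calls.extend(call_marker_on_nuclei(fit, nuclei, marker))
            for rec in phenotype_cells(nuclei, calls):
                if rec.phenotype in counts:
                    counts[rec.phenotype] += 1
        total = sum(counts.values())
        assert abs(counts["Thelper"] / total - 0.89) < 0.05
        assert abs(counts["Tkiller"] / total - 0.02) < 0.05
        assert abs(counts["Treg"] / total - 0.09) < 0.05
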