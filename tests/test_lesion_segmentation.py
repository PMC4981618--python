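import numpy as np
import pytest
from scipy.stats import norm

import wmlseg as w
from wmlseg import (
    BinaryMask,
    GMPeakEstimate,
    SegmentationParams,
    Volume,
    compute_threshold,
    detect_candidates,
    filter_by_neighborhood,
    filter_by_size,
    label_components,
    neighborhood_wm_ratio,
    segment,
)
from wmlseg.errors import (
    CoregistrationError,
    DegenerateInputError,
    EdgePeakError,
    InputError,
)
from wmlseg.lesion_segmentation import (
    FWHM_PER_SIGMA,
    STATUS_CANDIDATE,
    STATUS_KEPT,
    STATUS_REMOVED_NEIGHBORHOOD,
    STATUS_REMOVED_SIZE,
    estimate_gm_peak,
    estimate_peak_from_samples,
)
from wmlseg.tissue_model import CSF, GM, WM

from conftest import make_labels


class TestGMPeakEstimate:
    def test_sigma_derived_from_fwhm(self):
        p = GMPeakEstimate(mu=100.0, fwhm=23.54820045)
        assert p.sigma == pytest.approx(10.0, abs=1e-6)
        assert abs(p.sigma - p.fwhm / 2.354820045) < 1e-9

    def test_invalid(self):
        with pytest.raises(InputError):
            GMPeakEstimate(mu=np.nan, fwhm=1.0)
        with pytest.raises(InputError):
            GMPeakEstimate(mu=0.0, fwhm=-1.0)
        with pytest.raises(InputError):
            GMPeakEstimate(mu=0.0, fwhm=2.0, sigma=5.0)


class TestPeakEstimation:
    def test_gaussian_sample_recovery(self):
        rng = np.random.default_rng(0)
        p = estimate_peak_from_samples(rng.normal(100.0, 10.0, 100000))
        assert p.mu == pytest.approx(100.0, abs=0.5)
        assert p.sigma == pytest.approx(10.0, abs=0.5)

    def test_exact_pdf_closed_form(self):
        # noiseless histogram of an exact Gaussian: FWHM = 2 sqrt(2 ln 2) sigma
        centers = np.linspace(50.0, 150.0, 2001)
        weights = np.round(norm.pdf(centers, 100.0, 10.0) * 1e7).astype(int)
        samples = np.repeat(centers, weights)
        p = estimate_peak_from_samples(samples, bin_rule=400)
        assert p.sigma == pytest.approx(10.0, rel=1e-3)

    def test_bimodal_dominant_mode(self):
        rng = np.random.default_rng(1)
        x = np.concatenate(
            [rng.normal(100.0, 10.0, 90000), rng.normal(160.0, 5.0, 10000)]
        )
        p = estimate_peak_from_samples(x)
        assert abs(p.mu - 100.0) < 2.0

    def test_edge_peak_error(self):
        rng = np.random.default_rng(2)
        x = np.abs(rng.normal(0.0, 1.0, 50000)) + 100.0  # mode at the left edge
        with pytest.raises(EdgePeakError):
            estimate_peak_from_samples(x)

    def test_degenerate_samples(self):
        with pytest.raises(DegenerateInputError):
            estimate_peak_from_samples(np.full(5000, 7.0))

    def test_small_gm_mask_warns(self, rng):
        vol = Volume(rng.normal(100.0, 10.0, (8, 8, 8)))
        mask = BinaryMask(np.ones((8, 8, 8), np.uint8))
        with pytest.warns(RuntimeWarning, match="512 voxels"):
            estimate_gm_peak(vol, mask)

    def test_empty_gm_mask(self, small_volume):
        with pytest.raises(InputError):
            estimate_gm_peak(small_volume, BinaryMask(np.zeros((8, 8, 8), np.uint8)))


class TestThreshold:
    def test_direct_substitution(self):
        p = GMPeakEstimate(mu=100.0, fwhm=10.0 * FWHM_PER_SIGMA)
        assert compute_threshold(p, 2.5) == pytest.approx(125.0)

    def test_alpha_to_zero_limit(self):
        p = GMPeakEstimate(mu=100.0, fwhm=10.0 * FWHM_PER_SIGMA)
        assert compute_threshold(p, 1e-12) == pytest.approx(100.0, abs=1e-9)

    def test_default_alpha_covers_more_than_98pct(self):
        # fraction of a Normal(mu, sigma^2) below mu + 2.5 sigma
        assert norm.cdf(2.5) > 0.98

    def test_invalid_alpha(self):
        p = GMPeakEstimate(mu=0.0, fwhm=1.0)
        with pytest.raises(InputError):
            compute_threshold(p, 0.0)


class TestDetectCandidates:
    def _setup(self):
        flair = np.full((8, 8, 8), 100.0)
        brain = BinaryMask(np.ones((8, 8, 8), np.uint8))
        return flair, brain

    def test_all_below_threshold(self):
        flair, brain = self._setup()
        cand = detect_candidates(Volume(flair), 125.0, brain)
        assert cand.n_voxels == 0

    def test_exclusion_removes_hyperintensity(self):
        flair, brain = self._setup()
        flair[2, 2, 2] = 200.0
        excl = np.zeros((8, 8, 8), np.uint8)
        excl[2, 2, 2] = 1
        cand = detect_candidates(Volume(flair), 125.0, brain, BinaryMask(excl))
        assert cand.n_voxels == 0

    def test_blob_exactly_detected(self):
        flair, brain = self._setup()
        blob = [(3, 3, 3), (3, 3, 4), (3, 4, 3), (4, 3, 3), (3, 4, 4),
                (4, 3, 4), (4, 4, 3), (4, 4, 4), (5, 4, 4), (4, 5, 4)]
        for v in blob:
            flair[v] = 140.0
        cand = detect_candidates(Volume(flair), 125.0, brain)
        assert cand.n_voxels == 10
        assert all(cand.data[v] == 1 for v in blob)

    def test_threshold_is_inclusive(self):
        flair, brain = self._setup()
        flair[1, 1, 1] = 125.0
        cand = detect_candidates(Volume(flair), 125.0, brain)
        assert cand.data[1, 1, 1] == 1

    def test_grid_mismatch(self):
        flair, _ = self._setup()
        brain = BinaryMask(np.ones((9, 9, 9), np.uint8))
        with pytest.raises(CoregistrationError):
            detect_candidates(Volume(flair), 125.0, brain)


class TestLabelComponents:
    def test_two_separated_blobs(self):
        m = np.zeros((10, 10, 10), np.uint8)
        m[1:3, 1:3, 1:3] = 1
        m[7:9, 7:9, 7:9] = 1
        lesions = label_components(BinaryMask(m))
        assert len(lesions.components) == 2
        assert [c.id for c in lesions.components] == [1, 2]

    def test_corner_touch_connectivity(self):
        m = np.zeros((4, 4, 4), np.uint8)
        m[1, 1, 1] = 1
        m[2, 2, 2] = 1  # touches only at a corner
        assert len(label_components(BinaryMask(m), 26).components) == 1
        assert len(label_components(BinaryMask(m), 6).components) == 2

    def test_empty_mask(self):
        lesions = label_components(BinaryMask(np.zeros((4, 4, 4), np.uint8)))
        assert lesions.components == []

    def test_volume_equals_count_times_voxel_volume(self):
        m = np.zeros((6, 6, 6), np.uint8)
        m[1:4, 1, 1] = 1
        lesions = label_components(BinaryMask(m, (1.0, 1.2, 0.5)))
        c = lesions.components[0]
        assert c.voxel_count == 3
        assert abs(c.volume_mm3 - 3 * 1.0 * 1.2 * 0.5) < 1e-9

    def test_all_statuses_candidate(self):
        m = np.zeros((6, 6, 6), np.uint8)
        m[1:3, 1, 1] = 1
        lesions = label_components(BinaryMask(m))
        assert all(c.status == STATUS_CANDIDATE for c in lesions.components)

    def test_bad_connectivity(self):
        with pytest.raises(InputError):
            label_components(BinaryMask(np.zeros((4, 4, 4), np.uint8)), 10)


def _line_component(n, shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0)):
    m = np.zeros(shape, np.uint8)
    m[2 : 2 + n, 2, 2] = 1
    return label_components(BinaryMask(m, spacing))


class TestFilterBySize:
    @pytest.mark.parametrize(
        "n,expected",
        [(2, STATUS_REMOVED_SIZE), (3, STATUS_CANDIDATE),
         (4, STATUS_CANDIDATE), (5, STATUS_CANDIDATE)],
    )
    def test_boundary_semantics_at_unit_voxels(self, n, expected):
        lesions = filter_by_size(_line_component(n), 3.0)
        assert lesions.components[0].status == expected

    def test_anisotropic_voxels(self):
        # 2 voxels x 2 mm^3 each = 4 mm^3 -> survives
        lesions = filter_by_size(_line_component(2, spacing=(2.0, 1.0, 1.0)), 3.0)
        assert lesions.components[0].status == STATUS_CANDIDATE


class TestNeighborhoodRatio:
    def _single_voxel_setup(self, shell_labels):
        m = np.zeros((5, 5, 5), np.uint8)
        m[2, 2, 2] = 1
        lesions = label_components(BinaryMask(m))
        tissue = np.zeros((5, 5, 5), np.uint8)
        i = 0
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if (di, dj, dk) == (0, 0, 0):
                        continue
                    tissue[2 + di, 2 + dj, 2 + dk] = shell_labels[i]
                    i += 1
        return lesions, make_labels(tissue)

    def test_all_wm_shell(self):
        lesions, labels = self._single_voxel_setup([WM] * 26)
        assert neighborhood_wm_ratio(lesions, 1, labels) == pytest.approx(1.0)

    def test_20wm_6gm(self):
        lesions, labels = self._single_voxel_setup([WM] * 20 + [GM] * 6)
        assert neighborhood_wm_ratio(lesions, 1, labels) == pytest.approx(20.0 / 26.0)

    def test_background_excluded_from_denominator(self):
        lesions, labels = self._single_voxel_setup([WM] * 10 + [0] * 16)
        assert neighborhood_wm_ratio(lesions, 1, labels) == pytest.approx(1.0)

    def test_empty_denominator_is_zero(self):
        lesions, labels = self._single_voxel_setup([0] * 26)
        assert neighborhood_wm_ratio(lesions, 1, labels) == 0.0

    def test_majority_gm_shell_below_070(self):
        lesions, labels = self._single_voxel_setup([GM] * 14 + [WM] * 12)
        assert neighborhood_wm_ratio(lesions, 1, labels) < 0.7

    def test_unknown_component(self):
        lesions, labels = self._single_voxel_setup([WM] * 26)
        with pytest.raises(InputError):
            neighborhood_wm_ratio(lesions, 99, labels)


class TestFilterByNeighborhood:
    @pytest.mark.parametrize(
        "n_wm,expected",
        [(26, STATUS_KEPT), (19, STATUS_KEPT), (13, STATUS_REMOVED_NEIGHBORHOOD)],
    )
    def test_lambda_rule(self, n_wm, expected):
        # ratios 1.0, 0.7307..., 0.5 against lambda = 0.70
        m = np.zeros((5, 5, 5), np.uint8)
        m[2, 2, 2] = 1
        lesions = label_components(BinaryMask(m))
        tissue = np.full((5, 5, 5), GM, np.uint8)
        count = 0
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if (di, dj, dk) == (0, 0, 0):
                        continue
                    if count < n_wm:
                        tissue[2 + di, 2 + dj, 2 + dk] = WM
                    count += 1
        filter_by_neighborhood(lesions, make_labels(tissue), 0.70)
        c = lesions.components[0]
        if c.status == STATUS_CANDIDATE:
            c.status = STATUS_KEPT
        assert c.status == expected

    def test_exact_boundary_kept(self):
        # ratio exactly 0.70: 14 WM / 20 tissue, 6 shell voxels background
        m = np.zeros((5, 5, 5), np.uint8)
        m[2, 2, 2] = 1
        lesions = label_components(BinaryMask(m))
        tissue = np.zeros((5, 5, 5), np.uint8)
        shell = [(2 + di, 2 + dj, 2 + dk)
                 for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
                 if (di, dj, dk) != (0, 0, 0)]
        for v in shell[:14]:
            tissue[v] = WM
        for v in shell[14:20]:
            tissue[v] = GM
        filter_by_neighborhood(lesions, make_labels(tissue), 0.70)
        assert lesions.components[0].wm_ratio == pytest.approx(0.70)
        assert lesions.components[0].status == STATUS_CANDIDATE  # survives


@pytest.fixture(scope="module")
def clean_segmentation(clean_case):
    mask, lesions, report = segment(
        clean_case.t1, clean_case.flair, exclusion=clean_case.pf_mask, seed=1
    )
    return mask, lesions, report


class TestSegmentPipeline:
    def test_clean_phantom_perfect_recovery(self, clean_case, clean_segmentation):
        mask, lesions, report = clean_segmentation
        rep = w.evaluate_case(mask, clean_case.lesion_gt)
        assert rep.detection.tpr == 1.0
        assert rep.detection.ppv == 1.0
        assert rep.dsc >= 0.99

    def test_report_contents(self, clean_segmentation):
        _, _, report = clean_segmentation
        for key in ("mu", "sigma", "threshold", "stage_counts", "params", "seed"):
            assert key in report
        assert report["params"]["alpha"] == 2.5
        assert report["params"]["lambda"] == 0.70

    def test_final_mask_subset_chain(self, clean_case, clean_segmentation):
        mask, _, report = clean_segmentation
        from wmlseg.lesion_segmentation import build_context

        ctx = build_context(
            clean_case.t1, clean_case.flair, exclusion=clean_case.pf_mask, seed=1
        )
        cand = detect_candidates(
            ctx.flair, report["threshold"], ctx.brain, ctx.exclusion
        )
        assert (mask.as_bool() & ~cand.as_bool()).sum() == 0
        assert (cand.as_bool() & ~ctx.brain.as_bool()).sum() == 0

    def test_kept_components_satisfy_all_rules(self, clean_segmentation):
        _, lesions, _ = clean_segmentation
        for c in lesions.by_status(STATUS_KEPT):
            assert c.volume_mm3 >= 3.0
            assert c.wm_ratio is None or c.wm_ratio >= 0.70

    def test_pf_distractor_never_a_candidate(self):
        spec = w.PhantomSpec(
            seed=11,
            artifacts=[w.ArtifactSpec((31.5, 31.5, 9.0), 15, 6.0, "pf")],
        )
        case = w.generate_phantom(spec)
        assert case.pf_mask.data[31, 31, 9] == 1
        from wmlseg.lesion_segmentation import build_context, run_from_context

        ctx = build_context(case.t1, case.flair, exclusion=case.pf_mask, seed=1)
        cand = detect_candidates(
            ctx.flair,
            compute_threshold(ctx.gm_peak, 2.5),
            ctx.brain,
            ctx.exclusion,
        )
        assert cand.data[case.pf_mask.as_bool()].sum() == 0
        mask, _, _ = run_from_context(ctx)
        rep = w.evaluate_case(mask, case.lesion_gt)
        assert rep.detection.tpr == 1.0 and rep.detection.ppv == 1.0

    def test_two_voxel_hyperintensity_removed_by_size(self, clean_case):
        spec = w.PhantomSpec(
            seed=5,
            flair_noise_sd=0.0,
            t1_noise_sd=0.0,
            artifacts=[w.ArtifactSpec((31.5, 31.5, 31.5), 2, 6.0, "wm")],
        )
        case = w.generate_phantom(spec)
        mask, lesions, report = segment(
            case.t1, case.flair, exclusion=case.pf_mask, seed=1
        )
        removed = lesions.by_status(STATUS_REMOVED_SIZE)
        assert any(c.voxel_count == 2 for c in removed)
        assert mask.data[31, 31, 31] == 0
        rep = w.evaluate_case(mask, case.lesion_gt)
        assert rep.detection.tpr == 1.0 and rep.detection.ppv == 1.0

    def test_determinism(self, default_case):
        m1, _, r1 = segment(default_case.t1, default_case.flair, seed=42)
        m2, _, r2 = segment(default_case.t1, default_case.flair, seed=42)
        np.testing.assert_array_equal(m1.data, m2.data)
        assert r1 == r2

    def test_monotonicity_in_alpha(self, default_case):
        from wmlseg.lesion_segmentation import build_context

        ctx = build_context(default_case.t1, default_case.flair, seed=1)
        prev = None
        for alpha in (1.0, 1.5, 2.0, 2.5, 3.0):
            cand = detect_candidates(
                ctx.flair, compute_threshold(ctx.gm_peak, alpha), ctx.brain
            )
            if prev is not None:
                assert (cand.as_bool() & ~prev).sum() == 0
            prev = cand.as_bool()

    def test_monotonicity_in_lambda(self, default_case):
        from wmlseg.lesion_segmentation import build_context, run_from_context

        ctx = build_context(default_case.t1, default_case.flair, seed=1)
        prev_ids = None
        for lam in (0.0, 0.3, 0.7, 0.9, 1.0):
            _, lesions, _ = run_from_context(
                ctx, SegmentationParams(alpha=2.5, lam=lam)
            )
            ids = {c.id for c in lesions.by_status(STATUS_KEPT)}
            if prev_ids is not None:
                assert ids <= prev_ids
            prev_ids = ids

    def test_stage_error_names_stage(self):
        bad_t1 = Volume(np.zeros((32, 32, 32)))  # degenerate: one value
        flair = Volume(np.zeros((32, 32, 32)))
        from wmlseg.errors import PipelineError

        with pytest.raises(PipelineError) as exc:
            segment(bad_t1, flair)
        assert exc.value.stage is not None


class TestSegmentationParams:
    def test_defaults(self):
        p = SegmentationParams()
        assert (p.alpha, p.lam, p.min_volume_mm3) == (2.5, 0.70, 3.0)

    @pytest.mark.parametrize(
        "kwargs", [{"alpha": 0.0}, {"lam": -0.1}, {"lam": 1.5}, {"min_volume_mm3": 0.0}]
    )
    def test_invalid(self, kwargs):
        with pytest.raises(InputError):
            SegmentationParams(**kwargs)
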