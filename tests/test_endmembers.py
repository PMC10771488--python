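"""Elementary-spectrum determination workflow."""

import numpy as np
import pytest

from fossilfluor import (
    CandidateSpectrum,
    ElementarySpectrum,
    EndmemberExtractor,
    EndmemberMatrix,
    ExcitationSeries,
    NoiseParams,
    PolygonROI,
    SpectralStack,
    SyntheticScene,
    apply_excitation_rule,
    decompose_roi_spectrum,
    default_axis,
    excitation_profile,
    finalize_endmembers,
    group_candidates,
    make_amber_spectrum,
    make_gaussian_spectrum,
    make_scene,
    make_shg_spectrum,
    render_stack,
    roi_mean_spectrum,
    substrate_spectrum,
)
from fossilfluor.errors import CollinearityError


def rect(r0, c0, r1, c1, label=""):
    return PolygonROI([(r0, c0), (r0, c1), (r1, c1), (r1, c0)], label=label)


def cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestSubstrateSpectrum:
    def test_constant_stack_gives_flat_unit_spectrum(self, axis5):
        stack = SpectralStack(np.full((8, 8, 5), 4.0), axis=axis5, excitation_nm=760.0)
        rois = [rect(i, 0, i + 1, 8, f"r{i}") for i in range(5)]
        sub = substrate_spectrum([stack], rois)
        assert np.allclose(sub.values, 1.0)

    def test_roi_level_not_pixel_level_weighting(self, axis5):
        # big ROI with spectrum u, small ROI with spectrum v: output ∝ (u+v)/2
        arr = np.zeros((8, 8, 5))
        u, v = np.array([4, 2, 1, 0.5, 0.1]), np.array([0.1, 0.5, 1, 2, 4.0])
        arr[:4, :, :] = u  # 32 pixels
        arr[6:7, :2, :] = v  # 2 pixels
        stack = SpectralStack(arr, axis=axis5, excitation_nm=760.0)
        rois = [rect(0, 0, 4, 8, "big"), rect(6, 0, 7, 2, "small")]
        with pytest.warns(UserWarning, match="substrate ROI"):
            sub = substrate_spectrum([stack], rois)
        expected = (u + v) / 2
        assert np.allclose(sub.values, expected / expected.max(), atol=1e-12)
        pixel_weighted = (32 * u + 2 * v) / 34
        assert not np.allclose(sub.values, pixel_weighted / pixel_weighted.max())

    def test_recovers_matrix_spectrum_from_scene(self):
        scene = make_scene("matrix_only", shape=(32, 32), seed=1)
        stack = render_stack(scene)
        rois = [scene.reference_rois[f"substrate_{i}"] for i in range(1, 6)]
        sub = substrate_spectrum([stack], rois)
        truth = scene.endmembers["matrix"].values
        assert cosine(sub.values, truth) > 0.999


class TestDecomposeRoiSpectrum:
    axis = default_axis()

    def substrate(self):
        return make_amber_spectrum(760.0, self.axis, "substrate")

    def test_pure_substrate_keeps_zero_gaussians(self):
        sub = self.substrate()
        a0, comps, cand = decompose_roi_spectrum(2.0 * sub.values, sub)
        assert a0 == pytest.approx(2.0, rel=1e-9)
        assert comps == []
        assert np.allclose(cand.values, 0.0, atol=1e-9)

    def test_single_gaussian_recovery(self):
        sub = self.substrate()
        g = 0.8 * make_gaussian_spectrum(630, 15, self.axis).values
        a0, comps, cand = decompose_roi_spectrum(sub.values + g, sub)
        assert len(comps) == 1
        assert comps[0].mu_nm == pytest.approx(630, abs=1.0)
        assert comps[0].sigma_nm == pytest.approx(15, rel=0.10)
        assert a0 == pytest.approx(1.0, rel=1e-3)

    def test_two_separated_gaussians_recovered(self):
        sub = self.substrate()
        composite = (
            1.5 * sub.values
            + 0.9 * make_gaussian_spectrum(560, 25, self.axis).values
            + 0.7 * make_gaussian_spectrum(650, 25, self.axis).values
        )
        a0, comps, cand = decompose_roi_spectrum(composite, sub)
        assert len(comps) == 2
        peaks = sorted(c.mu_nm for c in comps)
        assert peaks[0] == pytest.approx(560, abs=2.0)
        assert peaks[1] == pytest.approx(650, abs=2.0)

    def test_candidate_is_substrate_free_and_clipped(self):
        sub = self.substrate()
        g = 0.5 * make_gaussian_spectrum(600, 20, self.axis).values
        _, _, cand = decompose_roi_spectrum(sub.values + g, sub)
        assert np.all(cand.values >= 0)
        assert cand.peak_nm == pytest.approx(600, abs=1.0)
        assert cosine(cand.values, g) > 0.999


class TestGroupCandidates:
    def fake(self, peak, fwhm):
        axis = default_axis()
        values = make_gaussian_spectrum(peak, fwhm / 2.3548, axis).values
        return CandidateSpectrum(values=values, axis=axis, peak_nm=peak, fwhm_nm=fwhm)

    def test_single_candidate_single_group(self):
        groups = group_candidates([self.fake(600, 50)])
        assert len(groups) == 1

    def test_linkage_matches_brute_force(self):
        cands = [self.fake(559, 60), self.fake(561, 62), self.fake(649, 60)]
        groups = group_candidates(cands, peak_tol_nm=10)
        assert [sorted(c.peak_nm for c in g) for g in groups] == [[559, 561], [649]]

    def test_width_dissimilarity_blocks_linkage(self):
        groups = group_candidates([self.fake(600, 20), self.fake(602, 80)])
        assert len(groups) == 2

    def test_duplicates_collapse_to_one_group(self):
        c = self.fake(600, 50)
        assert len(group_candidates([c, c, c, c])) == 1

    def test_permutation_invariant_contents(self):
        cands = [self.fake(p, w) for p, w in [(550, 40), (556, 44), (620, 50), (700, 30)]]
        g1 = group_candidates(cands)
        g2 = group_candidates(cands[::-1])
        key = lambda groups: sorted(tuple(sorted(c.peak_nm for c in g)) for g in groups)
        assert key(g1) == key(g2)


class TestFinalizeEndmembers:
    def test_groups_become_normalized_columns(self):
        axis = default_axis()
        sub = make_amber_spectrum(760, axis, "substrate")
        g560 = [
            CandidateSpectrum(
                values=a * make_gaussian_spectrum(560, 25, axis).values,
                axis=axis, peak_nm=560, fwhm_nm=59,
            )
            for a in (0.5, 0.8)
        ]
        g650 = [
            CandidateSpectrum(
                values=0.6 * make_gaussian_spectrum(650, 25, axis).values,
                axis=axis, peak_nm=650, fwhm_nm=59,
            )
        ]
        em = finalize_endmembers([g560, g650], sub, ["Amber", "Lignin", "Chl"])
        assert em.names == ["Amber", "Lignin", "Chl"]
        for s in em.spectra:
            assert s.values.max() == pytest.approx(1.0, abs=1e-9)
        assert em["Lignin"].peak_nm == 560

    def test_proportional_groups_raise_collinearity(self):
        axis = default_axis()
        sub = make_amber_spectrum(760, axis, "substrate")
        c1 = CandidateSpectrum(
            values=make_gaussian_spectrum(600, 25, axis).values,
            axis=axis, peak_nm=600, fwhm_nm=59,
        )
        c2 = CandidateSpectrum(
            values=0.5 * make_gaussian_spectrum(600, 25, axis).values,
            axis=axis, peak_nm=600, fwhm_nm=59,
        )
        with pytest.raises(CollinearityError):
            finalize_endmembers([[c1], [c2]], sub, ["s", "a", "b"])

    def test_name_count_must_match(self):
        axis = default_axis()
        sub = make_amber_spectrum(760, axis, "substrate")
        with pytest.raises(ValueError, match="names"):
            finalize_endmembers([], sub, ["s", "extra"])


class TestExcitationRule:
    def build(self):
        axis = default_axis()
        return EndmemberMatrix(
            [
                make_gaussian_spectrum(550, 30, axis, "S550"),
                make_shg_spectrum(920, axis),
            ]
        )

    def test_zeroed_at_non_shg_excitation(self):
        em = apply_excitation_rule(self.build(), 760.0)
        assert em.zeroed_names == ["SHG"]

    def test_unchanged_at_shg_excitation(self):
        em = self.build()
        assert apply_excitation_rule(em, 920.0) is em

    def test_unchanged_without_shg_column(self):
        axis = default_axis()
        em = EndmemberMatrix([make_gaussian_spectrum(550, 30, axis, "S550")])
        assert apply_excitation_rule(em, 760.0) is em

    def test_idempotent(self):
        once = apply_excitation_rule(self.build(), 760.0)
        twice = apply_excitation_rule(once, 760.0)
        assert twice is once


class TestExcitationProfile:
    axis = default_axis()

    def series_with_weights(self, weights, seed=3):
        em = EndmemberMatrix(
            [
                make_gaussian_spectrum(550, 30, self.axis, "bg"),
                make_gaussian_spectrum(630, 25, self.axis, "target"),
            ]
        )
        stacks = []
        for exc, w in zip((760.0, 800.0, 840.0), weights):
            fields = {"bg": np.full((16, 16), 0.5), "target": np.full((16, 16), w)}
            scene = SyntheticScene(
                true_abundances=fields, endmembers=em,
                noise=NoiseParams(), seed=seed, scenario="matrix_only",
                excitation_nm=exc,
            )
            stacks.append(render_stack(scene))
        mapping = {s.excitation_nm: em for s in stacks}
        return ExcitationSeries(stacks), mapping

    def test_single_excitation_equals_map_mean(self):
        series, mapping = self.series_with_weights([0.8])
        roi = rect(2, 2, 14, 14, "roi")
        table = excitation_profile(
            ExcitationSeries(series.stacks[:1]), mapping, roi
        )
        assert len(table) == 1
        from fossilfluor import unmix_stack

        maps = unmix_stack(series.stacks[0], mapping[760.0])
        mask = roi.mask(series.stacks[0].shape)
        assert table.loc[760.0, "target"] == pytest.approx(
            maps["target"][mask].mean(), rel=1e-12
        )

    def test_brightness_doubling_is_tracked(self):
        series, mapping = self.series_with_weights([0.25, 0.5, 1.0])
        roi = rect(2, 2, 14, 14, "roi")
        table = excitation_profile(series, mapping, roi)
        prof = table["target"] / 1e4
        assert prof.loc[800.0] == pytest.approx(2 * prof.loc[760.0], rel=0.05)
        assert prof.loc[840.0] == pytest.approx(2 * prof.loc[800.0], rel=0.05)

    def test_distinct_excitation_weights_give_distinct_profiles(self):
        s1, m1 = self.series_with_weights([0.25, 0.5, 1.0])
        s2, m2 = self.series_with_weights([1.0, 0.5, 0.25])
        roi = rect(2, 2, 14, 14, "roi")
        p1 = excitation_profile(s1, m1, roi)["target"]
        p2 = excitation_profile(s2, m2, roi)["target"]
        assert np.corrcoef(p1, p2)[0, 1] < 0.9


class TestEndmemberExtractorEstimator:
    def test_full_workflow_on_synthetic_amber(self):
        scene = make_scene(
            "amber_inclusion", shape=(64, 64), seed=11, noise=NoiseParams(enabled=False)
        )
        stack = render_stack(scene)
        rois = scene.reference_rois
        ext = EndmemberExtractor().fit(
            [stack],
            substrate_rois=[rois[f"substrate_{i}"] for i in range(1, 6)],
            candidate_rois=[rois["lignin_only"], rois["chl_only"]],
            group_names=["Lignin", "Chl"],
        )
        em = ext.endmembers_
        assert em.names == ["substrate", "Lignin", "Chl"]
        axis = scene.endmembers.axis
        for name, mu in (("Lignin", 560.0), ("Chl", 650.0)):
            assert em[name].peak_nm == pytest.approx(mu, abs=2.0)
            truth = make_gaussian_spectrum(mu, 30, axis).values
            assert cosine(em[name].values, truth) > 0.99

    def test_get_params_roundtrip(self):
        ext = EndmemberExtractor(peak_tol_nm=7.5)
        assert ext.get_params()["peak_tol_nm"] == 7.5
        ext.set_params(max_gaussians=2)
        assert ext.max_gaussians == 2
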