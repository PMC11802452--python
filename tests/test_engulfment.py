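"""Engulfment scene generator and 3D quantification pipeline."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from neuroquant.engulfment import (
    LABEL_ASTRO,
    LABEL_PUNCTA,
    CleanupParams,
    PixelClassifier,
    VoxelStack,
    analyze_stack,
    classify,
    clean_astro_mask,
    extract_puncta,
    mesh_surface,
    preprocess,
    score_engulfment,
)
from neuroquant.synth.engulfment import (
    EngulfmentSceneSpec,
    PunctumPlan,
    generate_engulfment_stack,
    random_engulfment_spec,
)

VS = (0.12, 0.045, 0.045)


def _simple_scene(snr=None, seed=0, **kw):
    """A single tube with one punctum of each class, in a small stack."""
    # tube volume ~18 um^3: stays above the 10 um^3 astro threshold even
    # after the one-voxel cleanup erosion
    defaults = dict(
        stack_shape=(24, 80, 80),
        arbor_segments=(((1.44, 1.8, 0.4), (1.44, 1.8, 3.2), 1.15),),
        puncta_plan=(
            PunctumPlan((1.44, 1.8, 1.2), 0.3, "inside"),
            PunctumPlan((1.44, 2.95, 2.4), 0.25, "straddling"),
            PunctumPlan((0.5, 0.5, 1.6), 0.3, "outside"),
        ),
        snr=snr,
        seed=seed,
    )
    defaults.update(kw)
    return generate_engulfment_stack(EngulfmentSceneSpec(**defaults))


# ------------------------------------------------------------ generator

def test_planted_classes_have_expected_ground_truth_fractions():
    scene = _simple_scene()
    by_class = {t.plan.klass: t for t in scene.truth}
    assert by_class["inside"].engulfment_fraction == 1.0
    assert by_class["outside"].engulfment_fraction == 0.0
    assert 0.0 < by_class["straddling"].engulfment_fraction < 1.0


def test_surface_centered_punctum_straddles_about_half():
    """A punctum centered exactly on the tube surface is ~50% inside."""
    scene = _simple_scene()
    straddler = [t for t in scene.truth if t.plan.klass == "straddling"][0]
    assert straddler.engulfment_fraction == pytest.approx(0.5, abs=0.1)


def test_subvoxel_radius_warns_but_renders():
    with pytest.warns(UserWarning, match="below the voxel size"):
        scene = _simple_scene(
            puncta_plan=(PunctumPlan((1.44, 0.45, 1.6), 0.05, "outside"),)
        )
    assert scene.truth[0].voxel_count >= 1


def test_inconsistent_plans_are_rejected():
    with pytest.raises(ValueError, match="outside the arbor"):
        _simple_scene(puncta_plan=(PunctumPlan((1.44, 2.75, 1.2), 0.3, "inside"),))
    with pytest.raises(ValueError, match="intersects the arbor"):
        _simple_scene(puncta_plan=(PunctumPlan((1.44, 1.8, 1.2), 0.3, "outside"),))
    with pytest.raises(ValueError, match="distractor"):
        _simple_scene(distractors=(((1.44, 1.8, 1.6), 0.5),))


def test_generator_is_deterministic():
    a = generate_engulfment_stack(random_engulfment_spec(5, snr=5.0))
    b = generate_engulfment_stack(random_engulfment_spec(5, snr=5.0))
    assert np.array_equal(a.stack.astro, b.stack.astro)
    assert np.array_equal(a.stack.puncta, b.stack.puncta)


def test_ground_truth_volumes_span_the_bouton_window():
    scene = generate_engulfment_stack(random_engulfment_spec(0))
    vols = np.array([t.volume_um3 for t in scene.truth])
    assert (vols < 0.01).any() and (vols > 1.0).any()
    assert ((vols >= 0.01) & (vols <= 1.0)).any()


# ----------------------------------------------------------- preprocess

def test_identity_configuration_preserves_normalized_input():
    scene = _simple_scene()
    stack = VoxelStack(scene.stack.astro / 200.0, scene.stack.puncta / 200.0, VS)
    out = preprocess(
        stack, percentiles=(0.0, 100.0), sharpen_amount=0.0,
        puncta_presmooth_um=0.0, astro_sigma_um=0.0,
    )
    assert np.allclose(out.astro, stack.astro)
    assert np.allclose(out.puncta, stack.puncta)


def test_unsharp_mask_boosts_punctum_peak():
    stack = np.zeros((15, 31, 31))
    stack[7, 15, 15] = 0.0
    punctum = np.zeros_like(stack)
    punctum[6:9, 12:19, 12:19] = 1.0
    vs = VoxelStack(stack, punctum, VS)
    out = preprocess(
        vs, percentiles=(0.0, 100.0), puncta_presmooth_um=0.0, astro_sigma_um=0.0
    )
    assert out.puncta.max() >= punctum.max()


def test_gaussian_blur_of_delta_matches_separable_kernel():
    """Physical-unit sigma maps to the right anisotropic voxel kernel."""
    delta = np.zeros((17, 33, 33))
    delta[8, 16, 16] = 1.0
    vs = VoxelStack(delta, np.zeros_like(delta), VS)
    sigma_um = 0.09
    out = preprocess(
        vs, percentiles=(0.0, 100.0), sharpen_amount=0.0,
        puncta_presmooth_um=0.0, astro_sigma_um=sigma_um,
    )

    def kernel_1d(sigma, n):
        i = np.arange(n) - n // 2
        k = np.exp(-(i**2) / (2 * sigma**2))
        return k / k.sum()

    sig_vox = [sigma_um / v for v in VS]
    oracle = np.einsum(
        "i,j,k->ijk",
        kernel_1d(sig_vox[0], 17),
        kernel_1d(sig_vox[1], 33),
        kernel_1d(sig_vox[2], 33),
    )
    assert np.abs(out.astro - oracle).max() < 1e-6


def test_constant_channel_normalizes_to_zero_with_warning():
    vs = VoxelStack(np.full((8, 8, 8), 3.0), np.zeros((8, 8, 8)), VS)
    with pytest.warns(UserWarning, match="constant"):
        out = preprocess(vs)
    assert out.astro.max() == 0.0


# ------------------------------------------------------------- classify

def test_threshold_classifier_is_exact_on_noiseless_scene():
    scene = _simple_scene()
    pre = preprocess(
        scene.stack, percentiles=(0.0, 100.0), sharpen_amount=0.0,
        puncta_presmooth_um=0.0, astro_sigma_um=0.0,
    )
    assert np.array_equal(classify(pre), scene.labels)


def test_all_background_stack_classifies_as_background():
    vs = VoxelStack(np.zeros((8, 16, 16)), np.zeros((8, 16, 16)), VS)
    with pytest.warns(UserWarning, match="constant"):
        pre = preprocess(vs)
    assert (classify(pre) == 0).all()


def test_untrained_forest_is_rejected():
    scene = _simple_scene()
    clf = PixelClassifier(mode="forest")
    with pytest.raises(ValueError, match="untrained"):
        clf.predict(scene.stack)


def test_trained_forest_reaches_95_percent_on_held_out_sections():
    scene = _simple_scene(snr=5.0, seed=11)
    pre = preprocess(scene.stack)
    train = list(range(0, 24, 2))[:15]
    test = list(range(1, 24, 2))
    clf = PixelClassifier(mode="forest", n_estimators=30, random_state=0)
    clf.fit(pre, scene.labels, train)
    acc = (clf.predict(pre)[test] == scene.labels[test]).mean()
    assert acc >= 0.95


# -------------------------------------------------------------- cleanup

def _blob(shape, center_vox, radius_um):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        ((zz - center_vox[0]) * VS[0]) ** 2
        + ((yy - center_vox[1]) * VS[1]) ** 2
        + ((xx - center_vox[2]) * VS[2]) ** 2
    )
    return d2 <= radius_um**2


def test_volume_threshold_keeps_large_and_drops_small_components():
    shape = (40, 140, 140)
    labels = np.zeros(shape, dtype=np.uint8)
    big = _blob(shape, (20, 35, 35), 1.7)  # ~20 um^3
    small = _blob(shape, (20, 105, 105), 1.06)  # ~5 um^3, below 10 um^3
    labels[big | small] = LABEL_ASTRO
    mask, table = clean_astro_mask(labels, CleanupParams(), VS)
    assert table.kept.sum() == 1
    assert (~table.kept).sum() == 1
    assert mask[20, 35, 35] and not mask[20, 105, 105]


def test_z_filament_bridge_is_separated_by_erosion():
    shape = (40, 60, 60)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[5:15, 20:40, 20:40] = LABEL_ASTRO
    labels[25:35, 20:40, 20:40] = LABEL_ASTRO
    labels[15:25, 30, 30] = LABEL_ASTRO  # 1-voxel-thick z filament
    before, _ = ndi.label(labels == LABEL_ASTRO, structure=np.ones((3, 3, 3)))
    assert before.max() == 1  # bridged before cleanup
    mask, table = clean_astro_mask(labels, CleanupParams(astro_min_volume=0.0), VS)
    assert len(table) == 2


def test_empty_astro_label_is_flagged():
    labels = np.zeros((8, 8, 8), dtype=np.uint8)
    with pytest.warns(UserWarning, match="empty"):
        mask, table = clean_astro_mask(labels, CleanupParams(), VS)
    assert not mask.any()
    assert table.empty


# ------------------------------------------------------- puncta extract

def test_punctum_volume_filter_follows_bouton_window():
    shape = (30, 60, 60)
    labels = np.zeros(shape, dtype=np.uint8)
    keep = _blob(shape, (15, 15, 15), 0.2)  # ~0.034 um^3: retained
    drop = _blob(shape, (15, 45, 45), 0.1)  # ~0.004 um^3: discarded
    labels[keep | drop] = LABEL_PUNCTA
    puncta, table = extract_puncta(labels, CleanupParams(), VS)
    assert len(puncta) == 1
    assert puncta[0].volume_um3 == pytest.approx(4 / 3 * np.pi * 0.2**3, rel=0.25)
    assert len(table) == 2
    assert int(table.retained.sum()) + int((~table.retained).sum()) == len(table)


def test_extraction_conserves_counts_on_planted_scene():
    scene = generate_engulfment_stack(random_engulfment_spec(1))
    puncta, table = extract_puncta(scene.labels, CleanupParams(), VS)
    in_window = [t for t in scene.truth if t.in_volume_window]
    assert len(puncta) == len(in_window)
    assert len(table) == len(scene.truth)
    got = sorted(p.volume_um3 for p in puncta)
    expected = sorted(t.volume_um3 for t in in_window)
    assert np.allclose(got, expected)


# ---------------------------------------------------------------- mesh

def test_cuboid_surface_area_close_to_analytic():
    vol = np.zeros((30, 24, 20), dtype=bool)
    vol[5:25, 4:20, 3:17] = True  # 2.0 x 1.6 x 1.4 um at 0.1-um voxels
    _, _, area = mesh_surface(vol, (0.1, 0.1, 0.1))
    exact = 2 * (2.0 * 1.6 + 1.6 * 1.4 + 2.0 * 1.4)
    assert area == pytest.approx(exact, rel=0.15)


def test_sphere_surface_area_close_to_analytic():
    n = 54
    zz, yy, xx = np.ogrid[:n, :n, :n]
    sph = ((zz - n / 2) ** 2 + (yy - n / 2) ** 2 + (xx - n / 2) ** 2) <= (1.0 / 0.04) ** 2
    _, _, area = mesh_surface(sph, (0.04, 0.04, 0.04))
    assert area == pytest.approx(4 * np.pi, rel=0.05)


def test_single_voxel_meshes_to_finite_area():
    vol = np.zeros((3, 3, 3), dtype=bool)
    vol[1, 1, 1] = True
    _, _, area = mesh_surface(vol, (0.1, 0.1, 0.1))
    assert 0 < area < np.inf


def test_empty_mask_cannot_be_meshed():
    with pytest.raises(ValueError, match="empty"):
        mesh_surface(np.zeros((4, 4, 4), dtype=bool), VS)


# -------------------------------------------------------------- scoring

def test_fully_inside_and_disjoint_puncta_score_one_and_zero():
    scene = _simple_scene()
    puncta, _ = extract_puncta(scene.labels, CleanupParams(), VS)
    astro_mask, _ = clean_astro_mask(scene.labels, CleanupParams(), VS)
    scored, report = score_engulfment(puncta, astro_mask, VS)
    fracs = sorted(p.engulfment_fraction for p in scored)
    assert fracs[0] == 0.0  # outside
    assert fracs[-1] == 1.0  # inside
    assert report.n_fully_engulfed == 1


def test_dilating_astro_mask_never_decreases_fractions():
    scene = generate_engulfment_stack(random_engulfment_spec(2))
    puncta, _ = extract_puncta(scene.labels, CleanupParams(), VS)
    astro_mask, _ = clean_astro_mask(scene.labels, CleanupParams(), VS)
    scored, _ = score_engulfment(puncta, astro_mask, VS)
    dilated = ndi.binary_dilation(astro_mask, iterations=3)
    scored_d, _ = score_engulfment(puncta, dilated, VS)
    for before, after in zip(scored, scored_d):
        assert after.engulfment_fraction >= before.engulfment_fraction - 1e-12


def test_astro_percentage_equals_direct_count_oracle():
    scene = _simple_scene()
    puncta, _ = extract_puncta(scene.labels, CleanupParams(), VS)
    astro_mask, _ = clean_astro_mask(scene.labels, CleanupParams(), VS)
    _, report = score_engulfment(puncta, astro_mask, VS)
    vox_vol = np.prod(VS)
    expected = 100.0 * astro_mask.sum() * vox_vol / (astro_mask.size * vox_vol)
    assert report.astro_percent_of_stack == pytest.approx(expected, abs=1e-12)


def test_geometry_mismatch_is_rejected():
    scene = _simple_scene()
    puncta, _ = extract_puncta(scene.labels, CleanupParams(), VS)
    with pytest.raises(ValueError, match="geometry"):
        score_engulfment(puncta, np.zeros((4, 4, 4), dtype=bool), VS)


# ------------------------------------------------------------ end to end

@pytest.mark.parametrize("seed", [0, 1])
def test_pipeline_recovers_planted_counts_noiselessly(seed):
    scene = generate_engulfment_stack(random_engulfment_spec(seed))
    _, report, _ = analyze_stack(scene.stack)
    expected_full = sum(
        1 for t in scene.truth if t.plan.klass == "inside" and t.in_volume_window
    )
    expected_retained = sum(1 for t in scene.truth if t.in_volume_window)
    assert report.n_fully_engulfed == expected_full
    assert report.n_puncta_filtered == expected_retained
    assert report.n_puncta_total >= report.n_puncta_filtered


@pytest.mark.parametrize("seed", [2, 3])
def test_pipeline_is_robust_at_snr_five(seed):
    scene = generate_engulfment_stack(random_engulfment_spec(seed, snr=5.0))
    _, report, _ = analyze_stack(scene.stack)
    expected_full = sum(
        1 for t in scene.truth if t.plan.klass == "inside" and t.in_volume_window
    )
    assert abs(report.n_fully_engulfed - expected_full) <= 1
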