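"""Template boxes, brightest-connected-voxel search, LC-I normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lcnbm import (
    BoxGeometry,
    DeformationField,
    ImageVolume,
    PhantomDesign,
    build_template_boxes,
    compute_lc_intensity,
    exact_brightest_connected,
    generate_lc_phantom,
    resample_boxes,
    select_brightest_connected,
)
from lcnbm.lc_intensity import LC_VOLUME_MM3, REFERENCE_VOLUME_MM3

from _greedy_oracle import greedy_brightest_connected


def _native_boxes(design, subject):
    boxes = build_template_boxes(design.tse_voxel, BoxGeometry(grid_shape=design.tse_grid))
    return resample_boxes(boxes, subject.tse_transform, subject.tse_image.shape, subject.tse_image.affine)


# --------------------------------------------------------------------- boxes
@pytest.mark.parametrize("spacing", [(0.4, 0.4, 3.0), (1.0, 1.0, 1.0), (0.5, 0.5, 2.0)])
def test_box_volumes_within_one_voxel(spacing):
    boxes = build_template_boxes(spacing)
    vv = float(np.prod(spacing))
    assert abs(boxes.volume_mm3("reference") - REFERENCE_VOLUME_MM3) <= vv
    assert abs(boxes.volume_mm3("lc_left") - LC_VOLUME_MM3) <= vv
    assert abs(boxes.volume_mm3("lc_right") - LC_VOLUME_MM3) <= vv


def test_unit_voxels_give_exact_reference_count():
    boxes = build_template_boxes((1.0, 1.0, 1.0))
    assert int(boxes.masks["reference"].sum()) == 6200


def test_lc_boxes_mirror_symmetric():
    boxes = build_template_boxes((0.4, 0.4, 3.0))
    assert np.array_equal(boxes.masks["lc_right"], boxes.masks["lc_left"][::-1, :, :])
    # disjointness is part of construction
    union = sum(m.astype(int) for m in boxes.masks.values())
    assert union.max() == 1


def test_too_coarse_spacing_raises():
    with pytest.raises(ValueError, match="coarse"):
        build_template_boxes((10.0, 10.0, 10.0))


# ----------------------------------------------------------------- resampling
def test_resample_identity_reproduces_boxes():
    boxes = build_template_boxes((1.0, 1.0, 1.0), BoxGeometry(grid_shape=(96, 96, 24)))
    native = resample_boxes(boxes, DeformationField.identity(), (96, 96, 24), np.eye(4))
    for name in boxes.masks:
        assert np.array_equal(native.masks[name], boxes.masks[name])


def test_resample_translation_preserves_counts():
    boxes = build_template_boxes((1.0, 1.0, 1.0), BoxGeometry(grid_shape=(96, 96, 24)))
    shift = DeformationField.translation((1.0, 0.0, 0.0))
    native = resample_boxes(boxes, shift, (96, 96, 24), np.eye(4))
    for name in boxes.masks:
        assert native.masks[name].sum() == boxes.masks[name].sum()
        assert np.array_equal(native.masks[name][1:], boxes.masks[name][:-1])


def test_phantom_truth_inside_resampled_boxes(noiseless_design):
    subject = generate_lc_phantom(noiseless_design, 0)
    native = _native_boxes(noiseless_design, subject)
    for side, name in (("left", "lc_left"), ("right", "lc_right")):
        sel = subject.true_lc_voxels[side]
        assert native.masks[name][sel[:, 0], sel[:, 1], sel[:, 2]].all()


# ------------------------------------------------------------------ selection
def test_plateau_selection_returns_k_voxels(noiseless_design):
    subject = generate_lc_phantom(noiseless_design, 0)
    native = _native_boxes(noiseless_design, subject)
    res = compute_lc_intensity(subject.tse_image, native, k=10)
    assert len(res.selected_left) == 10
    assert len(res.selected_right) == 10


def test_uniform_box_pure_tiebreak_path():
    data = np.ones((6, 6, 3))
    box = np.zeros((6, 6, 3), dtype=bool)
    box[1:5, 1:5, :] = True
    sel = select_brightest_connected(data, box, k=3)
    # seed is the lowest-linear-index box voxel; growth follows index order
    assert tuple(sel[0]) == (1, 1, 0)
    assert [tuple(v) for v in sel] == greedy_brightest_connected(data, box, 3)


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_greedy_matches_independent_oracle(connectivity, rng):
    for _ in range(100):
        data = rng.normal(size=(8, 8, 4))
        box = np.zeros((8, 8, 4), dtype=bool)
        box[1:7, 1:7, 1:4] = True
        sel = select_brightest_connected(data, box, k=5, connectivity=connectivity)
        assert [tuple(v) for v in sel] == greedy_brightest_connected(data, box, 5, connectivity)


def test_exact_search_never_below_greedy(rng):
    for _ in range(25):
        data = rng.normal(size=(5, 5, 3))
        box = np.ones((5, 5, 3), dtype=bool)
        greedy = select_brightest_connected(data, box, k=4)
        exact = exact_brightest_connected(data, box, k=4)
        s = lambda sel: data[sel[:, 0], sel[:, 1], sel[:, 2]].sum()
        assert s(exact) >= s(greedy) - 1e-12
        assert len(exact) == 4


def test_exact_selection_on_exact_size_cluster():
    """A noiseless cluster of exactly k voxels is recovered voxel for voxel."""
    design = PhantomDesign(
        noise_sigma=0.0, n_distractors=0, missing_lc_i={}, lc_cluster_voxels=10, seed=5
    )
    subject = generate_lc_phantom(design, 0)
    native = _native_boxes(design, subject)
    res = compute_lc_intensity(subject.tse_image, native, k=10)
    for side, sel in (("left", res.selected_left), ("right", res.selected_right)):
        assert np.array_equal(sel, subject.true_lc_voxels[side])


def test_selection_short_set_is_qc_not_error():
    data = np.zeros((4, 4, 2))
    box = np.zeros((4, 4, 2), dtype=bool)
    box[0, 0, 0] = True
    box[3, 3, 1] = True  # two voxels, not 26-adjacent
    data[0, 0, 0] = 5.0
    sel = select_brightest_connected(data, box, k=2)
    assert len(sel) == 1 and tuple(sel[0]) == (0, 0, 0)


def test_selection_errors():
    data = np.ones((4, 4, 2))
    with pytest.raises(ValueError, match="empty"):
        select_brightest_connected(data, np.zeros_like(data, dtype=bool), k=3)
    bad = data.copy()
    bad[1, 1, 1] = np.nan
    with pytest.raises(ValueError, match="finite"):
        select_brightest_connected(bad, np.ones_like(data, dtype=bool), k=3)


# ----------------------------------------------------------------------- LC-I
def _uniform_setup(c=3.0):
    boxes = build_template_boxes((1.0, 1.0, 1.0), BoxGeometry(grid_shape=(96, 96, 24)))
    native = resample_boxes(boxes, DeformationField.identity(), (96, 96, 24), np.eye(4))
    image = ImageVolume(np.full((96, 96, 24), c), np.eye(4))
    return image, native


@pytest.mark.parametrize("c", [0.5, 1.0, 250.0])
def test_constant_image_null_values(c):
    image, native = _uniform_setup(c)
    assert compute_lc_intensity(image, native, formula="ratio").lc_i == pytest.approx(1.0, abs=1e-12)
    assert compute_lc_intensity(image, native, formula="contrast").lc_i == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("factor", [0.1, 7.0, 1000.0])
def test_global_rescaling_invariance(noiseless_design, factor):
    subject = generate_lc_phantom(noiseless_design, 0)
    native = _native_boxes(noiseless_design, subject)
    for formula in ("ratio", "contrast"):
        base = compute_lc_intensity(subject.tse_image, native, formula=formula)
        scaled_img = ImageVolume(subject.tse_image.data * factor, subject.tse_image.affine)
        scaled = compute_lc_intensity(scaled_img, native, formula=formula)
        assert abs(scaled.lc_i - base.lc_i) < 1e-12
        assert np.array_equal(scaled.selected_left, base.selected_left)


def test_monotonicity_in_true_lc_intensity(small_design):
    subject = generate_lc_phantom(small_design, 0)
    native = _native_boxes(small_design, subject)
    base = compute_lc_intensity(subject.tse_image, native)
    raised = subject.tse_image.data.copy()
    for sel in subject.true_lc_voxels.values():
        raised[sel[:, 0], sel[:, 1], sel[:, 2]] += 10.0
    res = compute_lc_intensity(ImageVolume(raised, subject.tse_image.affine), native)
    assert res.lc_i >= base.lc_i


def test_noiseless_phantom_recovers_contrast(noiseless_design):
    subject = generate_lc_phantom(noiseless_design, 0)
    native = _native_boxes(noiseless_design, subject)
    res = compute_lc_intensity(subject.tse_image, native)
    assert res.lc_i == pytest.approx(subject.true_lc_contrast, rel=1e-12)
    assert res.lc_i_left == pytest.approx(res.lc_i_right, rel=1e-12)
    assert all(all(flags.values()) for flags in res.qc.values())


def test_nonpositive_reference_mean_raises():
    image, native = _uniform_setup(0.0)
    with pytest.raises(ValueError, match="reference mean"):
        compute_lc_intensity(image, native)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), k=st.integers(1, 12))
def test_selected_set_connected_and_boxed(seed, k):
    """Property: selections are connected, inside the box, of size <= k."""
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(7, 7, 4))
    box = rng.uniform(size=(7, 7, 4)) < 0.5
    box[3, 3, 2] = True  # never empty
    sel = select_brightest_connected(data, box, k=k)
    assert 1 <= len(sel) <= k
    assert box[sel[:, 0], sel[:, 1], sel[:, 2]].all()
    chosen = {tuple(v) for v in sel}
    if len(sel) > 1:
        # connected under 26-adjacency
        seen = {next(iter(chosen))}
        grew = True
        while grew:
            grew = False
            for v in list(chosen - seen):
                if any(
                    max(abs(a - b) for a, b in zip(v, w)) == 1 for w in seen
                ):
                    seen.add(v)
                    grew = True
        assert seen == chosen
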