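"""Segmentation and shape descriptors against generator ground truth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morpholink import morphometry
from morpholink.morphometry import (
    LabeledImage,
    RasterImage,
    exclude_edge_cells,
    invasion_fold_change,
    measure_shapes,
    segment_cells,
    spheroid_invasion,
)
from morpholink.synthetic import (
    ShapeSpec,
    generate_shape_image,
    generate_spheroid_positions,
    rasterize_spec,
    shape_truth,
)

DESCRIPTORS = ["area_um2", "perimeter_um", "form_factor", "solidity", "eccentricity", "compactness"]


# --- segmentation -----------------------------------------------------------

def test_two_disjoint_cells_segment_to_two_labels():
    specs = [
        ShapeSpec("disk", (120, 120), 60, nucleus_radius=12),
        ShapeSpec("ellipse", (360, 360), (80, 50), nucleus_radius=12),
    ]
    image, _ = generate_shape_image(specs, (512, 512), 1.0)
    labeled = segment_cells(image)
    assert labeled.n_labels == 2
    # each label encloses exactly one nucleus centroid
    for spec in specs:
        cx, cy = spec.center
        assert labeled.labels[int(cy), int(cx)] > 0
    assert labeled.labels[int(specs[0].center[1]), int(specs[0].center[0])] != (
        labeled.labels[int(specs[1].center[1]), int(specs[1].center[0])]
    )


def test_blank_image_zero_labels():
    image = RasterImage(np.zeros((128, 128)), np.zeros((128, 128)), 1.0)
    assert segment_cells(image).n_labels == 0


def test_mismatched_channels_error():
    with pytest.raises(ValueError, match="identical shapes"):
        RasterImage(np.zeros((64, 64)), np.zeros((64, 65)), 1.0)


def test_touching_cells_split_by_nucleus_seeds():
    """Two touching disks with separated nuclei: watershed recovers each
    planted mask at >= 95% IoU."""
    r = 60
    specs = [
        ShapeSpec("disk", (196, 256), r, nucleus_radius=12, overlap_ok=True),
        ShapeSpec("disk", (316, 256), r, nucleus_radius=12, overlap_ok=True),
    ]
    image, _ = generate_shape_image(specs, (512, 512), 1.0)
    labeled = segment_cells(image)
    assert labeled.n_labels == 2
    for spec in specs:
        true_mask = rasterize_spec(spec, (512, 512))
        label_at_seed = labeled.labels[int(spec.center[1]), int(spec.center[0])]
        got = labeled.labels == label_at_seed
        iou = (got & true_mask).sum() / (got | true_mask).sum()
        assert iou >= 0.95


def test_min_area_filter_drops_small_objects():
    specs = [
        ShapeSpec("disk", (100, 100), 40, nucleus_radius=8),
        ShapeSpec("disk", (300, 300), 6, nucleus_radius=2),
    ]
    image, _ = generate_shape_image(specs, (512, 512), 1.0)
    assert segment_cells(image, min_area_um2=500.0).n_labels == 1


# --- edge exclusion ---------------------------------------------------------

def test_border_touching_object_discarded():
    specs = [
        ShapeSpec("disk", (30, 256), 40, nucleus_radius=8, edge_ok=True),
        ShapeSpec("disk", (300, 256), 40, nucleus_radius=8),
    ]
    image, _ = generate_shape_image(specs, (512, 512), 1.0)
    labeled = exclude_edge_cells(segment_cells(image))
    assert labeled.n_labels == 1
    assert labeled.labels[256, 300] == 1  # relabelled consecutively


def test_interior_objects_untouched_and_all_border_case():
    image, _ = generate_shape_image([ShapeSpec("disk", (256, 256), 50)], (512, 512), 1.0)
    before = segment_cells(image)
    after = exclude_edge_cells(before)
    assert after.n_labels == before.n_labels == 1
    assert np.array_equal(after.labels > 0, before.labels > 0)

    edge_img, _ = generate_shape_image(
        [ShapeSpec("disk", (2, 256), 30, edge_ok=True)], (512, 512), 1.0
    )
    assert exclude_edge_cells(segment_cells(edge_img)).n_labels == 0


# --- descriptors ------------------------------------------------------------

@pytest.mark.parametrize(
    "spec",
    [
        ShapeSpec("disk", (256, 256), 200),
        ShapeSpec("ellipse", (256, 256), (200, 100)),
        ShapeSpec("rectangle", (256, 256), (300, 300)),
        ShapeSpec("star", (256, 256), (180, 120), amplitude=0.25, n_lobes=5),
    ],
    ids=["disk", "ellipse", "square", "star"],
)
def test_measured_descriptors_match_analytic_truth(spec):
    image, truth = generate_shape_image([spec], (512, 512), 1.0)
    measured = measure_shapes(segment_cells(image), 1.0).iloc[0]
    expected = truth.iloc[0]
    for col in DESCRIPTORS:
        tol = 0.01 if col == "solidity" else 0.02
        if expected[col] == 0:
            assert abs(measured[col]) < 0.05
        else:
            assert measured[col] == pytest.approx(expected[col], rel=tol), col


def test_pixel_size_scales_area_and_perimeter_only():
    spec = ShapeSpec("ellipse", (256, 256), (150, 90))
    image, _ = generate_shape_image([spec], (512, 512), pixel_size_um=1.0)
    labeled = segment_cells(image)
    at1 = measure_shapes(labeled, 1.0).iloc[0]
    at2 = measure_shapes(labeled, 2.0).iloc[0]
    assert at2["area_um2"] == pytest.approx(4 * at1["area_um2"])
    assert at2["perimeter_um"] == pytest.approx(2 * at1["perimeter_um"])
    for col in ["form_factor", "solidity", "eccentricity", "compactness"]:
        assert at2[col] == at1[col]


@settings(max_examples=6, deadline=None)
@given(angle=st.floats(0.0, math.pi, allow_nan=False))
def test_rotation_invariance_of_descriptors(angle):
    """Re-rasterizing a rotated silhouette changes no descriptor by > 2%."""
    base = ShapeSpec("star", (256, 256), (150, 100), amplitude=0.2, n_lobes=5, rotation=0.0)
    rot = ShapeSpec("star", (256, 256), (150, 100), amplitude=0.2, n_lobes=5, rotation=angle)
    ref = measure_shapes(
        LabeledImage.from_array(rasterize_spec(base, (512, 512)).astype(int)), 1.0
    ).iloc[0]
    turned = measure_shapes(
        LabeledImage.from_array(rasterize_spec(rot, (512, 512)).astype(int)), 1.0
    ).iloc[0]
    for col in DESCRIPTORS:
        assert turned[col] == pytest.approx(ref[col], rel=0.02), col


def test_descriptor_invariants_hold_on_irregular_shape():
    spec = ShapeSpec("star", (256, 256), (170, 110), amplitude=0.35, n_lobes=7)
    m = measure_shapes(
        LabeledImage.from_array(rasterize_spec(spec, (512, 512)).astype(int)), 1.0
    ).iloc[0]
    assert 0 < m["solidity"] <= 1
    assert 0 <= m["eccentricity"] < 1
    assert m["form_factor"] < 1  # lobed outline is far from circular
    assert m["compactness"] > 1


def test_measure_errors():
    with pytest.raises(ValueError):
        measure_shapes(LabeledImage(np.zeros((10, 10), dtype=int), 0), 1.0)
    labeled = LabeledImage.from_array(rasterize_spec(ShapeSpec("disk", (64, 64), 20), (128, 128)).astype(int))
    with pytest.raises(ValueError):
        measure_shapes(labeled, -1.0)


# --- spheroid invasion ------------------------------------------------------

def test_spheroid_invasion_mean_distance():
    ring = generate_spheroid_positions(200.0, [400.0] * 30, seed=0)
    assert spheroid_invasion(ring.positions, ring.center) == pytest.approx(400.0)
    two = generate_spheroid_positions(200.0, [100.0, 300.0], seed=1)
    assert spheroid_invasion(two.positions, two.center) == pytest.approx(200.0)


def test_spheroid_invasion_matches_planted_mean():
    distances = np.linspace(250, 500, 40)
    sph = generate_spheroid_positions(200.0, distances, seed=3, center=(50.0, -20.0))
    assert spheroid_invasion(sph.positions, sph.center) == pytest.approx(distances.mean())


def test_empty_spheroid_flagged_undefined():
    sph = generate_spheroid_positions(200.0, [], seed=0)
    with pytest.warns(UserWarning, match="undefined"):
        assert math.isnan(spheroid_invasion(sph.positions, sph.center))
    with pytest.raises(ValueError):
        generate_spheroid_positions(200.0, [-5.0])
    with pytest.raises(ValueError):
        generate_spheroid_positions(0.0, [10.0])


def test_invasion_fold_change():
    folds = invasion_fold_change([200.0, 200.0], [100.0, 100.0])
    assert folds == pytest.approx([2.0, 2.0])
    assert invasion_fold_change([150.0], [100.0, 200.0])[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        invasion_fold_change([100.0], [])
    with pytest.raises(ValueError):
        invasion_fold_change([100.0], [0.0])


# --- image IO ---------------------------------------------------------------

def test_tiff_roundtrip(tmp_path, disk_image):
    image, _ = disk_image
    path = tmp_path / "img.tiff"
    image.to_tiff(path)
    back = morphometry.RasterImage.from_tiff(path)
    assert np.array_equal(back.nuclei, image.nuclei)
    assert np.array_equal(back.cytoplasm, image.cytoplasm)
    assert back.pixel_size_um == image.pixel_size_um
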