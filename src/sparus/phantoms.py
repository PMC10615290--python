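"""Synthetic phantoms: wire targets, tooth/gingiva-like layered speckle
scenes, negative controls, paired sparse/dense dataset assembly, and
automated perpendicular thickness measurement on ground-truth geometry.

Coordinates are (lateral x, depth z) in meters, z increasing downward.
The tooth surface is a gently convex arc starting at the gingival margin;
the gingiva surface is an offset curve whose perpendicular separation at
the measurement arc distance equals the requested thickness exactly by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .acquisition import (
    Phantom,
    PlaneWaveSequence,
    TransducerArray,
    ValidationError,
    decimate_aperture,
    make_linear_array,
    mask_rf,
    simulate_rf,
)
from .beamform import BModeImage, ImageGrid, beamform_bmode

__all__ = [
    "ToothScene",
    "PairedDataset",
    "wire_phantom",
    "make_tooth_scene",
    "tooth_phantom",
    "negative_control_phantom",
    "measure_thickness",
    "dataset_phantom",
    "make_paired_dataset",
    "points_in_polygon",
]


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Crossing-number point-in-polygon test, vectorized over points."""
    px, py = points[:, 0], points[:, 1]
    x0, y0 = polygon[:, 0], polygon[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    inside = np.zeros(px.shape, dtype=bool)
    for ax, ay, bx, by in zip(x0, y0, x1, y1):
        crosses = (ay > py) != (by > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = ax + (py - ay) * (bx - ax) / (by - ay)
        inside ^= crosses & (px < x_int)
    return inside


@dataclass(frozen=True)
class ToothScene:
    """Ground-truth geometry of a tooth/gingiva interface pair.

    Both curves are piecewise-linear (n, 2) arrays starting at the
    gingival margin, ordered by arc length.
    """

    tooth_surface_curve: np.ndarray
    gingiva_surface_curve: np.ndarray
    gingival_margin: tuple[float, float]
    scatterer_density: float = 40.0  # per mm^2
    contrast: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.tooth_surface_curve, dtype=float)
        g = np.asarray(self.gingiva_surface_curve, dtype=float)
        if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
            raise ValidationError("tooth curve must be an (n>=2, 2) array")
        if g.ndim != 2 or g.shape[1] != 2 or g.shape[0] < 2:
            raise ValidationError("gingiva curve must be an (n>=2, 2) array")
        object.__setattr__(self, "tooth_surface_curve", t)
        object.__setattr__(self, "gingiva_surface_curve", g)

    def rotated(self, angle_rad: float, center: tuple[float, float] | None = None) -> "ToothScene":
        """Rigidly rotate the whole scene about ``center`` (default: margin)."""
        if center is None:
            center = self.gingival_margin
        c = np.asarray(center, dtype=float)
        rot = np.array(
            [
                [np.cos(angle_rad), -np.sin(angle_rad)],
                [np.sin(angle_rad), np.cos(angle_rad)],
            ]
        )
        t = (self.tooth_surface_curve - c) @ rot.T + c
        g = (self.gingiva_surface_curve - c) @ rot.T + c
        m = tuple((np.asarray(self.gingival_margin) - c) @ rot.T + c)
        return replace(
            self, tooth_surface_curve=t, gingiva_surface_curve=g, gingival_margin=m
        )


def wire_phantom(depth: float = 10e-3) -> Phantom:
    """Single unit-reflectivity scatterer on axis (the wire target)."""
    if depth <= 0:
        raise ValidationError("wire depth must be positive")
    return Phantom(
        scatterer_positions=np.array([[0.0, depth]]),
        reflectivities=np.array([1.0]),
        metadata={"generator": "wire_phantom", "depth": depth},
    )


def _arc_curve(
    start: np.ndarray,
    tangent_angle: float,
    curvature: float,
    length: float,
    n_points: int = 200,
) -> np.ndarray:
    """Constant-curvature polyline parameterized by arc length.

    ``tangent_angle`` is measured from +x toward +z; positive curvature
    turns the tangent back toward horizontal (convex toward the probe).
    """
    s = np.linspace(0.0, length, n_points)
    ang = tangent_angle - curvature * s
    if abs(curvature) < 1e-9:
        x = start[0] + s * np.cos(tangent_angle)
        z = start[1] + s * np.sin(tangent_angle)
    else:
        # closed-form arc integration of (cos(ang), sin(ang)) over s
        x = start[0] + (np.sin(tangent_angle) - np.sin(ang)) / curvature
        z = start[1] - (np.cos(tangent_angle) - np.cos(ang)) / curvature
    return np.column_stack([x, z])


def _curve_normals(curve: np.ndarray) -> np.ndarray:
    """Unit normals per vertex, rotated -90 deg from the local tangent
    (points toward shallower z for a rightward-descending curve)."""
    grad = np.gradient(curve, axis=0)
    tangent = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    return np.column_stack([tangent[:, 1], -tangent[:, 0]])


def _arc_lengths(curve: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def make_tooth_scene(
    thickness_mm: float,
    margin: tuple[float, float] = (-1.5e-3, 2.5e-3),
    tangent_angle_deg: float = 55.0,
    curvature: float = 40.0,
    curve_length: float = 6e-3,
    measure_distance_mm: float = 2.0,
    scatterer_density: float = 40.0,
    contrast: float = 8.0,
    seed: int = 0,
) -> ToothScene:
    """Build a scene whose perpendicular thickness at the measurement arc
    distance from the margin equals ``thickness_mm`` exactly.

    The gingiva surface is the tooth arc offset along its local normal by
    ``d(s) = thickness * min(s / s0, 1.25)`` (zero at the margin), so the
    normal ray from the tooth point at arc length ``s0`` meets the gingiva
    surface at exactly the requested thickness; the saturation keeps the
    offset curve below the transducer plane for steep scenes.
    """
    if not (0.5 <= thickness_mm <= 3.0):
        raise ValidationError("thickness must lie in [0.5, 3.0] mm")
    start = np.asarray(margin, dtype=float)
    tooth = _arc_curve(start, np.deg2rad(tangent_angle_deg), curvature, curve_length)
    normals = _curve_normals(tooth)
    s = _arc_lengths(tooth)
    s0 = measure_distance_mm * 1e-3
    d = (thickness_mm * 1e-3) * np.minimum(s / s0, 1.25)
    gingiva = tooth + normals * d[:, None]
    return ToothScene(
        tooth_surface_curve=tooth,
        gingiva_surface_curve=gingiva,
        gingival_margin=tuple(start),
        scatterer_density=scatterer_density,
        contrast=contrast,
        seed=seed,
    )


def _resample_polyline(curve: np.ndarray, spacing: float) -> np.ndarray:
    s = _arc_lengths(curve)
    targets = np.arange(0.0, s[-1], spacing)
    x = np.interp(targets, s, curve[:, 0])
    z = np.interp(targets, s, curve[:, 1])
    return np.column_stack([x, z])


def _gingiva_polygon(scene: ToothScene) -> np.ndarray:
    return np.vstack([scene.tooth_surface_curve, scene.gingiva_surface_curve[::-1]])


def gingiva_region_mask(scene: ToothScene, grid: ImageGrid) -> np.ndarray:
    """Binary mask of the gingiva region (between the curves) on the grid."""
    poly = _gingiva_polygon(scene)
    xx, zz = np.meshgrid(grid.x, grid.z)
    pts = np.column_stack([xx.ravel(), zz.ravel()])
    return points_in_polygon(pts, poly).reshape(grid.n_rows, grid.n_cols)


def tooth_phantom(
    thickness_mm: float,
    scene: ToothScene | None = None,
    grid: ImageGrid | None = None,
    seed: int = 0,
    interface_spacing: float = 35e-6,
) -> Phantom:
    """Scatterer realization of a tooth/gingiva scene.

    Bright scatterers trace the tooth surface, moderate ones the gingiva
    surface, and diffuse Gaussian-amplitude speckle (Poisson count at the
    scene density) fills the region between.  Emits a "gingiva" region
    mask when a grid is given.
    """
    if scene is None:
        scene = make_tooth_scene(thickness_mm, seed=seed)
    rng = np.random.default_rng(scene.seed if scene.seed is not None else seed)

    tooth_pts = _resample_polyline(scene.tooth_surface_curve, interface_spacing)
    # skip the shared margin vertex so the gingival edge is not doubled
    ging_pts = _resample_polyline(scene.gingiva_surface_curve, interface_spacing)[1:]
    tooth_refl = scene.contrast * (1.0 + 0.1 * rng.standard_normal(len(tooth_pts)))
    ging_refl = 0.5 * scene.contrast * (1.0 + 0.1 * rng.standard_normal(len(ging_pts)))

    poly = _gingiva_polygon(scene)
    area_mm2 = 0.5 * abs(
        np.sum(poly[:, 0] * np.roll(poly[:, 1], -1) - np.roll(poly[:, 0], -1) * poly[:, 1])
    ) / 1e-6
    n_speckle = rng.poisson(scene.scatterer_density * area_mm2)
    lo = poly.min(axis=0)
    hi = poly.max(axis=0)
    speckle = np.empty((0, 2))
    while speckle.shape[0] < n_speckle:
        cand = rng.uniform(lo, hi, size=(max(4 * n_speckle, 64), 2))
        cand = cand[points_in_polygon(cand, poly)]
        speckle = np.vstack([speckle, cand])
    speckle = speckle[:n_speckle]
    speckle_refl = rng.standard_normal(n_speckle)

    positions = np.vstack([tooth_pts, ging_pts, speckle])
    refl = np.concatenate([tooth_refl, ging_refl, speckle_refl])
    masks = {}
    if grid is not None:
        masks["gingiva"] = gingiva_region_mask(scene, grid)
    return Phantom(
        scatterer_positions=positions,
        reflectivities=refl,
        region_masks=masks,
        metadata={
            "generator": "tooth_phantom",
            "seed": int(scene.seed),
            "thickness_mm": float(thickness_mm),
            "n_speckle": int(n_speckle),
        },
    )


def negative_control_phantom(kind: str, seed: int = 0, density: float = 40.0) -> Phantom:
    """Non-tooth scenes: anechoic vessel, layered muscle, or pure noise."""
    rng = np.random.default_rng(seed)
    x_lo, x_hi = -3e-3, 3e-3
    z_lo, z_hi = 2e-3, 9e-3
    area_mm2 = (x_hi - x_lo) * (z_hi - z_lo) / 1e-6
    n = rng.poisson(density * area_mm2)
    pos = np.column_stack(
        [rng.uniform(x_lo, x_hi, n), rng.uniform(z_lo, z_hi, n)]
    )
    refl = rng.standard_normal(n)
    meta = {"generator": "negative_control_phantom", "kind": kind, "seed": int(seed)}

    if kind == "vessel":
        cx, cz, a, b = 0.0, 5.5e-3, 1.2e-3, 0.7e-3
        inside = ((pos[:, 0] - cx) / a) ** 2 + ((pos[:, 1] - cz) / b) ** 2 < 1.0
        pos, refl = pos[~inside], refl[~inside]
        meta["ellipse"] = {"cx": cx, "cz": cz, "a": a, "b": b}
    elif kind == "muscle":
        band = 1.0 + 0.9 * np.sin(2.0 * np.pi * pos[:, 1] / 1.5e-3)
        refl = refl * band
    elif kind == "noise":
        refl = refl * rng.uniform(0.2, 1.0, refl.shape)
    else:
        raise ValidationError(f"unknown negative-control kind: {kind!r}")
    return Phantom(scatterer_positions=pos, reflectivities=refl, metadata=meta)


def measure_thickness(scene: ToothScene, distance_from_margin_mm: float = 2.0) -> float:
    """Perpendicular tooth-to-gingiva distance, in mm, 0.01 mm precision.

    Walks ``distance_from_margin_mm`` along the tooth surface (arc length)
    from the margin, casts a ray along the local surface normal, and
    returns the distance to its first intersection with the gingiva
    surface polyline.
    """
    tooth = scene.tooth_surface_curve
    s = _arc_lengths(tooth)
    target = distance_from_margin_mm * 1e-3
    if target > s[-1]:
        raise ValidationError("measurement point beyond the tooth surface extent")
    px = np.interp(target, s, tooth[:, 0])
    pz = np.interp(target, s, tooth[:, 1])
    p0 = np.array([px, pz])
    seg = np.searchsorted(s, target, side="right") - 1
    seg = min(max(seg, 0), tooth.shape[0] - 2)
    tangent = tooth[seg + 1] - tooth[seg]
    tangent = tangent / np.linalg.norm(tangent)
    normal = np.array([tangent[1], -tangent[0]])

    best = None
    g = scene.gingiva_surface_curve
    for sign in (1.0, -1.0):
        d = normal * sign
        for a, b in zip(g[:-1], g[1:]):
            # solve p0 + t d = a + u (b - a), t > tiny, 0 <= u <= 1
            m = np.array([[d[0], a[0] - b[0]], [d[1], a[1] - b[1]]])
            det = np.linalg.det(m)
            if abs(det) < 1e-18:
                continue
            t, u = np.linalg.solve(m, np.asarray(a) - p0)
            if t > 1e-9 and -1e-9 <= u <= 1 + 1e-9:
                if best is None or t < best:
                    best = t
    if best is None:
        raise ValidationError("surface normal does not intersect the gingiva surface")
    return round(float(best) * 1e3, 2)


@dataclass
class PairedDataset:
    """Pixel-aligned sparse/dense B-mode pairs with a train/val(/test) split.

    ``sparse_images`` maps each decimation factor to its list of frames;
    all lists align index-wise with ``dense_images`` (identical phantoms).
    """

    dense_images: list
    sparse_images: dict
    split: dict
    seed: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.dense_images)
        for f, imgs in self.sparse_images.items():
            if len(imgs) != n:
                raise ValidationError(f"factor-{f} list length mismatch")

    @property
    def n_pairs(self) -> int:
        return len(self.dense_images)

    def pairs(self, factor: int, indices=None) -> list:
        """(sparse, dense) tuples for one decimation factor."""
        idx = range(self.n_pairs) if indices is None else indices
        return [(self.sparse_images[factor][i], self.dense_images[i]) for i in idx]


def train_val_split(n: int, seed: int, val_fraction: float = 0.2) -> dict:
    """Seeded 80/20 shuffle split (counts: floor(0.8 n) train)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor((1.0 - val_fraction) * n))
    return {
        "train": np.sort(perm[:n_train]).tolist(),
        "val": np.sort(perm[n_train:]).tolist(),
    }


def dataset_phantom(
    seed: int,
    index: int,
    grid: ImageGrid | None = None,
    scatterer_density: float = 20.0,
) -> Phantom:
    """The ``index``-th randomized tooth phantom of a seeded dataset stream."""
    child = np.random.SeedSequence([int(seed), 0xD5]).spawn(index + 1)[index]
    rng = np.random.default_rng(child)
    thickness = float(rng.uniform(0.8, 2.2))
    scene = make_tooth_scene(
        thickness,
        margin=(float(rng.uniform(-2.5e-3, -0.5e-3)), float(rng.uniform(2.0e-3, 3.2e-3))),
        tangent_angle_deg=float(rng.uniform(45.0, 65.0)),
        curvature=float(rng.uniform(20.0, 60.0)),
        scatterer_density=scatterer_density,
        contrast=float(rng.uniform(6.0, 10.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return tooth_phantom(thickness, scene=scene, grid=grid)


def make_paired_dataset(
    n_pairs: int,
    factors: list[int],
    seed: int = 0,
    image_size: int = 128,
    n_test: int = 0,
    array: TransducerArray | None = None,
    sequence: PlaneWaveSequence | None = None,
    grid: ImageGrid | None = None,
    dynamic_range_db: float = 50.0,
    scatterer_density: float = 20.0,
) -> PairedDataset:
    """Simulate and beamform ``n_pairs`` phantoms per aperture configuration.

    Each phantom is simulated once with the dense array; sparse members
    re-beamform the masked RF (equivalent to sparse re-simulation under
    the plane-wave transmit model).  Deterministic under ``seed``; the
    80/20 train/val split covers the non-test pool.
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    if array is None:
        array = make_linear_array()
    if sequence is None:
        sequence = PlaneWaveSequence()
    if grid is None:
        grid = ImageGrid(
            n_rows=image_size,
            n_cols=image_size,
            lateral_min=-4.48e-3,
            lateral_max=4.48e-3,
            depth_min=0.5e-3,
            depth_max=9.5e-3,
        )
    sparse_arrays = {f: decimate_aperture(array, f) for f in factors}

    total = n_pairs + n_test
    dense_images: list[BModeImage] = []
    sparse_images: dict[int, list[BModeImage]] = {f: [] for f in factors}
    for i in range(total):
        phantom = dataset_phantom(seed, i, grid=grid, scatterer_density=scatterer_density)
        rf = simulate_rf(
            phantom,
            array,
            sequence,
            cover_depth=grid.depth_max,
            cover_lateral=max(abs(grid.lateral_min), abs(grid.lateral_max)),
        )
        dense_images.append(
            beamform_bmode(rf, grid, array, sequence.sound_speed, dynamic_range_db)
        )
        for f, arr_f in sparse_arrays.items():
            rf_f = mask_rf(rf, arr_f)
            sparse_images[f].append(
                beamform_bmode(rf_f, grid, arr_f, sequence.sound_speed, dynamic_range_db)
            )

    split = train_val_split(n_pairs, seed)
    if n_test:
        split["test"] = list(range(n_pairs, total))
    else:
        split["test"] = []
    return PairedDataset(
        dense_images=dense_images,
        sparse_images=sparse_images,
        split=split,
        seed=seed,
        metadata={"factors": list(factors), "image_size": image_size, "n_test": n_test},
    )
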