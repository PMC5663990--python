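"""Synthetic SIRT phantoms.

Generates everything the downstream chain needs without patient data: an
ellipsoidal liver, a lung slab, spherical tumors, a procedurally grown
bifurcating arterial tree (analytic centerline graph + rasterized vessel
mask), ground-truth arterial territories, a piecewise-uniform activity
distribution with a prescribed tumor-to-normal uptake ratio and lung shunt,
and a SPECT-like count image (Gaussian PSF blur + Poisson counts).

The defaults emulate the imaging conditions of a typical MAA SPECT liver
study: 4.795 mm isotropic voxels, a 6-mm-FWHM Gaussian standing in for the
reconstruction point-spread function, and ~1e6 total counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import InvalidSpecError
from .graph import Branch, CenterlineGraph, Node, canonicalize_branch_ids
from .image import VolumeImage
from .territories import TerritoryLabelMap, assign_territories, group_branches

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "make_vessel_tree",
    "make_activity_truth",
    "simulate_spect",
    "generate",
    "small_spec",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic patient.

    All lengths are world mm; ``tumors`` entries are (x, y, z, radius).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = (4.795, 4.795, 4.795)
    liver_center_mm: tuple[float, float, float] = (150.0, 150.0, 100.0)
    liver_semiaxes_mm: tuple[float, float, float] = (90.0, 65.0, 50.0)
    lung_box_mm: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (60.0, 60.0, 170.0),
        (240.0, 240.0, 250.0),
    )
    vessel_root_mm: tuple[float, float, float] = (150.0, 92.0, 100.0)
    vessel_generations: int = 3
    branching_angle_deg: tuple[float, float] = (25.0, 40.0)
    segment_length_mm: tuple[float, float] = (30.0, 50.0)
    length_taper: float = 0.75
    root_radius_mm: float = 3.2
    radius_taper: float = 0.72
    tumors: tuple[tuple[float, float, float, float], ...] = ((170.0, 170.0, 100.0, 20.0),)
    true_TN: float = 6.0
    true_lung_shunt: float = 0.10
    psf_fwhm_mm: float = 6.0
    total_counts: int = 1_000_000
    grouping_generation: int = 2
    rng_seed: int = 0

    def validate(self) -> None:
        if self.vessel_generations < 1:
            raise InvalidSpecError("vessel_generations must be >= 1")
        if not (0.0 <= self.true_lung_shunt < 1.0):
            raise InvalidSpecError("true_lung_shunt must lie in [0, 1)")
        if self.true_TN <= 0:
            raise InvalidSpecError("true_TN must be > 0")
        if self.psf_fwhm_mm < 0:
            raise InvalidSpecError("psf_fwhm_mm must be >= 0")
        if self.total_counts <= 0:
            raise InvalidSpecError("total_counts must be > 0")
        if self._ellipsoid_value(np.asarray(self.vessel_root_mm)) >= 1.0:
            raise InvalidSpecError("vessel root lies outside the liver ellipsoid")
        for t in self.tumors:
            c, r = np.asarray(t[:3], dtype=float), float(t[3])
            if r <= 0:
                raise InvalidSpecError("tumor radius must be > 0")
            # conservative inscribed check: sphere surface sampled along axes
            for axis in np.vstack([np.eye(3), -np.eye(3)]):
                if self._ellipsoid_value(c + r * axis) > 1.0:
                    raise InvalidSpecError(
                        f"tumor at {tuple(t[:3])} (r={r} mm) leaves the liver"
                    )

    def _ellipsoid_value(self, p: np.ndarray) -> float:
        rel = (p - np.asarray(self.liver_center_mm)) / np.asarray(self.liver_semiaxes_mm)
        return float(np.dot(rel, rel))

    # -- analytic masks -----------------------------------------------------

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        sp = self.voxel_spacing_mm
        return tuple(  # type: ignore[return-value]
            np.arange(n) * s for n, s in zip(self.grid_shape, sp)
        )

    def _grids(self):
        xs, ys, zs = self.voxel_centers_mm()
        return np.meshgrid(xs, ys, zs, indexing="ij")

    def liver_mask(self) -> np.ndarray:
        X, Y, Z = self._grids()
        cx, cy, cz = self.liver_center_mm
        ax, ay, az = self.liver_semiaxes_mm
        return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0

    def lung_mask(self) -> np.ndarray:
        X, Y, Z = self._grids()
        (x0, y0, z0), (x1, y1, z1) = self.lung_box_mm
        return (
            (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1) & (Z >= z0) & (Z <= z1)
        )

    def tumor_masks(self) -> list[np.ndarray]:
        X, Y, Z = self._grids()
        out = []
        for cx, cy, cz, r in self.tumors:
            out.append((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r**2)
        return out


@dataclass
class PhantomBundle:
    """One generated synthetic patient with full ground truth."""

    spec: PhantomSpec
    liver_mask: VolumeImage
    lung_mask: VolumeImage
    tumor_masks: list[VolumeImage]
    vessel_mask: VolumeImage
    centerline_truth: CenterlineGraph
    territory_truth: TerritoryLabelMap
    activity_truth: VolumeImage
    count_image: VolumeImage
    branch_to_territory: dict[int, int] = field(default_factory=dict)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.liver_mask.spacing

    def tumor_union(self) -> np.ndarray:
        out = np.zeros(self.liver_mask.shape, dtype=bool)
        for t in self.tumor_masks:
            out |= t.data.astype(bool)
        return out


# ---------------------------------------------------------------------------
# vessel tree
# ---------------------------------------------------------------------------


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v around a unit axis."""
    k = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle_rad)
        + np.cross(k, v) * np.sin(angle_rad)
        + k * np.dot(k, v) * (1.0 - np.cos(angle_rad))
    )


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        r = rng.normal(size=3)
        p = r - v * np.dot(r, v)
        n = np.linalg.norm(p)
        if n > 1e-8:
            return p / n


def make_vessel_tree(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[CenterlineGraph, VolumeImage]:
    """Grow a bifurcating arterial tree inside the liver and rasterize it.

    Segments are straight polylines stepped at 1 mm, clipped to the liver
    ellipsoid; children leave the parent tip at angles drawn from the spec's
    branching range, in a random plane through the parent direction.  A
    strict tree of g generations yields 2^g - 1 branches.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)

    root = np.asarray(spec.vessel_root_mm, dtype=float)
    center = np.asarray(spec.liver_center_mm, dtype=float)
    d0 = center - root
    n0 = np.linalg.norm(d0)
    d0 = d0 / n0 if n0 > 1e-9 else np.array([0.0, 1.0, 0.0])

    nodes: dict[int, Node] = {0: Node(id=0, position=root, kind="root")}
    branches: dict[int, Branch] = {}
    radii: dict[int, float] = {}
    next_node = 1
    next_branch = 1

    # stack of (start_point, direction, generation, start_node_id); DFS pre-order
    stack = [(root, d0, 1, 0)]
    while stack:
        start, direction, gen, start_node = stack.pop(0)
        lo, hi = spec.segment_length_mm
        length = rng.uniform(lo, hi) * spec.length_taper ** (gen - 1)
        n_steps = max(1, int(round(length)))
        pts = [start]
        p = start
        for _ in range(n_steps):
            q = p + direction  # 1 mm steps
            if spec._ellipsoid_value(q) >= 0.98:
                break
            pts.append(q)
            p = q
        if len(pts) < 2:  # forced minimal stub so the polyline is valid
            pts.append(start + 0.5 * direction)
            p = pts[-1]

        gen_is_leaf = gen >= spec.vessel_generations
        end_kind = "endpoint" if gen_is_leaf else "bifurcation"
        end_node = next_node
        nodes[end_node] = Node(id=end_node, position=p, kind=end_kind)
        next_node += 1
        bid = next_branch
        next_branch += 1
        branches[bid] = Branch(
            id=bid,
            points=np.asarray(pts),
            start_node=start_node,
            end_node=end_node,
        )
        radii[bid] = max(1.0, spec.root_radius_mm * spec.radius_taper ** (gen - 1))

        if not gen_is_leaf:
            u = _perpendicular(direction, rng)
            a1 = np.deg2rad(rng.uniform(*spec.branching_angle_deg))
            a2 = np.deg2rad(rng.uniform(*spec.branching_angle_deg))
            for child_dir in (
                _rotate(direction, u, +a1),
                _rotate(direction, u, -a2),
            ):
                stack.append((p, child_dir / np.linalg.norm(child_dir), gen + 1, end_node))

    graph = CenterlineGraph(nodes=nodes, branches=branches, root_node=0)
    remap = canonicalize_branch_ids(graph)
    radii = {remap[b]: r for b, r in radii.items()}
    mask = _rasterize_tree(graph, radii, spec)
    return graph, VolumeImage(mask, spec.voxel_spacing_mm)


def _rasterize_tree(
    graph: CenterlineGraph, radii: dict[int, float], spec: PhantomSpec
) -> np.ndarray:
    sp = np.asarray(spec.voxel_spacing_mm)
    shape = spec.grid_shape
    mask = np.zeros(shape, dtype=bool)
    step = 0.5 * float(sp.min())
    from .graph import densify_polyline

    for bid, br in graph.branches.items():
        r = radii.get(bid, 1.0)
        for p in densify_polyline(br.points, step):
            # stamp a ball centered on the voxel nearest the centerline point:
            # the center voxel is always marked (tube stays 26-connected even
            # when r < voxel size) and cross-sections are odd and symmetric,
            # which thinning reduces to a stable one-voxel centerline
            # (even-width tubes have no stable medial axis and can vanish)
            c = np.round(p / sp).astype(int)
            if np.any(c < 0) or np.any(c >= shape):
                continue
            mask[tuple(c)] = True
            reach = np.floor(r / sp).astype(int)
            lo = np.maximum(c - reach, 0)
            hi = np.minimum(c + reach + 1, shape)
            ii, jj, kk = np.meshgrid(
                np.arange(lo[0], hi[0]),
                np.arange(lo[1], hi[1]),
                np.arange(lo[2], hi[2]),
                indexing="ij",
            )
            offs = np.stack([ii, jj, kk], axis=-1) - c
            inside = np.sum((offs * sp) ** 2, axis=-1) <= r**2
            mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= inside
    return mask


# ---------------------------------------------------------------------------
# activity and counts
# ---------------------------------------------------------------------------


def make_activity_truth(
    liver_mask: np.ndarray,
    tumor_union: np.ndarray,
    lung_mask: np.ndarray,
    true_TN: float,
    true_lung_shunt: float,
) -> np.ndarray:
    """Piecewise-uniform relative activity density.

    Unit density in normal liver, ``true_TN`` in tumors, and a uniform lung
    density fixed so the lung fraction of (lung + liver) activity equals
    ``true_lung_shunt`` exactly.
    """
    liver = np.asarray(liver_mask, dtype=bool)
    tumor = np.asarray(tumor_union, dtype=bool)
    lung = np.asarray(lung_mask, dtype=bool)
    if not liver.any():
        raise InvalidSpecError("liver mask is empty")
    if true_TN != 1.0 and not tumor.any():
        raise InvalidSpecError("true_TN != 1 requested but no tumor voxels exist")
    if not (0.0 <= true_lung_shunt < 1.0):
        raise InvalidSpecError("true_lung_shunt must lie in [0, 1)")
    if np.any(liver & lung):
        raise InvalidSpecError("lung and liver masks overlap")

    act = np.zeros(liver.shape, dtype=float)
    normal = liver & ~tumor
    act[normal] = 1.0
    act[tumor & liver] = float(true_TN)
    liver_total = float(act.sum())
    if true_lung_shunt > 0:
        if not lung.any():
            raise InvalidSpecError("nonzero lung shunt requested but lung mask is empty")
        lung_total = true_lung_shunt / (1.0 - true_lung_shunt) * liver_total
        act[lung] = lung_total / lung.sum()
    return act


def simulate_spect(
    activity_truth: np.ndarray,
    spacing,
    psf_fwhm_mm: float,
    total_counts: int,
    seed: int | np.random.Generator | None = 0,
    poisson: bool = True,
) -> np.ndarray:
    """SPECT-like count image from a relative activity distribution.

    The activity is normalized to ``total_counts``, convolved with an
    anisotropy-aware Gaussian (per-axis sigma = FWHM / (2 sqrt(2 ln 2)) /
    spacing, zero-padded boundaries), then Poisson-sampled.  With
    ``poisson=False`` the blurred expectation image is returned (floats).
    """
    if psf_fwhm_mm < 0:
        raise InvalidSpecError("psf_fwhm_mm must be >= 0")
    if total_counts <= 0:
        raise InvalidSpecError("total_counts must be > 0")
    act = np.asarray(activity_truth, dtype=float)
    total = act.sum()
    if total <= 0:
        raise InvalidSpecError("activity distribution has no counts")
    expected = act * (float(total_counts) / total)
    if psf_fwhm_mm > 0:
        sigma_vox = [
            psf_fwhm_mm * FWHM_TO_SIGMA / s for s in np.asarray(spacing, dtype=float)
        ]
        expected = ndimage.gaussian_filter(expected, sigma=sigma_vox, mode="constant")
    if not poisson:
        return expected
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(expected).astype(np.int64)


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


def generate(spec: PhantomSpec) -> PhantomBundle:
    """Generate a complete phantom bundle from a spec (fully seed-determined)."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    sp = spec.voxel_spacing_mm

    liver = spec.liver_mask()
    lung = spec.lung_mask()
    tumors = spec.tumor_masks()
    tumor_union = np.zeros(spec.grid_shape, dtype=bool)
    for t in tumors:
        if not (t <= liver).all():
            raise InvalidSpecError("a tumor mask leaves the liver mask")
        tumor_union |= t
    if np.any(liver & lung):
        raise InvalidSpecError("lung slab intersects the liver ellipsoid")

    graph, vessel_mask = make_vessel_tree(spec, rng)
    b2t, names = group_branches(graph, generation=spec.grouping_generation)
    territory_truth = assign_territories(
        liver & ~tumor_union, graph, sp, branch_to_territory=b2t, territory_names=names
    )

    activity = make_activity_truth(
        liver, tumor_union, lung, spec.true_TN, spec.true_lung_shunt
    )
    counts = simulate_spect(
        activity, sp, spec.psf_fwhm_mm, spec.total_counts, seed=rng, poisson=True
    )

    return PhantomBundle(
        spec=spec,
        liver_mask=VolumeImage(liver, sp),
        lung_mask=VolumeImage(lung, sp),
        tumor_masks=[VolumeImage(t, sp) for t in tumors],
        vessel_mask=vessel_mask,
        centerline_truth=graph,
        territory_truth=territory_truth,
        activity_truth=VolumeImage(activity, sp),
        count_image=VolumeImage(counts, sp),
        branch_to_territory=b2t,
    )


def small_spec(seed: int = 0, grid: int = 32, generations: int = 3) -> PhantomSpec:
    """A compact phantom on a ``grid``^3 lattice, for fast tests and oracles."""
    s = 4.795
    extent = grid * s
    c = extent / 2.0
    return PhantomSpec(
        grid_shape=(grid, grid, grid),
        voxel_spacing_mm=(s, s, s),
        liver_center_mm=(c, c, c * 0.7),
        liver_semiaxes_mm=(0.42 * extent, 0.32 * extent, 0.24 * extent),
        # lung slab kept >= 3 sigma of the 6-mm PSF away from the grid edge
        # so constant-zero blurring loses no counts from the field of view
        lung_box_mm=(
            (0.2 * extent, 0.2 * extent, 0.72 * extent),
            (0.8 * extent, 0.8 * extent, 0.88 * extent),
        ),
        vessel_root_mm=(c, c - 0.29 * extent, c * 0.7),
        vessel_generations=generations,
        segment_length_mm=(0.10 * extent, 0.16 * extent),
        tumors=((c + 0.12 * extent, c + 0.10 * extent, c * 0.7, 0.065 * extent),),
        rng_seed=seed,
    )


def with_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    """Copy of a spec with a different RNG seed."""
    return replace(spec, rng_seed=seed)
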