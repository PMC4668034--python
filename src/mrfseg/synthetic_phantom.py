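"""Synthetic anisotropic co-culture phantoms with voxel-level ground truth.

The generator emulates the statistical structure of two-channel confocal
stacks of tumour/fibroblast co-cultures: roughly spherical tumour organoids
in the red channel and thin curvilinear CAF strands in the green channel,
both textured (i.i.d. Gaussian speckle) with per-object mean intensities
drawn at random — the intensity heterogeneity the entropy filter is there to
absorb — on a smooth low-noise background, with strong z-anisotropy
(default 10 um between slices vs 0.5 um pixels, ratio 20).

Geometry is built in physical micrometre coordinates and rasterized onto the
voxel grid, so an organoid of radius 20 um spans ~4 slices but ~80 in-plane
pixels, as in the real stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io_stack import CAF, TUMOUR, ImageStack, LabelMap, VoxelSpacing


@dataclass
class PhantomSpec:
    """Parameters of a synthetic co-culture stack.

    Defaults give a 12x128x128 stack (64 x 64 um in plane, 110 um deep) with
    two organoids and three multicellular CAF strands, separable by local
    entropy (textured foreground vs smooth background) but not by a single
    global intensity threshold (per-object means vary widely).
    """

    shape: tuple[int, int, int] = (12, 128, 128)
    spacing: VoxelSpacing = field(default_factory=lambda: VoxelSpacing(10.0, 0.5, 0.5))
    n_organoids: int = 2
    organoid_radius_range: tuple[float, float] = (10.0, 18.0)   # um
    n_strands: int = 3
    strand_radius: float = 5.0        # um; multicellular strands are ~cell-sized thick
    strand_steps: int = 60
    strand_step_length: float = 1.5   # um per random-walk step
    #: per-object mean intensities span dim-to-bright: weakly fluorescent
    #: structures barely above background are the case texture separates
    #: but a global intensity threshold does not
    fg_mean_range: tuple[float, float] = (45.0, 180.0)
    bg_mean: float = 30.0
    fg_texture_sd: float = 25.0
    bg_sd: float = 2.0
    contact_fraction: float = 0.3
    min_gap: float = 2.0              # um clearance for non-contact strands
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_organoids < 0 or self.n_strands < 0:
            raise ValueError("object counts must be >= 0")
        if min(self.organoid_radius_range) <= 0 or self.strand_radius <= 0:
            raise ValueError("radii must be positive")
        for v in (*self.fg_mean_range, self.bg_mean):
            if not 0 <= v <= 255:
                raise ValueError("mean intensities must lie in [0, 255]")
        if not self.fg_texture_sd > self.bg_sd:
            raise ValueError("texture separability requires fg_texture_sd > bg_sd")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["spacing"] = [self.spacing.dz, self.spacing.dy, self.spacing.dx]
        return d


_MAX_PLACEMENT_ATTEMPTS = 100


def _physical_grids(shape, spacing):
    nz, ny, nx = shape
    z = np.arange(nz) * spacing.dz
    y = np.arange(ny) * spacing.dy
    x = np.arange(nx) * spacing.dx
    return np.meshgrid(z, y, x, indexing="ij", sparse=True)


def _place_organoids(spec: PhantomSpec, rng) -> list[tuple[np.ndarray, float]]:
    """Draw non-overlapping sphere centres/radii in physical coordinates."""
    nz, ny, nx = spec.shape
    extent = np.array([(nz - 1) * spec.spacing.dz, (ny - 1) * spec.spacing.dy,
                       (nx - 1) * spec.spacing.dx])
    spheres: list[tuple[np.ndarray, float]] = []
    for _ in range(spec.n_organoids):
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            r = rng.uniform(*spec.organoid_radius_range)
            # keep the sphere inside the imaged volume in-plane; allow it to
            # poke out in z, as real organoids extend past the imaged depth
            lo = np.array([0.0, r, r])
            hi = np.array([extent[0], extent[1] - r, extent[2] - r])
            if (hi < lo).any():
                continue
            c = rng.uniform(lo, hi)
            if all(np.linalg.norm(c - c2) > r + r2 for c2, r2 in spheres):
                spheres.append((c, r))
                break
        else:
            raise RuntimeError("could not place organoid after "
                               f"{_MAX_PLACEMENT_ATTEMPTS} attempts")
    return spheres


def _rasterize_spheres(spheres, shape, spacing) -> tuple[np.ndarray, np.ndarray]:
    """TUMOUR mask plus per-voxel organoid index (-1 outside)."""
    zz, yy, xx = _physical_grids(shape, spacing)
    mask = np.zeros(shape, dtype=bool)
    index = np.full(shape, -1, dtype=np.int32)
    for k, (c, r) in enumerate(spheres):
        inside = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= r**2
        index[inside & ~mask] = k
        mask |= inside
    return mask, index


def _strand_polyline(spec: PhantomSpec, rng, start: np.ndarray) -> np.ndarray:
    """Random-walk polyline in physical coordinates, mostly in-plane."""
    nz, ny, nx = spec.shape
    extent = np.array([(nz - 1) * spec.spacing.dz, (ny - 1) * spec.spacing.dy,
                       (nx - 1) * spec.spacing.dx])
    points = [start]
    direction = rng.normal(size=3)
    direction[0] *= 0.2   # strands spread laterally, little z drift
    direction /= np.linalg.norm(direction)
    for _ in range(spec.strand_steps):
        turn = rng.normal(scale=0.4, size=3)
        turn[0] *= 0.2
        direction = direction + turn
        direction /= np.linalg.norm(direction)
        nxt = points[-1] + direction * spec.strand_step_length
        # reflect off the volume faces
        for ax in range(3):
            if nxt[ax] < 0:
                nxt[ax] = -nxt[ax]
                direction[ax] = -direction[ax]
            elif nxt[ax] > extent[ax]:
                nxt[ax] = 2 * extent[ax] - nxt[ax]
                direction[ax] = -direction[ax]
        points.append(nxt)
    return np.array(points)


def _rasterize_polyline(polyline: np.ndarray, radius: float, shape,
                        spacing) -> np.ndarray:
    """Voxels within ``radius`` (um) of any polyline vertex.

    Vertices are ~1.5 um apart, well under the 5 um default radius, so the
    union of vertex balls is an adequate tube rasterization.
    """
    zz, yy, xx = _physical_grids(shape, spacing)
    mask = np.zeros(shape, dtype=bool)
    for p in polyline:
        mask |= ((zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2) <= radius**2
    return mask


def _dilate6(mask: np.ndarray) -> np.ndarray:
    """6-neighbour dilation (used to enforce face-adjacency clearance)."""
    out = mask.copy()
    for ax in range(3):
        out[tuple(slice(1, None) if a == ax else slice(None) for a in range(3))] |= \
            mask[tuple(slice(None, -1) if a == ax else slice(None) for a in range(3))]
        out[tuple(slice(None, -1) if a == ax else slice(None) for a in range(3))] |= \
            mask[tuple(slice(1, None) if a == ax else slice(None) for a in range(3))]
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[ImageStack, LabelMap]:
    """Generate a two-channel phantom stack and its ground-truth label map.

    Deterministic given ``spec.seed``.  A ``contact_fraction`` of the strands
    is seeded on organoid surfaces (touching); the rest must keep a face-
    adjacency clearance from every tumour voxel, so with
    ``contact_fraction=0`` the ground truth has zero tumour--CAF contact.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing

    spheres = _place_organoids(spec, rng)
    tumour_mask, organoid_idx = _rasterize_spheres(spheres, shape, spacing)
    tumour_halo = _dilate6(tumour_mask)

    n_contact = int(round(spec.contact_fraction * spec.n_strands))
    strand_masks: list[np.ndarray] = []
    extent = np.array([(shape[0] - 1) * spacing.dz, (shape[1] - 1) * spacing.dy,
                       (shape[2] - 1) * spacing.dx])
    for s in range(spec.n_strands):
        want_contact = s < n_contact and spheres
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            if want_contact:
                c, r = spheres[rng.integers(len(spheres))]
                u = rng.normal(size=3)
                u[0] *= 0.2
                u /= np.linalg.norm(u)
                start = np.clip(c + u * (r + spec.strand_radius), 0, extent)
            else:
                start = rng.uniform(np.zeros(3), extent)
            mask = _rasterize_polyline(_strand_polyline(spec, rng, start),
                                       spec.strand_radius, shape, spacing)
            if not mask.any():
                continue
            if not want_contact and (mask & tumour_halo).any():
                continue
            strand_masks.append(mask)
            break
        else:
            raise RuntimeError("could not place strand after "
                               f"{_MAX_PLACEMENT_ATTEMPTS} attempts")

    labels = np.zeros(shape, dtype=np.uint8)
    caf_mask = np.zeros(shape, dtype=bool)
    strand_idx = np.full(shape, -1, dtype=np.int32)
    for k, m in enumerate(strand_masks):
        strand_idx[m & ~caf_mask] = k
        caf_mask |= m
    caf_mask &= ~tumour_mask   # tumour takes precedence where tubes overlap
    labels[caf_mask] = CAF
    labels[tumour_mask] = TUMOUR

    red = rng.normal(spec.bg_mean, spec.bg_sd, size=shape)
    green = rng.normal(spec.bg_mean, spec.bg_sd, size=shape)
    for k in range(len(spheres)):
        mean_k = rng.uniform(*spec.fg_mean_range)
        sel = organoid_idx == k
        red[sel] = mean_k + rng.normal(0.0, spec.fg_texture_sd, size=int(sel.sum()))
    for k in range(len(strand_masks)):
        mean_k = rng.uniform(*spec.fg_mean_range)
        sel = (strand_idx == k) & caf_mask
        green[sel] = mean_k + rng.normal(0.0, spec.fg_texture_sd, size=int(sel.sum()))

    data = np.stack([red, green], axis=-1)
    data = np.floor(np.clip(data, 0, 255) + 0.5).astype(np.uint8)
    return (ImageStack(data, spacing, ["red", "green"]),
            LabelMap(labels, spacing))


def generate_greyscale_phantom(spec: PhantomSpec) -> tuple[ImageStack, LabelMap]:
    """Single-channel, single-slice phantom: textured discs vs smooth background.

    Exercises the single-channel 4-neighbour mode.  Truth labels are binary
    (0 background, 1 foreground).
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape[1], spec.shape[2]
    shape = (1, ny, nx)
    spacing = VoxelSpacing(spec.spacing.dz, spec.spacing.dy, spec.spacing.dx)
    extent = np.array([0.0, (ny - 1) * spacing.dy, (nx - 1) * spacing.dx])

    discs: list[tuple[np.ndarray, float]] = []
    for _ in range(spec.n_organoids):
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            r = rng.uniform(*spec.organoid_radius_range)
            lo = np.array([0.0, r, r])
            hi = np.array([0.0, extent[1] - r, extent[2] - r])
            if (hi < lo).any():
                continue
            c = rng.uniform(lo, hi + 1e-12)
            if all(np.linalg.norm(c - c2) > r + r2 for c2, r2 in discs):
                discs.append((c, r))
                break
        else:
            raise RuntimeError("could not place disc after "
                               f"{_MAX_PLACEMENT_ATTEMPTS} attempts")

    mask, disc_idx = _rasterize_spheres(discs, shape, spacing)
    labels = mask.astype(np.uint8)

    img = rng.normal(spec.bg_mean, spec.bg_sd, size=shape)
    for k in range(len(discs)):
        mean_k = rng.uniform(*spec.fg_mean_range)
        sel = disc_idx == k
        img[sel] = mean_k + rng.normal(0.0, spec.fg_texture_sd, size=int(sel.sum()))
    data = np.floor(np.clip(img, 0, 255) + 0.5).astype(np.uint8)[..., None]
    return (ImageStack(data, spacing, ["grey"]), LabelMap(labels, spacing))
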