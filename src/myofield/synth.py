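"""Synthetic bipennate-muscle geometry, fibre field and streamline generator.

Real inputs for this pipeline are subject-specific (MRI segmentation, DTI
tractography).  This module generates a fully synthetic stand-in with known
ground truth: a fusiform solid of revolution around the ``e2 = y`` axis with
flat tendon end discs, a thin planar aponeurosis sheet on the ``z = 0``
mid-plane extending to the distal muscle-tendon junction, an analytic
feather-pattern fibre field with configurable pennation angle, and
streamlines integrated through that field from surface seeds with optional
angular noise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.interpolate import PchipInterpolator

from .aponeurosis import BinaryVoxelMask
from .mesh import REGION_IDS, TaggedTetMesh
from .tract_fields import E2_DEFAULT, StreamlineSet, VoxelGrid

__all__ = [
    "BipennateSpec",
    "make_bipennate_mesh",
    "analytic_bipennate_field",
    "synth_streamlines",
    "true_sheet_mask",
    "default_grid",
]


@dataclass
class BipennateSpec:
    """Parameters of the synthetic bipennate muscle (lengths in mm).

    The muscle belly spans ``[tendon_length_proximal,
    total_length - tendon_length_distal]`` along the ``y`` axis; the
    aponeurosis sheet occupies the slab ``|z| <= sheet_thickness/2`` from
    ``apo_start_fraction * total_length`` to the distal muscle-tendon
    junction, over the anterior part ``u >= apo_anterior_limit`` of the
    cross-section (``u`` is the normalised anterior-posterior coordinate,
    +1 = anterior surface).
    """

    total_length: float = 160.0
    tendon_length_proximal: float = 20.0
    tendon_length_distal: float = 20.0
    max_radius: float = 15.0
    tendon_radius: float = 6.0
    sheet_thickness: float = 3.0
    apo_start_fraction: float = 0.35
    apo_anterior_limit: float = -0.6
    pennation_deg: float = 15.0
    element_size: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pennation_deg < 90.0):
            raise ValueError("pennation angle must be in (0, 90) degrees")
        for name in (
            "total_length",
            "tendon_length_proximal",
            "tendon_length_distal",
            "max_radius",
            "tendon_radius",
            "sheet_thickness",
            "element_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.muscle_start >= self.muscle_end:
            raise ValueError("tendons overlap: no muscle belly left")
        if self.apo_start < self.muscle_start:
            raise ValueError("aponeurosis must start inside the muscle belly")
        if self.element_size > 2.0 * self.sheet_thickness + 1e-12:
            raise ValueError(
                "element size too large to resolve the aponeurosis sheet"
            )

    @property
    def muscle_start(self) -> float:
        return self.tendon_length_proximal

    @property
    def muscle_end(self) -> float:
        return self.total_length - self.tendon_length_distal

    @property
    def apo_start(self) -> float:
        return self.apo_start_fraction * self.total_length

    def radius(self, y) -> np.ndarray:
        """Fusiform radius profile: monotone spline through control points."""
        y = np.asarray(y, dtype=float)
        ms, me = self.muscle_start, self.muscle_end
        mid = 0.5 * (ms + me)
        rt, rm = self.tendon_radius, self.max_radius
        knots = np.array(
            [0.0, ms, ms + 0.25 * (mid - ms), mid, me - 0.25 * (me - mid), me,
             self.total_length]
        )
        vals = np.array(
            [rt, rt, rt + 0.75 * (rm - rt), rm, rt + 0.75 * (rm - rt), rt, rt]
        )
        return PchipInterpolator(knots, vals)(np.clip(y, 0.0, self.total_length))

    def to_dict(self) -> dict:
        return asdict(self)


def _segment_coords(breaks: np.ndarray, target: float) -> np.ndarray:
    """1D grid hitting every break point with roughly uniform spacing."""
    out = [breaks[0]]
    for a, b in zip(breaks[:-1], breaks[1:]):
        n = max(int(round((b - a) / target)), 1)
        out.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(out)


_KUHN_PERMS = [
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)
]


def _square_to_disc(u: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map the reference square [-1,1]^2 onto the unit disc.

    Points scale radially by max(|u|,|w|)/||(u,w)||, so the square boundary
    lands on the circle while the planes u=0 and w=0 stay flat.
    """
    m = np.maximum(np.abs(u), np.abs(w))
    rho = np.hypot(u, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(rho > 0, m / np.where(rho > 0, rho, 1.0), 0.0)
    return u * s, w * s


def make_bipennate_mesh(spec: BipennateSpec) -> TaggedTetMesh:
    """Build the tagged tetrahedral mesh of the synthetic bipennate muscle.

    A structured hexahedral grid over the reference block
    ``(u, y, w) in [-1,1] x [0,L] x [-1,1]`` is mapped cross-section-wise
    onto the fusiform solid of revolution and split into tetrahedra (Kuhn
    subdivision, conforming across cells).  The ``w`` grid always contains
    the sheet planes ``-t/2, 0, +t/2`` so the aponeurosis is exactly two
    element layers thin with mid-plane nodes available for boundary
    conditions.  Deterministic: no randomness enters the construction.
    """
    L = spec.total_length
    # reference half-thickness so the physical sheet is ~sheet_thickness at
    # the belly; thickness scales with the local radius like every other
    # cross-section length
    th = 0.5 * spec.sheet_thickness / spec.max_radius
    if th >= 0.5:
        raise ValueError("sheet too thick for the cross-section")

    n_side = max(int(round((1.0 - th) / (spec.element_size / spec.max_radius))), 2)
    outer = np.linspace(th, 1.0, n_side + 1)
    w_coords = np.concatenate([-outer[::-1], [0.0], outer])
    u_coords = _segment_coords(
        np.array([-1.0, spec.apo_anterior_limit, 1.0]),
        spec.element_size / spec.max_radius,
    )
    y_coords = _segment_coords(
        np.array([0.0, spec.muscle_start, spec.apo_start, spec.muscle_end, L]),
        spec.element_size,
    )

    nu, ny, nw = len(u_coords), len(y_coords), len(w_coords)
    U, Y, W = np.meshgrid(u_coords, y_coords, w_coords, indexing="ij")
    r = spec.radius(Y)
    X, Z = _square_to_disc(U, W)
    nodes = np.stack([(X * r).ravel(), Y.ravel(), (Z * r).ravel()], axis=1)

    def nid(i, j, k):
        return (i * ny + j) * nw + k

    # Kuhn subdivision of every hex cell into 6 tets sharing the main
    # diagonal; identical in every cell, hence conforming
    I, J, K = np.meshgrid(
        np.arange(nu - 1), np.arange(ny - 1), np.arange(nw - 1), indexing="ij"
    )
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corner = {
        (a, b, c): nid(I + a, J + b, K + c)
        for a in (0, 1) for b in (0, 1) for c in (0, 1)
    }
    tets = []
    for perm in _KUHN_PERMS:
        path = [(0, 0, 0)]
        for ax in perm:
            nxt = list(path[-1])
            nxt[ax] += 1
            path.append(tuple(nxt))
        tets.append(np.stack([corner[p] for p in path], axis=1))
    elements = np.concatenate(tets, axis=0)

    mesh = TaggedTetMesh(
        nodes=nodes,
        elements=elements,
        region=np.zeros(len(elements), dtype=np.int64),
    )
    mesh.fix_orientation()

    # region tagging by centroid in reference (u, y, w) coordinates
    ref = np.stack([U.ravel(), Y.ravel(), W.ravel()], axis=1)
    cref = ref[mesh.elements].mean(axis=1)
    cy = cref[:, 1]
    region = np.full(len(elements), REGION_IDS["muscle"], dtype=np.int64)
    region[cy < spec.muscle_start] = REGION_IDS["tendon_proximal"]
    region[cy > spec.muscle_end] = REGION_IDS["tendon_distal"]
    in_sheet = (
        (np.abs(cref[:, 2]) < th)
        & (cy >= spec.apo_start)
        & (cy <= spec.muscle_end)
        & (cref[:, 0] >= spec.apo_anterior_limit)
    )
    region[in_sheet] = REGION_IDS["aponeurosis"]
    mesh.region = region

    # face sets
    faces, owner = mesh.boundary_faces()
    fy = mesh.nodes[faces][:, :, 1]
    tol = 1e-9 * L
    inlet = faces[np.all(fy < tol, axis=1)]
    outlet = faces[np.all(fy > L - tol, axis=1)]
    lateral = np.all(fy >= tol, axis=1) & np.all(fy <= L - tol, axis=1)
    muscle_surface = faces[lateral & (region[owner] == REGION_IDS["muscle"])]

    # midline strip of the sheet: interior triangles on the w = 0 plane
    # bounded by aponeurosis elements
    apo_faces = _midplane_faces(mesh, ref, spec, th)
    mesh.face_sets = {
        "inlet": inlet,
        "outlet": outlet,
        "muscle_surface": muscle_surface,
        "aponeurosis_surface": apo_faces,
    }
    mesh.validate()
    return mesh


def _midplane_faces(mesh, ref, spec, th) -> np.ndarray:
    from .mesh import _all_faces

    faces, owner = _all_faces(mesh.elements)
    apo_owner = mesh.region[owner] == REGION_IDS["aponeurosis"]
    w = ref[:, 2]
    on_plane = np.all(np.abs(w[faces]) < 1e-12, axis=1)
    sel = faces[apo_owner & on_plane]
    if len(sel) == 0:
        return sel
    key = np.sort(sel, axis=1)
    _, idx = np.unique(key, axis=0, return_index=True)
    return sel[np.sort(idx)]


def analytic_bipennate_field(
    points: np.ndarray, spec: BipennateSpec, tol_mm: float = 0.0
) -> np.ndarray:
    """Ground-truth feather fibre field at points inside the solid.

    In the muscle belly the fibre direction is ``e2`` tilted by the
    pennation angle towards the sheet mid-plane (``-sign(z) e_z``
    component), mirror-symmetric across the plane; inside tendons and the
    aponeurosis slab it is axial.  Raises for points outside the solid.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    y, z = pts[:, 1], pts[:, 2]
    r = spec.radius(y)
    rad = np.hypot(pts[:, 0], z)
    outside = (
        (y < -1e-9 - tol_mm)
        | (y > spec.total_length + 1e-9 + tol_mm)
        | (rad > r * (1 + 1e-9) + tol_mm)
    )
    if np.any(outside):
        raise ValueError("point(s) outside the muscle solid")
    theta = np.radians(spec.pennation_deg)
    tendon = (y < spec.muscle_start) | (y > spec.muscle_end)
    # full pennation tilt outside the sheet slab; inside it the tilt decays
    # linearly to zero at the mid-plane, so integrated tracks converge onto
    # the sheet instead of skimming along its surface
    scale = np.where(
        tendon, 0.0, np.minimum(np.abs(z) / (0.5 * spec.sheet_thickness), 1.0)
    )
    theta_eff = theta * scale
    v = np.zeros_like(pts)
    v[:, 1] = np.cos(theta_eff)
    v[:, 2] = -np.sign(z) * np.sin(theta_eff)
    return v if points.ndim > 1 else v[0]


def synth_streamlines(
    spec: BipennateSpec,
    n: int = 4000,
    step_mm: float = 0.5,
    noise_deg: float = 0.0,
    seed: int | None = None,
    seeds: np.ndarray | None = None,
    max_length_mm: float = 200.0,
    capture_mm: float = 0.3,
) -> StreamlineSet:
    """Integrate feather-pattern streamlines through the analytic field.

    Fibres of a bipennate muscle insert along the whole aponeurosis, so
    insertion points are drawn uniformly over the sheet (axial position,
    anterior-posterior position, side of the plane) at a small standoff
    ``capture_mm`` from the mid-plane, and each track is integrated
    backwards through the field until it leaves the muscle belly; the
    reversed path is the surface-to-sheet fibre track.  Per-step angular
    noise of scale ``noise_deg`` (Gaussian tangential perturbation, a
    von-Mises-type dispersion for small angles) is applied to the step
    direction.  If explicit ``seeds`` are given, tracks are instead
    integrated forwards from them until reaching the sheet mid-plane, a
    boundary, or ``max_length_mm``.
    """
    if n < 1:
        raise ValueError("need at least one streamline")
    rng = np.random.default_rng(seed)
    theta_noise = np.radians(noise_deg)
    max_steps = int(np.ceil(max_length_mm / step_mm))

    if seeds is None:
        y_ins = rng.uniform(spec.apo_start, spec.muscle_end - 0.5, n)
        r_ins = spec.radius(y_ins)
        x_ins = r_ins * rng.uniform(spec.apo_anterior_limit, 0.95, n)
        side = rng.choice([-1.0, 1.0], n)
        start = np.stack([x_ins, y_ins, side * capture_mm], axis=1)
        direction = -1.0
    else:
        start = np.atleast_2d(np.asarray(seeds, dtype=float))
        n = len(start)
        direction = 1.0

    pos = start.copy()
    active = np.ones(n, dtype=bool)
    paths = [[p.copy()] for p in pos]

    for _ in range(max_steps):
        if not active.any():
            break
        ai = np.flatnonzero(active)
        d = direction * analytic_bipennate_field(pos[ai], spec)
        if theta_noise > 0:
            pert = rng.normal(0.0, theta_noise, size=(len(ai), 3))
            pert -= d * np.sum(pert * d, axis=1, keepdims=True)
            d = d + pert
            d /= np.linalg.norm(d, axis=1, keepdims=True)
        nxt = pos[ai] + step_mm * d
        y, z = nxt[:, 1], nxt[:, 2]
        rad = np.hypot(nxt[:, 0], z)
        out = (
            (y <= spec.muscle_start)
            | (y >= spec.muscle_end)
            | (rad >= spec.radius(y))
        )
        stop = out
        if direction > 0:
            hit_sheet = (
                (np.abs(z) <= capture_mm)
                & (y >= spec.apo_start)
                & (nxt[:, 0] >= spec.apo_anterior_limit * spec.radius(y))
            )
            stop = out | hit_sheet
        for j, idx in enumerate(ai):
            if not out[j]:
                paths[idx].append(nxt[j].copy())
        pos[ai[~stop]] = nxt[~stop]
        active[ai[stop]] = False

    if direction < 0:
        tracks = [np.asarray(p)[::-1] for p in paths if len(p) >= 2]
    else:
        tracks = [np.asarray(p) for p in paths if len(p) >= 2]
    return StreamlineSet(tracks, validate=False)


def map_analytic_field(
    mesh: TaggedTetMesh,
    spec: BipennateSpec,
    pennation_deg: float | None = None,
):
    """Analytic fibre field sampled at element centroids.

    ``pennation_deg`` overrides the spec's pennation angle, making it easy
    to build steeper/flatter fields on the same mesh.  A geometric
    tolerance of half the element size absorbs faceting of the curved
    surface.
    """
    from .thermal import ElementFibreField

    if pennation_deg is not None:
        spec = BipennateSpec(**{**spec.to_dict(), "pennation_deg": pennation_deg})
    v = analytic_bipennate_field(
        mesh.centroids(), spec, tol_mm=0.5 * spec.element_size
    )
    return ElementFibreField(vectors=v, source="analytic")


def default_grid(spec: BipennateSpec, spacing=(2.625, 6.25, 2.625)) -> VoxelGrid:
    """Voxel grid covering the solid, slice axis along the muscle axis.

    In-plane spacing mirrors clinical DTI resolution (2.625 mm) with coarse
    slices along the axis; the grid is aligned so the sheet mid-plane
    ``z = 0`` runs through voxel centres.
    """
    R = spec.max_radius
    return VoxelGrid.from_bounds(
        lo=(-R, 0.0, -R),
        hi=(R, spec.total_length, R),
        spacing=spacing,
        e2=E2_DEFAULT,
        align_point=(0.0, 0.5 * spec.total_length, 0.0),
    )


def true_sheet_mask(spec: BipennateSpec, grid: VoxelGrid) -> BinaryVoxelMask:
    """Ground-truth aponeurosis voxel mask: centres inside the sheet slab."""
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    c = grid.centres(idx)
    x, y, z = c[:, 0], c[:, 1], c[:, 2]
    r = spec.radius(y)
    inside = (
        (np.abs(z) <= 0.5 * spec.sheet_thickness)
        & (y >= spec.apo_start)
        & (y <= spec.muscle_end)
        & (np.hypot(x, z) <= r)
        & (x >= spec.apo_anterior_limit * r)
    )
    return BinaryVoxelMask(grid, inside.reshape(grid.shape), tag="reference")
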