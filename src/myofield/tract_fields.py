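"""Per-voxel orientation, density and discrete-divergence fields from streamlines.

Fibre tractography delivers a set of polylines ("tracks") in world
millimetres.  In a pennate muscle the tracks converge onto the internal
aponeurosis, which therefore acts as a sink of the track vector field.  This
module rasterises a track set onto a voxel grid and produces the three maps
the aponeurosis detector consumes:

* ``K`` — fibre density: number of distinct tracks with a sample inside a
  sphere embedded in each voxel,
* ``a0`` — mean track orientation per voxel, sign-fixed along the muscle's
  principal axis ``e2``,
* ``D`` — discrete divergence: oriented tracks entering minus leaving each
  voxel (endpoint mode), or a central-difference divergence of ``a0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "StreamlineSet",
    "VoxelFieldSet",
    "compute_fa",
    "filter_streamlines",
    "resample_polyline",
    "voxel_fibre_count",
    "voxel_mean_orientation",
    "discrete_divergence",
]

E2_DEFAULT = np.array([0.0, 1.0, 0.0])


@dataclass
class VoxelGrid:
    """Axis-aligned voxel grid.

    Voxel ``(i, j, k)`` occupies the half-open box
    ``origin + spacing * [i, i+1) x [j, j+1) x [k, k+1)`` in world mm; its
    centre is ``origin + spacing * (ijk + 0.5)``.  ``e2`` is the unit vector
    of the muscle's principal axis used for orientation sign conventions.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (2.625, 2.625, 6.25)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    e2: np.ndarray = field(default_factory=lambda: E2_DEFAULT.copy())

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        self.e2 = np.asarray(self.e2, dtype=float)
        n = np.linalg.norm(self.e2)
        if not np.isfinite(n) or n == 0:
            raise ValueError("e2 must be a non-zero vector")
        self.e2 = self.e2 / n

    @property
    def affine(self) -> np.ndarray:
        """4x4 affine taking continuous index coordinates to world mm."""
        A = np.eye(4)
        A[:3, :3] = np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    @property
    def nifti_affine(self) -> np.ndarray:
        """Affine with the NIfTI convention (voxel centre at integer index)."""
        A = self.affine
        A[:3, 3] += 0.5 * np.asarray(self.spacing)
        return A

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_of(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel index per point (may fall outside the grid)."""
        return np.floor(self.world_to_index(points)).astype(np.int64)

    def inside(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return np.all((ijk >= 0) & (ijk < np.asarray(self.shape)), axis=1)

    def centres(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(self.spacing) * (
            np.atleast_2d(ijk) + 0.5
        )

    def ravel(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return np.ravel_multi_index(
            (ijk[:, 0], ijk[:, 1], ijk[:, 2]), self.shape
        )

    @classmethod
    def from_bounds(
        cls,
        lo,
        hi,
        spacing=(2.625, 2.625, 6.25),
        e2=E2_DEFAULT,
        margin_voxels: int = 1,
        align_point=None,
    ) -> "VoxelGrid":
        """Grid covering ``[lo, hi]`` with a margin.

        If ``align_point`` is given the origin is shifted so that the point
        lies exactly at the centre of some voxel; this keeps thin planar
        structures (e.g. the aponeurosis sheet) centred in one voxel layer
        rather than split across two.
        """
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        sp = np.asarray(spacing, dtype=float)
        origin = lo - margin_voxels * sp
        extent = hi + margin_voxels * sp - origin
        shape = np.maximum(np.ceil(extent / sp).astype(int), 1)
        if align_point is not None:
            p = np.asarray(align_point, dtype=float)
            # shift so that p - origin is (n + 0.5) * spacing for integer n
            frac = (p - origin) / sp - 0.5
            origin = origin + (frac - np.round(frac)) * sp
        return cls(tuple(shape), tuple(sp), tuple(origin), e2=np.asarray(e2))


class StreamlineSet:
    """Ordered collection of 3D polylines in world millimetres."""

    def __init__(self, streamlines, validate: bool = True):
        self._data = [np.asarray(s, dtype=float) for s in streamlines]
        if validate:
            for i, s in enumerate(self._data):
                if s.ndim != 2 or s.shape[1] != 3:
                    raise ValueError(f"streamline {i} is not an (N, 3) array")
                if len(s) < 2:
                    raise ValueError(f"streamline {i} has fewer than 2 points")
                if np.any(np.all(np.diff(s, axis=0) == 0.0, axis=1)):
                    raise ValueError(
                        f"streamline {i} has consecutive duplicate points"
                    )

    def __len__(self) -> int:
        return len(self._data)

    def __iter__(self):
        return iter(self._data)

    def __getitem__(self, i):
        return self._data[i]

    @property
    def streamlines(self) -> list[np.ndarray]:
        return self._data

    def lengths(self) -> np.ndarray:
        """Arc length of every streamline in mm."""
        return np.array(
            [np.sum(np.linalg.norm(np.diff(s, axis=0), axis=1)) for s in self]
        )

    def tangents(self, i: int) -> np.ndarray:
        """Unit segment tangents of streamline ``i``."""
        d = np.diff(self._data[i], axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)


@dataclass
class VoxelFieldSet:
    """Co-registered per-voxel maps sharing one grid."""

    grid: VoxelGrid
    orientation: np.ndarray  # (nx, ny, nz, 3), zero where count == 0
    count: np.ndarray  # (nx, ny, nz) int
    divergence: np.ndarray  # (nx, ny, nz) float
    valid: np.ndarray  # (nx, ny, nz) bool

    def __post_init__(self) -> None:
        sh = self.grid.shape
        if (
            self.orientation.shape != sh + (3,)
            or self.count.shape != sh
            or self.divergence.shape != sh
            or self.valid.shape != sh
        ):
            raise ValueError("field shapes do not match the grid")


def compute_fa(eigenvalues, prefactor: float = 0.5) -> float:
    """Fractional anisotropy of a diffusion tensor from its eigenvalues.

    ``FA = prefactor * sqrt(sum of squared pairwise eigenvalue differences)
    / sqrt(sum of squared eigenvalues)``.  The default prefactor is 1/2; the
    more common normalisation ``sqrt(1/2)`` can be requested via
    ``prefactor=np.sqrt(0.5)``.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected three eigenvalues")
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    den = np.sqrt(np.sum(lam**2, axis=-1))
    if np.any(den == 0):
        raise ValueError("FA undefined for an all-zero tensor")
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = np.sqrt((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2)
    out = prefactor * num / den
    return float(out) if out.ndim == 0 else out


def _max_turn_deg(points: np.ndarray) -> float:
    d = np.diff(points, axis=0)
    t = d / np.linalg.norm(d, axis=1, keepdims=True)
    if len(t) < 2:
        return 0.0
    c = np.clip(np.sum(t[:-1] * t[1:], axis=1), -1.0, 1.0)
    return float(np.degrees(np.max(np.arccos(c))))


def filter_streamlines(
    sset: StreamlineSet,
    fa_values=None,
    fa_range=(0.1, 0.5),
    max_turn_deg: float = 10.0,
    length_range_mm=(15.0, 200.0),
) -> StreamlineSet:
    """Track filtering: arc length, per-step turning angle and optional FA.

    ``fa_values`` is an optional sequence of per-point FA samples, one array
    per streamline; a track is kept only if every sample stays inside
    ``fa_range`` (inclusive).  Order is preserved.
    """
    if fa_values is not None and len(fa_values) != len(sset):
        raise ValueError("fa_values must have one entry per streamline")
    lo, hi = length_range_mm
    kept = []
    for i, s in enumerate(sset):
        length = np.sum(np.linalg.norm(np.diff(s, axis=0), axis=1))
        if not (lo <= length <= hi):
            continue
        if _max_turn_deg(s) > max_turn_deg:
            continue
        if fa_values is not None:
            fa = np.asarray(fa_values[i], dtype=float)
            if np.any(fa < fa_range[0]) or np.any(fa > fa_range[1]):
                continue
        kept.append(s)
    return StreamlineSet(kept, validate=False)


def resample_polyline(points: np.ndarray, step_mm: float = 0.5) -> np.ndarray:
    """Resample a polyline at a fixed arc-length step (endpoints kept)."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0.0:
        return points[:1].copy()
    n = max(int(np.ceil(total / step_mm)), 1)
    s = np.linspace(0.0, total, n + 1)
    out = np.empty((n + 1, 3))
    for k in range(3):
        out[:, k] = np.interp(s, arc, points[:, k])
    return out


def _sphere_samples(sset, grid, sphere_diameter_mm, resample_step_mm):
    """Per streamline: (sorted sample points, voxel flat id) of the samples
    that fall inside the embedded sphere of their containing voxel."""
    r = sphere_diameter_mm / 2.0
    if sphere_diameter_mm > min(grid.spacing) + 1e-12:
        raise ValueError(
            "sphere diameter exceeds the minimum voxel spacing; the sphere "
            "must fit inside the voxel"
        )
    for s in sset:
        pts = resample_polyline(s, resample_step_mm)
        ijk = grid.voxel_of(pts)
        ok = grid.inside(ijk)
        pts, ijk = pts[ok], ijk[ok]
        if len(pts) == 0:
            yield pts, np.empty(0, dtype=np.int64)
            continue
        d = np.linalg.norm(pts - grid.centres(ijk), axis=1)
        in_sphere = d <= r
        yield pts[in_sphere], grid.ravel(ijk[in_sphere])


def voxel_fibre_count(
    sset: StreamlineSet,
    grid: VoxelGrid,
    sphere_diameter_mm: float = 2.625,
    resample_step_mm: float = 0.5,
) -> np.ndarray:
    """Density map K: distinct streamlines per embedded voxel sphere.

    A streamline is counted at most once per voxel regardless of how many of
    its samples (or separate visits) fall inside the sphere.
    """
    K = np.zeros(grid.shape, dtype=np.int64).ravel()
    for _, flat in _sphere_samples(sset, grid, sphere_diameter_mm, resample_step_mm):
        if len(flat):
            K[np.unique(flat)] += 1
    return K.reshape(grid.shape)


def voxel_mean_orientation(
    sset: StreamlineSet,
    grid: VoxelGrid,
    sphere_diameter_mm: float = 2.625,
    resample_step_mm: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-voxel orientation with the axis sign convention.

    Per voxel the contribution of streamline k is the unit chord between its
    first and last sample inside the sphere (local tangent for a single
    sample).  The voxel vector is the plain mean of those unit vectors,
    sign-flipped as a whole so its ``e2`` component is non-negative; it is
    deliberately not re-normalised, so its norm (<= 1) measures intra-voxel
    orientation coherence.  Returns ``(orientation, count)``.
    """
    nvox = int(np.prod(grid.shape))
    acc = np.zeros((nvox, 3))
    cnt = np.zeros(nvox, dtype=np.int64)
    for pts, flat in _sphere_samples(sset, grid, sphere_diameter_mm, resample_step_mm):
        if len(flat) == 0:
            continue
        order = np.argsort(flat, kind="stable")
        flat_s, pts_s = flat[order], pts[order]
        uniq, start = np.unique(flat_s, return_index=True)
        stop = np.append(start[1:], len(flat_s))
        for v, a, b in zip(uniq, start, stop):
            # samples a:b are this streamline's visit(s) to the sphere of v,
            # in arc-length order (stable sort preserves it)
            chord = pts_s[b - 1] - pts_s[a]
            n = np.linalg.norm(chord)
            if n < 1e-12:
                # single sample (or closed loop): fall back to local tangent
                chord = _local_tangent(pts, order[a])
                n = np.linalg.norm(chord)
                if n < 1e-12:
                    continue
            acc[v] += chord / n
            cnt[v] += 1
    h = np.where(acc @ grid.e2 >= 0.0, 1.0, -1.0)
    with np.errstate(invalid="ignore"):
        mean = np.where(
            cnt[:, None] > 0, h[:, None] * acc / np.maximum(cnt[:, None], 1), 0.0
        )
    return mean.reshape(grid.shape + (3,)), cnt.reshape(grid.shape)


def _local_tangent(pts: np.ndarray, i: int) -> np.ndarray:
    if len(pts) < 2:
        return np.zeros(3)
    j = min(i + 1, len(pts) - 1)
    k = max(j - 1, 0)
    return pts[j] - pts[k]


def _orient_streamline(points: np.ndarray, e2: np.ndarray) -> np.ndarray:
    """Reverse the polyline if its end-to-end chord points against e2."""
    if (points[-1] - points[0]) @ e2 < 0.0:
        return points[::-1]
    return points


def discrete_divergence(
    sset: StreamlineSet,
    grid: VoxelGrid,
    mode: str = "endpoint",
    resample_step_mm: float = 0.5,
    orient: bool = True,
    orientation_field: np.ndarray | None = None,
    count: np.ndarray | None = None,
) -> np.ndarray:
    """Discrete divergence map D.

    ``endpoint`` mode counts, per voxel, oriented streamlines entering (+1)
    minus leaving (-1); a pass-through contributes 0, a track terminating
    inside contributes +1 and one originating inside -1.  Streamlines are
    first oriented so their end-to-end chord has a non-negative ``e2``
    component (disable with ``orient=False``).

    ``fd`` mode takes the central-difference divergence of the voxel
    orientation field (computed on the fly unless supplied), masked to zero
    where the density count vanishes.
    """
    if mode == "endpoint":
        D = np.zeros(int(np.prod(grid.shape)), dtype=np.int64)
        for s in sset:
            pts = resample_polyline(s, resample_step_mm)
            if orient:
                pts = _orient_streamline(pts, grid.e2)
            ijk = grid.voxel_of(pts)
            ins = grid.inside(ijk)
            # flat voxel id per sample; -1 marks "outside the grid"
            flat = np.where(ins, grid.ravel(np.where(ins[:, None], ijk, 0)), -1)
            # collapse consecutive repeats into the visited-voxel sequence
            keep = np.concatenate([[True], flat[1:] != flat[:-1]])
            seq = flat[keep]
            for a, b in zip(seq[:-1], seq[1:]):
                if a >= 0:
                    D[a] -= 1  # leaves a
                if b >= 0:
                    D[b] += 1  # enters b
        return D.reshape(grid.shape).astype(float)
    if mode == "fd":
        if orientation_field is None or count is None:
            orientation_field, count = voxel_mean_orientation(
                sset, grid, resample_step_mm=resample_step_mm
            )
        D = np.zeros(grid.shape)
        for ax in range(3):
            D += np.gradient(
                orientation_field[..., ax], grid.spacing[ax], axis=ax
            )
        D[count == 0] = 0.0
        return D
    raise ValueError(f"unknown divergence mode {mode!r}")


def compute_voxel_fields(
    sset: StreamlineSet,
    grid: VoxelGrid,
    sphere_diameter_mm: float = 2.625,
    resample_step_mm: float = 0.5,
    divergence_mode: str = "endpoint",
) -> VoxelFieldSet:
    """Convenience wrapper producing the full co-registered field set."""
    orientation, count = voxel_mean_orientation(
        sset, grid, sphere_diameter_mm, resample_step_mm
    )
    D = discrete_divergence(
        sset,
        grid,
        mode=divergence_mode,
        resample_step_mm=resample_step_mm,
        orientation_field=orientation,
        count=count,
    )
    return VoxelFieldSet(
        grid=grid,
        orientation=orientation,
        count=count,
        divergence=D,
        valid=count > 0,
    )
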