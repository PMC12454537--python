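"""Tagged linear-tetrahedron mesh container and shared FE geometry helpers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TaggedTetMesh", "REGIONS", "REGION_IDS"]

REGIONS = {
    1: "muscle",
    2: "tendon_proximal",
    3: "tendon_distal",
    4: "aponeurosis",
}
REGION_IDS = {v: k for k, v in REGIONS.items()}

FACE_SET_NAMES = ("inlet", "outlet", "muscle_surface", "aponeurosis_surface")


@dataclass
class TaggedTetMesh:
    """Nodes + 4-node tetrahedra with region labels and boundary face sets.

    ``region`` holds one integer id per element (see ``REGIONS``).
    ``face_sets`` maps a set name to an (k, 3) array of node-index triangles;
    inlet/outlet/muscle_surface are boundary faces, aponeurosis_surface may
    be an interior interface (the sheet's midline strip).
    """

    nodes: np.ndarray  # (n, 3) float, mm
    elements: np.ndarray  # (m, 4) int
    region: np.ndarray  # (m,) int
    face_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.region = np.asarray(self.region, dtype=np.int64)
        if self.elements.shape[0] != self.region.shape[0]:
            raise ValueError("one region id per element required")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_nodes(self) -> np.ndarray:
        """Coordinates of element corners, shape (m, 4, 3)."""
        return self.nodes[self.elements]

    def volumes(self) -> np.ndarray:
        x = self.element_nodes()
        d = x[:, 1:] - x[:, :1]
        return np.einsum("ij,ij->i", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0

    def centroids(self) -> np.ndarray:
        return self.element_nodes().mean(axis=1)

    def fix_orientation(self) -> None:
        """Swap two nodes of negatively oriented elements in place."""
        neg = self.volumes() < 0
        self.elements[neg] = self.elements[neg][:, [0, 1, 3, 2]]

    def shape_gradients(self) -> tuple[np.ndarray, np.ndarray]:
        """Constant P1 shape-function gradients and volumes.

        Returns ``(grads, vols)`` with ``grads`` of shape (m, 4, 3) where
        ``grads[e, a]`` is the gradient of the barycentric shape function of
        local node ``a`` on element ``e``.
        """
        x = self.element_nodes()
        # rows of J are edge vectors from node 0
        J = x[:, 1:] - x[:, :1]  # (m, 3, 3)
        vols = np.linalg.det(J) / 6.0
        Jinv = np.linalg.inv(J)  # (m, 3, 3)
        # grad of barycentric coords 1..3 are the columns of Jinv^T
        g = np.transpose(Jinv, (0, 2, 1))  # (m, 3, 3): g[e, i] = grad N_{i+1}
        g0 = -g.sum(axis=1, keepdims=True)
        grads = np.concatenate([g0, g], axis=1)
        return grads, vols

    def boundary_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """Boundary triangles and the owning element index of each."""
        faces, owner = _all_faces(self.elements)
        key = np.sort(faces, axis=1)
        uniq, inv, cnt = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        on_bnd = cnt[inv] == 1
        return faces[on_bnd], owner[on_bnd]

    def boundary_node_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_nodes, dtype=bool)
        faces, _ = self.boundary_faces()
        mask[np.unique(faces)] = True
        return mask

    def face_set_nodes(self, name: str) -> np.ndarray:
        """Sorted unique node indices of a face set."""
        faces = self.face_sets[name]
        return np.unique(faces)

    def quality(self) -> dict[str, float]:
        """Basic quality metrics: min/mean scaled Jacobian proxy and aspect."""
        x = self.element_nodes()
        vols = self.volumes()
        edges = np.stack(
            [x[:, a] - x[:, b] for a, b in
             ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))],
            axis=1,
        )
        elen = np.linalg.norm(edges, axis=2)
        lmax = elen.max(axis=1)
        # regular-tet normalised volume ratio in (0, 1]
        reg = (lmax**3) / (6.0 * np.sqrt(2.0))
        shape = vols / reg
        aspect = lmax / elen.min(axis=1)
        return {
            "min_volume": float(vols.min()),
            "min_shape_ratio": float(shape.min()),
            "max_aspect_ratio": float(aspect.max()),
        }

    def validate(self, require_all_regions: bool = True) -> None:
        if np.any(self.volumes() <= 0):
            raise ValueError("mesh contains non-positive element volumes")
        if require_all_regions:
            present = set(np.unique(self.region))
            missing = set(REGIONS) - present
            if missing:
                raise ValueError(
                    f"missing regions: {[REGIONS[m] for m in sorted(missing)]}"
                )
        for name in FACE_SET_NAMES:
            if name not in self.face_sets or len(self.face_sets[name]) == 0:
                raise ValueError(f"face set {name!r} missing or empty")


def refine_tet_mesh(mesh: TaggedTetMesh) -> TaggedTetMesh:
    """Uniform octasection: each tetrahedron into 8 children.

    Edge midpoints become new nodes; the four corner tetrahedra plus four
    from the interior octahedron (split along one diagonal) replace each
    parent.  Children inherit the parent's region; tagged faces are
    subdivided into their four sub-triangles.  Used for hierarchical
    mesh-sensitivity studies: child centroids lie inside the parent, so
    nearest-centroid pairing across levels is exact.
    """
    elems = mesh.elements
    edges = np.array(
        [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]], dtype=np.int64
    )
    pair = np.sort(elems[:, edges], axis=2).reshape(-1, 2)
    uniq, inv = np.unique(pair, axis=0, return_inverse=True)
    mid_id = mesh.n_nodes + inv.reshape(-1, 6)
    nodes = np.concatenate(
        [mesh.nodes, 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])]
    )
    v = [elems[:, i] for i in range(4)]
    # midpoint of local edge (a, b)
    m01, m02, m03, m12, m13, m23 = (mid_id[:, k] for k in range(6))
    children = [
        (v[0], m01, m02, m03),
        (m01, v[1], m12, m13),
        (m02, m12, v[2], m23),
        (m03, m13, m23, v[3]),
        # octahedron split along the m01-m23 diagonal
        (m01, m02, m03, m23),
        (m01, m02, m12, m23),
        (m01, m03, m13, m23),
        (m01, m12, m13, m23),
    ]
    new_elems = np.concatenate(
        [np.stack(c, axis=1) for c in children], axis=0
    )
    region = np.tile(mesh.region, 8)
    out = TaggedTetMesh(nodes=nodes, elements=new_elems, region=region)
    out.fix_orientation()

    edge_lookup = {
        (int(a), int(b)): int(mesh.n_nodes + i)
        for i, (a, b) in enumerate(uniq)
    }

    def split_faces(faces):
        if len(faces) == 0:
            return faces
        sub = []
        for tri in faces:
            a, b, c = (int(x) for x in tri)
            ab = edge_lookup[tuple(sorted((a, b)))]
            bc = edge_lookup[tuple(sorted((b, c)))]
            ca = edge_lookup[tuple(sorted((c, a)))]
            sub += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        return np.asarray(sub, dtype=np.int64)

    out.face_sets = {k: split_faces(f) for k, f in mesh.face_sets.items()}
    return out


def box_mesh(
    divisions=(4, 4, 4), lengths=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)
) -> TaggedTetMesh:
    """Structured tetrahedral box (Kuhn subdivision), tagged as one region.

    Face sets ``inlet``/``outlet`` are the faces at minimum/maximum y;
    ``muscle_surface`` and ``aponeurosis_surface`` are left empty.  Intended
    for verification problems (closed-form Laplace solutions, homogeneous
    deformation patch tests).
    """
    nx, ny, nz = (int(d) + 1 for d in divisions)
    xs = np.linspace(0, lengths[0], nx) + origin[0]
    ys = np.linspace(0, lengths[1], ny) + origin[1]
    zs = np.linspace(0, lengths[2], nz) + origin[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    I, J, K = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corner = {
        (a, b, c): nid(I + a, J + b, K + c)
        for a in (0, 1) for b in (0, 1) for c in (0, 1)
    }
    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    tets = []
    for perm in perms:
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
        region=np.full(len(elements), 1, dtype=np.int64),
    )
    mesh.fix_orientation()
    faces, _ = mesh.boundary_faces()
    fy = nodes[faces][:, :, 1]
    y0, y1 = ys[0], ys[-1]
    tol = 1e-12 * max(lengths) + 1e-15
    mesh.face_sets = {
        "inlet": faces[np.all(np.abs(fy - y0) < 1e-9, axis=1)],
        "outlet": faces[np.all(np.abs(fy - y1) < 1e-9, axis=1)],
        "muscle_surface": np.empty((0, 3), dtype=np.int64),
        "aponeurosis_surface": np.empty((0, 3), dtype=np.int64),
    }
    return mesh


_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def _all_faces(elements: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = len(elements)
    faces = elements[:, _FACE_LOCAL].reshape(-1, 3)
    owner = np.repeat(np.arange(m), 4)
    return faces, owner
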