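"""Heat-flux fibre fields: steady-state conduction with power-law Dirichlet BCs.

A smooth stand-in for tractography-derived fibre orientations is obtained by
solving the steady-state heat equation div(grad T) = 0 on the tagged
muscle-tendon-aponeurosis mesh and taking the unit heat-flux directions
q = -kappa grad T, element-wise, as the fibre field.  The Dirichlet data are
parameterised: constant temperatures T0/T1 at the tendon end faces, and
power-law ramps T0 * n^alpha along the lateral muscle surface (exponent
alpha1) and the aponeurosis midline strip (exponent alpha2), where n is the
normalised axial coordinate of the respective surface.  The end-face BCs
alone yield a fusiform (near-axial) field; the two ramps with alpha2 >=
alpha1 bend the flux towards the aponeurosis and produce the bipennate
feather pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TaggedTetMesh
from .tract_fields import E2_DEFAULT

__all__ = [
    "ThermalBCParams",
    "ElementFibreField",
    "build_dirichlet_values",
    "assemble_stiffness",
    "solve_steady_heat",
    "element_flux_fibres",
    "thermal_fibre_field",
]

DIRECT_SOLVE_MAX_NODES = 200_000


@dataclass
class ThermalBCParams:
    """Dirichlet boundary-condition parameters.

    Temperatures are dimensionless (they only shape gradients).  ``T0`` is
    the inlet (proximal tendon end) value, ``T1`` the outlet value;
    ``alpha1``/``alpha2`` are the power-law exponents of the muscle-surface
    and aponeurosis ramps.  With ``proximal_high`` (default) the normalised
    axial coordinate n equals 1 at the proximal side of each ramped surface,
    so the ramps join the inlet value continuously.
    """

    T0: float = 1.0
    T1: float = -100.0
    alpha1: float = 5.0
    alpha2: float = 10.0
    proximal_high: bool = True

    def __post_init__(self) -> None:
        if self.T0 == self.T1:
            raise ValueError("T0 and T1 must differ")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("ramp exponents must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.array([self.T1, self.alpha1, self.alpha2])

    @classmethod
    def from_vector(cls, s, T0: float = 1.0, proximal_high: bool = True):
        return cls(T0=T0, T1=float(s[0]), alpha1=float(s[1]),
                   alpha2=float(s[2]), proximal_high=proximal_high)


@dataclass
class ElementFibreField:
    """One 3-vector per tetrahedron with a source tag and validity mask."""

    vectors: np.ndarray  # (m, 3), unit where valid
    source: str = "thermal"  # thermal | dti_mapped | analytic
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.vectors), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)


def _ramp(n: np.ndarray, alpha: float, T0: float) -> np.ndarray:
    # 0^0 := 1 so alpha = 0 degenerates to a constant-T0 surface without a
    # jump at the far end of the ramp
    if alpha == 0.0:
        return np.full_like(n, T0)
    return T0 * np.power(n, alpha)


def build_dirichlet_values(
    mesh: TaggedTetMesh,
    params: ThermalBCParams,
    e2: np.ndarray = E2_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """Nodal Dirichlet data from the four tagged face sets.

    Each ramped face set is normalised over its own axial (``e2``) extent:
    n = (z - z_min) / (z_max - z_min), with z measured along ``e2`` and the
    orientation flipped when ``proximal_high``.  A node belonging to several
    sets takes the value of the highest-precedence set:
    inlet > outlet > aponeurosis > muscle.  Returns ``(indices, values)``.
    """
    e2 = np.asarray(e2, dtype=float)
    z = mesh.nodes @ e2
    values: dict[int, float] = {}

    # apply lowest precedence first; later sets overwrite
    for name, const, alpha in (
        ("muscle_surface", None, params.alpha1),
        ("aponeurosis_surface", None, params.alpha2),
        ("outlet", params.T1, None),
        ("inlet", params.T0, None),
    ):
        nodes = mesh.face_set_nodes(name)
        if const is not None:
            for i in nodes:
                values[int(i)] = float(const)
            continue
        zs = z[nodes]
        zmin, zmax = zs.min(), zs.max()
        if zmax - zmin < 1e-12:
            raise ValueError(
                f"face set {name!r} has a degenerate axial extent; "
                "power-law ramp undefined"
            )
        n = (zs - zmin) / (zmax - zmin)
        if params.proximal_high:
            # proximal = small z in this convention; ramp peaks proximally
            n = 1.0 - n
        vals = _ramp(n, alpha, params.T0)
        for i, v in zip(nodes, vals):
            values[int(i)] = float(v)

    idx = np.array(sorted(values), dtype=np.int64)
    return idx, np.array([values[i] for i in idx])


def assemble_stiffness(mesh: TaggedTetMesh, kappa: float = 1.0) -> sp.csr_matrix:
    """P1 Galerkin stiffness matrix of -div(kappa grad T)."""
    grads, vols = mesh.shape_gradients()
    ke = kappa * np.einsum("e,eai,ebi->eab", vols, grads, grads)
    el = mesh.elements
    rows = np.repeat(el, 4, axis=1).ravel()
    cols = np.tile(el, (1, 4)).ravel()
    K = sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return K.tocsr()


def solve_steady_heat(
    mesh: TaggedTetMesh,
    dirichlet: tuple[np.ndarray, np.ndarray],
    kappa: float = 1.0,
    tol: float = 1e-10,
) -> np.ndarray:
    """Nodal temperatures of the steady-state conduction problem.

    Direct sparse factorisation up to 2e5 nodes, diagonal-preconditioned
    conjugate gradients beyond.  The reduced system is symmetric positive
    definite whenever at least one node is constrained.
    """
    fixed_idx, fixed_val = dirichlet
    if len(fixed_idx) == 0:
        raise ValueError("no Dirichlet constraints: singular system")
    K = assemble_stiffness(mesh, kappa)
    n = mesh.n_nodes
    free = np.ones(n, dtype=bool)
    free[fixed_idx] = False
    T = np.zeros(n)
    T[fixed_idx] = fixed_val
    rhs = -K[free][:, fixed_idx] @ fixed_val
    Kff = K[free][:, free]
    if free.sum() == 0:
        return T
    if n <= DIRECT_SOLVE_MAX_NODES:
        Tf = spla.spsolve(Kff.tocsc(), rhs)
    else:
        M = sp.diags(1.0 / Kff.diagonal())
        Tf, info = spla.cg(Kff, rhs, rtol=tol, M=M)
        if info != 0:
            raise RuntimeError(f"CG failed to converge (info={info})")
    T[free] = Tf
    # relative residual check on the free equations
    res = np.linalg.norm(Kff @ Tf - rhs)
    scale = max(np.linalg.norm(rhs), 1e-300)
    if res / scale > max(tol * 1e3, 1e-8):
        raise RuntimeError(f"steady-heat solve residual too large: {res/scale:g}")
    return T


def element_flux_fibres(
    mesh: TaggedTetMesh,
    T: np.ndarray,
    kappa: float = 1.0,
    e2: np.ndarray = E2_DEFAULT,
    eps_rel: float = 1e-12,
    smooth_passes: int = 1,
) -> ElementFibreField:
    """Unit heat-flux directions per element, aligned with the axis.

    The flux q = -kappa grad T is constant on each linear tetrahedron; its
    unit vector (sign-flipped so the ``e2`` component is non-negative) is
    the fibre direction.  By default one pass of nodal flux recovery
    (volume-weighted nodal averaging, re-interpolated to elements) is
    applied: the raw P0 gradient carries large inter-element jumps on
    anisotropic tetrahedra while the underlying flux field is smooth.
    ``smooth_passes=0`` gives the raw element gradients.  Elements whose
    flux magnitude falls below ``eps_rel`` times the mean are masked
    invalid.
    """
    grads, vols = mesh.shape_gradients()
    q = -kappa * np.einsum("eai,ea->ei", grads, T[mesh.elements])
    for _ in range(smooth_passes):
        nodal = np.zeros((mesh.n_nodes, 3))
        w = np.zeros(mesh.n_nodes)
        np.add.at(
            nodal,
            mesh.elements.ravel(),
            np.repeat(q * vols[:, None], 4, axis=0),
        )
        np.add.at(w, mesh.elements.ravel(), np.repeat(vols, 4))
        nodal /= np.maximum(w, 1e-300)[:, None]
        q = nodal[mesh.elements].mean(axis=1)
    mag = np.linalg.norm(q, axis=1)
    # degenerate when the flux is negligible against the global temperature
    # spread per characteristic element length (a constant field is fully
    # invalid rather than amplified roundoff noise)
    h_char = np.cbrt(6.0 * np.abs(vols).mean())
    scale = kappa * np.ptp(T) / h_char
    valid = mag > max(eps_rel * mag.mean(), 1e-9 * scale, 1e-300)
    if scale == 0.0:
        valid = np.zeros(len(mag), dtype=bool)
    v = np.zeros_like(q)
    v[valid] = q[valid] / mag[valid, None]
    e2 = np.asarray(e2, dtype=float)
    flip = (v @ e2) < 0.0
    v[flip] *= -1.0
    return ElementFibreField(vectors=v, source="thermal", valid=valid)


def thermal_fibre_field(
    mesh: TaggedTetMesh,
    params: ThermalBCParams,
    kappa: float = 1.0,
    e2: np.ndarray = E2_DEFAULT,
) -> tuple[ElementFibreField, np.ndarray]:
    """BCs -> solve -> flux directions; returns ``(field, T)``."""
    dirichlet = build_dirichlet_values(mesh, params, e2)
    T = solve_steady_heat(mesh, dirichlet, kappa)
    return element_flux_fibres(mesh, T, kappa, e2), T
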