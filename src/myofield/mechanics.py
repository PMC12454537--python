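"""Transversely isotropic active/passive muscle mechanics on tet meshes.

Constitutive model (second Piola-Kirchhoff stress, MPa, lengths in mm so
forces come out in N):

* isotropic matrix: quasi-compressible Mooney-Rivlin,
  ``S_iso = B1 I + B2 C + B3 C^-1 + k (J - 1) J C^-1`` with the B-terms
  built from the invariants of C = F^T F,
* passive fibre reinforcement along a0 (tension only):
  ``S_pas = C3 / L^2 (L^C4 - 1) M`` for fibre stretch L >= 1, zero in
  compression, with structural tensor M = a0 (x) a0,
* active fibre stress with an exponential force-length relation around the
  optimal stretch L_opt, scaled by the activation level in [0, 1]; only the
  muscle region activates,
* optional additive pre-stretch: the stretch entering both fibre laws is
  ``L = sqrt(I4) + shift`` where shift = applied_pre_stretch - 1 models an
  internal fibre pre-tension without altering the kinematics.

The quasi-static solver is total-Lagrangian on linear tetrahedra with a
full Newton loop (element tangents by central finite differences of the
element internal force), backtracking line search, and adaptive load
stepping.  Two standard load cases are provided: passive axial stretch of
the distal tendon end, and isometric activation after a fibre pre-stretch
with both tendon ends fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import REGION_IDS, TaggedTetMesh
from .thermal import ElementFibreField

__all__ = [
    "MaterialParams",
    "DeformationState",
    "LoadCase",
    "default_materials",
    "invariants",
    "s_iso",
    "s_passive",
    "s_active",
    "total_pk2",
    "strain_energy",
    "solve_quasistatic",
    "run_load_case_1",
    "run_load_case_2",
]

E2 = np.array([0.0, 1.0, 0.0])


@dataclass
class MaterialParams:
    """Constitutive constants of one tissue region.

    Units: stresses in MPa, the remaining constants dimensionless.
    ``gamma_table`` keeps the activation flag exactly as tabulated in the
    source material data (0 for muscle, 1 for tendon), which taken literally
    would disable muscle activation; ``activation_scaling`` is the value the
    model actually uses (1 for muscle, 0 for tendon/aponeurosis).
    """

    c1: float
    c2: float
    k: float
    c3: float
    c4: float
    sigma_max: float = 0.0
    dw_asc: float = 0.15
    dw_dsc: float = 0.16
    nu_asc: float = 2.0
    nu_dsc: float = 6.0
    lam_opt: float = 1.3
    activation_scaling: float = 0.0
    gamma_table: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("bulk modulus must be positive")
        for p in ("c1", "c2", "c3", "c4"):
            if getattr(self, p) < 0:
                raise ValueError(f"{p} must be non-negative")
        if self.sigma_max > 0 and self.lam_opt <= 1.0:
            raise ValueError("optimal fibre stretch must exceed 1")

    @classmethod
    def muscle(cls) -> "MaterialParams":
        return cls(
            c1=2e-3, c2=2e-4, k=7.2, c3=5e-3, c4=6.0,
            sigma_max=0.3, dw_asc=0.15, dw_dsc=0.16, nu_asc=2.0, nu_dsc=6.0,
            lam_opt=1.3, activation_scaling=1.0, gamma_table=0.0,
            name="muscle",
        )

    @classmethod
    def tendon(cls) -> "MaterialParams":
        # also used for the aponeurosis; no active behaviour
        return cls(
            c1=2e-2, c2=2e-3, k=7.2, c3=0.5, c4=25.0,
            sigma_max=0.0, activation_scaling=0.0, gamma_table=1.0,
            name="tendon_aponeurosis",
        )


def default_materials() -> dict[int, MaterialParams]:
    """Region id -> parameters; tendons and aponeurosis share one set."""
    muscle = MaterialParams.muscle()
    tendon = MaterialParams.tendon()
    return {
        REGION_IDS["muscle"]: muscle,
        REGION_IDS["tendon_proximal"]: tendon,
        REGION_IDS["tendon_distal"]: tendon,
        REGION_IDS["aponeurosis"]: tendon,
    }


@dataclass
class LoadCase:
    """Loading programme for the quasi-static solver."""

    kind: str = "passive_stretch"  # passive_stretch | isometric
    f2_max: float = 5.0  # N, passive axial force at the outlet
    lam_app: float = 1.25  # applied fibre pre-stretch (isometric)
    n_steps: int = 10
    n_pre_steps: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ("passive_stretch", "isometric"):
            raise ValueError(f"unknown load case kind {self.kind!r}")
        if self.n_steps < 1 or self.n_pre_steps < 1:
            raise ValueError("load steps must be >= 1")


@dataclass
class DeformationState:
    """Converged equilibrium state at one load level."""

    displacements: np.ndarray  # (n_nodes, 3)
    F: np.ndarray  # (m, 3, 3)
    lam_s: np.ndarray  # (m,) fibre stretch incl. pre-stretch shift
    activation: float
    lam_shift: np.ndarray  # (m,) additive stretch shift applied
    load_factor: float
    reactions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def det_F(self) -> np.ndarray:
        return np.linalg.det(self.F)


# ---------------------------------------------------------------------------
# constitutive law (vectorised over elements; scalars broadcast)

_I3x3 = np.eye(3)


def invariants(C: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """I1, I2, I3 of the right Cauchy-Green tensor (batched)."""
    C = np.asarray(C, dtype=float)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    CC = C @ C
    I2 = 0.5 * (I1**2 - np.trace(CC, axis1=-2, axis2=-1))
    I3 = np.linalg.det(C)
    return I1, I2, I3


def _as_batch(F):
    F = np.asarray(F, dtype=float)
    single = F.ndim == 2
    return (F[None] if single else F), single


def s_iso(F: np.ndarray, mat: MaterialParams) -> np.ndarray:
    """Isotropic quasi-compressible Mooney-Rivlin PK2 stress."""
    Fb, single = _as_batch(F)
    J = np.linalg.det(Fb)
    if np.any(J <= 0):
        raise ValueError("inverted element: det F <= 0")
    C = np.einsum("eji,ejk->eik", Fb, Fb)
    I1, I2, I3 = invariants(C)
    Cinv = np.linalg.inv(C)
    B1 = 2 * mat.c1 * I3 ** (-1 / 3) + 2 * mat.c2 * I3 ** (-2 / 3) * I1
    B2 = -2 * mat.c2 * I3 ** (-2 / 3)
    B3 = (
        -2 / 3 * mat.c1 * I3 ** (-1 / 3) * I1
        - 4 / 3 * mat.c2 * I3 ** (-2 / 3) * I2
    )
    S = (
        B1[:, None, None] * _I3x3
        + B2[:, None, None] * C
        + B3[:, None, None] * Cinv
        + (mat.k * (J - 1) * np.sqrt(I3))[:, None, None] * Cinv
    )
    return S[0] if single else S


def _passive_magnitude(lam: np.ndarray, mat: MaterialParams, smooth_delta: float):
    mag = np.where(
        lam >= 1.0, mat.c3 / lam**2 * (np.abs(lam) ** mat.c4 - 1.0), 0.0
    )
    if smooth_delta > 0.0:
        # C1 Hermite blend of the tension-compression kink at lam = 1 over
        # [1, 1 + 2 delta]: zero value and slope at lam = 1 (the reference
        # state stays exactly stress-free), exact law beyond the band.
        # Without it the slope jump ~C3*C4 makes full Newton cycle.
        d = smooth_delta
        lam1 = 1.0 + 2.0 * d
        m1 = mat.c3 / lam1**2 * (lam1**mat.c4 - 1.0)
        dm1 = mat.c3 * (
            (mat.c4 - 2.0) * lam1 ** (mat.c4 - 3.0) + 2.0 * lam1**-3.0
        )
        t = np.clip((lam - 1.0) / (2.0 * d), 0.0, 1.0)
        # Hermite basis with zero value and slope at the lower knot
        h = m1 * t**2 * (3.0 - 2.0 * t) + dm1 * 2.0 * d * (t**3 - t**2)
        in_band = (lam > 1.0) & (lam < lam1)
        mag = np.where(in_band, h, mag)
    return mag


def s_passive(
    lam_s, mat: MaterialParams, M: np.ndarray, smooth_delta: float = 0.0
) -> np.ndarray:
    """Tension-only passive fibre PK2 stress ``C3/L^2 (L^C4 - 1) M``.

    ``smooth_delta`` optionally regularises the kink at L = 1 (used by the
    quasi-static solver); the default is the exact piecewise law.
    """
    lam = np.atleast_1d(np.asarray(lam_s, dtype=float))
    if np.any(lam <= 0):
        raise ValueError("fibre stretch must be positive")
    mag = _passive_magnitude(lam, mat, smooth_delta)
    M = np.asarray(M, dtype=float)
    out = mag[..., None, None] * (M[None] if M.ndim == 2 else M)
    return out[0] if np.isscalar(lam_s) or np.asarray(lam_s).ndim == 0 else out


def s_active(lam_s, mat: MaterialParams, M: np.ndarray, activation) -> np.ndarray:
    """Active fibre PK2 stress with the exponential force-length relation.

    Ascending-branch constants apply for L <= L_opt, descending beyond; the
    magnitude peaks at sigma_max / L_opt^2 for L = L_opt and decays
    monotonically on both branches.  Scaled by activation in [0, 1] and the
    region's activation scaling.
    """
    act = np.asarray(activation, dtype=float)
    if np.any(act < 0) or np.any(act > 1):
        raise ValueError("activation must lie in [0, 1]")
    lam = np.atleast_1d(np.asarray(lam_s, dtype=float))
    if mat.sigma_max == 0.0 or mat.activation_scaling == 0.0:
        mag = np.zeros_like(lam)
    else:
        dw = np.where(lam <= mat.lam_opt, mat.dw_asc, mat.dw_dsc)
        nu = np.where(lam <= mat.lam_opt, mat.nu_asc, mat.nu_dsc)
        mag = (
            act
            * mat.activation_scaling
            * mat.sigma_max
            / lam**2
            * np.exp(-np.abs((lam / mat.lam_opt - 1.0) / dw) ** nu)
        )
    M = np.asarray(M, dtype=float)
    out = mag[..., None, None] * (M[None] if M.ndim == 2 else M)
    return out[0] if np.isscalar(lam_s) or np.asarray(lam_s).ndim == 0 else out


def total_pk2(
    F: np.ndarray,
    a0: np.ndarray,
    mat: MaterialParams,
    activation: float = 0.0,
    lam_shift: float = 0.0,
) -> np.ndarray:
    """Total PK2 stress: isotropic + passive fibre + active fibre.

    ``lam_shift`` is the additive pre-stretch shift (applied pre-stretch
    minus one); the fibre stretch entering the fibre laws is
    ``sqrt(I4) + lam_shift`` while the kinematics are untouched.
    """
    Fb, single = _as_batch(F)
    a = np.atleast_2d(np.asarray(a0, dtype=float))
    C = np.einsum("eji,ejk->eik", Fb, Fb)
    I4 = np.einsum("ei,eij,ej->e", a, C, a)
    lam = np.sqrt(I4) + lam_shift
    M = np.einsum("ei,ej->eij", a, a)
    S = s_iso(Fb, mat) + s_passive(lam, mat, M)
    if np.any(np.asarray(activation) > 0):
        S = S + s_active(lam, mat, M, activation)
    return S[0] if single else S


def strain_energy(
    F: np.ndarray,
    a0: np.ndarray,
    mat: MaterialParams,
    lam_shift: float = 0.0,
) -> np.ndarray:
    """Passive strain-energy density whose C-derivative is the passive PK2.

    Mooney-Rivlin part ``C1 (J^(-2/3) I1 - 3) + C2 (J^(-4/3) I2 - 3)`` plus
    the volumetric penalty ``k/2 (J - 1)^2`` and the fibre potential
    integrating the tension-only reinforcement.  Exact consistency with
    ``total_pk2`` (activation 0) holds for ``lam_shift = 0``; with a shift
    the stress law is an internal-load model, not an energy derivative.
    """
    Fb, single = _as_batch(F)
    a = np.atleast_2d(np.asarray(a0, dtype=float))
    J = np.linalg.det(Fb)
    C = np.einsum("eji,ejk->eik", Fb, Fb)
    I1, I2, I3 = invariants(C)
    W = (
        mat.c1 * (I3 ** (-1 / 3) * I1 - 3.0)
        + mat.c2 * (I3 ** (-2 / 3) * I2 - 3.0)
        + 0.5 * mat.k * (J - 1.0) ** 2
    )
    I4 = np.einsum("ei,eij,ej->e", a, C, a)
    lam = np.sqrt(I4) + lam_shift
    fib = np.where(
        lam >= 1.0,
        mat.c3 * (lam**mat.c4 / mat.c4 - np.log(lam) - 1.0 / mat.c4),
        0.0,
    )
    W = W + fib
    return W[0] if single else W


# ---------------------------------------------------------------------------
# quasi-static total-Lagrangian solver


class _Model:
    """Precomputed mesh/material data for residual and tangent assembly."""

    def __init__(
        self,
        mesh: TaggedTetMesh,
        fibre_field: ElementFibreField,
        materials: dict[int, MaterialParams],
        kink_smoothing: float = 5e-3,
    ):
        self.kink_smoothing = float(kink_smoothing)
        self.mesh = mesh
        self.grads, self.vols = mesh.shape_gradients()
        if np.any(self.vols <= 0):
            raise ValueError("mesh has non-positive volumes")
        self.a0 = np.asarray(fibre_field.vectors, dtype=float)
        norms = np.linalg.norm(self.a0, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("fibre field contains zero vectors")
        self.a0 = self.a0 / norms
        self.M = np.einsum("ei,ej->eij", self.a0, self.a0)
        self.materials = materials
        self.region_groups = {
            rid: np.flatnonzero(mesh.region == rid)
            for rid in np.unique(mesh.region)
        }
        for rid in self.region_groups:
            if rid not in materials:
                raise ValueError(f"no material for region id {rid}")
        self.elements = mesh.elements
        self.n_dof = mesh.n_nodes * 3
        # sparse assembly pattern for the 12x12 element blocks
        edof = (3 * self.elements[:, :, None] + np.arange(3)).reshape(-1, 12)
        self.edof = edof
        self.rows = np.repeat(edof, 12, axis=1).ravel()
        self.cols = np.tile(edof, (1, 12)).ravel()

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1, 3)[self.elements]  # (m, 4, 3)
        return _I3x3 + np.einsum("eai,eaj->eij", ue, self.grads)

    def stresses(
        self, F: np.ndarray, activation: float, lam_shift: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """PK2 per element and fibre stretch (with shift)."""
        C = np.einsum("eji,ejk->eik", F, F)
        I4 = np.einsum("eij,eij->e", self.M, C)
        lam = np.sqrt(I4) + lam_shift
        S = np.empty_like(F)
        for rid, idx in self.region_groups.items():
            mat = self.materials[rid]
            S[idx] = s_iso(F[idx], mat) + s_passive(
                lam[idx], mat, self.M[idx], smooth_delta=self.kink_smoothing
            )
            if activation > 0 and mat.activation_scaling > 0:
                S[idx] += s_active(lam[idx], mat, self.M[idx], activation)
        return S, lam

    def element_internal_forces(
        self, F: np.ndarray, activation: float, lam_shift: np.ndarray
    ) -> np.ndarray:
        S, _ = self.stresses(F, activation, lam_shift)
        P = np.einsum("eij,ejk->eik", F, S)
        return np.einsum("e,eik,eak->eai", self.vols, P, self.grads)

    def internal_force(
        self, u: np.ndarray, activation: float, lam_shift: np.ndarray
    ) -> np.ndarray:
        F = self.deformation_gradients(u)
        fe = self.element_internal_forces(F, activation, lam_shift)
        f = np.zeros(self.n_dof)
        np.add.at(f, self.edof, fe.reshape(-1, 12))
        return f

    # -- pseudo-potential -------------------------------------------------
    # For fixed activation and pre-stretch shift the model is conservative:
    # every fibre-stress magnitude m(lam) admits a potential
    # Phi(lam; shift) = A(lam) - shift * B(lam) with A = int m t dt and
    # B = int m dt, both shift-independent and tabulated once per material.
    _LAM_GRID = np.linspace(0.05, 5.0, 49501)

    def _potential_tables(self):
        if hasattr(self, "_pot"):
            return self._pot
        from scipy.integrate import cumulative_trapezoid

        g = self._LAM_GRID
        self._pot = {}
        for rid, mat in self.materials.items():
            key = id(mat)
            if key in self._pot:
                continue
            mp = _passive_magnitude(g, mat, self.kink_smoothing)
            if mat.sigma_max > 0 and mat.activation_scaling > 0:
                dw = np.where(g <= mat.lam_opt, mat.dw_asc, mat.dw_dsc)
                nu = np.where(g <= mat.lam_opt, mat.nu_asc, mat.nu_dsc)
                ma = (
                    mat.activation_scaling
                    * mat.sigma_max
                    / g**2
                    * np.exp(-np.abs((g / mat.lam_opt - 1.0) / dw) ** nu)
                )
            else:
                ma = np.zeros_like(g)
            self._pot[key] = tuple(
                cumulative_trapezoid(w, g, initial=0.0)
                for w in (mp * g, mp, ma * g, ma)
            )
        return self._pot

    def energy(
        self, u: np.ndarray, activation: float, lam_shift: np.ndarray
    ) -> float:
        """Total internal pseudo-energy consistent with the stress law."""
        pot = self._potential_tables()
        g = self._LAM_GRID
        F = self.deformation_gradients(u)
        C = np.einsum("eji,ejk->eik", F, F)
        I4 = np.einsum("eij,eij->e", self.M, C)
        lam = np.clip(np.sqrt(I4) + lam_shift, g[0], g[-1])
        W = np.zeros(len(F))
        for rid, idx in self.region_groups.items():
            mat = self.materials[rid]
            I1, I2, I3 = invariants(C[idx])
            J = np.sqrt(I3)
            W[idx] = (
                mat.c1 * (I3 ** (-1 / 3) * I1 - 3.0)
                + mat.c2 * (I3 ** (-2 / 3) * I2 - 3.0)
                + 0.5 * mat.k * (J - 1.0) ** 2
            )
            Ap, Bp, Aa, Ba = pot[id(mat)]
            li = lam[idx]
            sh = lam_shift[idx]
            W[idx] += np.interp(li, g, Ap) - sh * np.interp(li, g, Bp)
            if activation > 0:
                W[idx] += activation * (
                    np.interp(li, g, Aa) - sh * np.interp(li, g, Ba)
                )
        return float(np.sum(self.vols * W))

    def tangent(
        self,
        u: np.ndarray,
        activation: float,
        lam_shift: np.ndarray,
        h: float = 1e-6,
    ) -> sp.csr_matrix:
        """Consistent tangent by central differences per element dof."""
        ue = u.reshape(-1, 3)[self.elements]
        ke = np.empty((len(self.elements), 12, 12))
        for d in range(12):
            a, i = divmod(d, 3)
            for sgn, store in ((1.0, 0), (-1.0, 1)):
                up = ue.copy()
                up[:, a, i] += sgn * h
                Fp = _I3x3 + np.einsum("eai,eaj->eij", up, self.grads)
                fe = self.element_internal_forces(Fp, activation, lam_shift)
                if store == 0:
                    plus = fe
                else:
                    ke[:, :, d] = (plus - fe).reshape(-1, 12) / (2 * h)
        K = sp.coo_matrix(
            (ke.ravel(), (self.rows, self.cols)),
            shape=(self.n_dof, self.n_dof),
        )
        return K.tocsr()


def _newton(
    model: _Model,
    u0: np.ndarray,
    f_ext: np.ndarray,
    fixed: np.ndarray,
    fixed_values: np.ndarray,
    activation: float,
    lam_shift: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 30,
) -> tuple[np.ndarray, bool]:
    u = u0.copy()
    u[fixed] = fixed_values
    free = np.ones(model.n_dof, dtype=bool)
    free[fixed] = False

    def residual(uv):
        return model.internal_force(uv, activation, lam_shift) - f_ext

    r = residual(u)
    ref = max(np.linalg.norm(f_ext[free]), np.linalg.norm(r[free]), 1e-12)
    # absolute floor (N): an already-equilibrated start otherwise turns its
    # own roundoff residual into the convergence reference
    abs_tol = 1e-12
    for _ in range(max_iter):
        rn = np.linalg.norm(r[free])
        if rn <= max(tol * ref, abs_tol):
            return u, True
        K = model.tangent(u, activation, lam_shift)
        du = np.zeros(model.n_dof)
        Kff = K[free][:, free]
        du[free] = spla.spsolve(Kff.tocsc(), -r[free])
        # backtracking line search on the residual norm
        step = 1.0
        for _ in range(12):
            u_try = u + step * du
            try:
                r_try = residual(u_try)
            except ValueError:  # inverted element
                step *= 0.5
                continue
            if np.linalg.norm(r_try[free]) < rn or step < 1e-3:
                u, r = u_try, r_try
                break
            step *= 0.5
        else:
            return u, False
    return u, np.linalg.norm(r[free]) <= max(tol * ref, abs_tol)


def _minimise_energy(
    model: _Model,
    u0: np.ndarray,
    f_ext: np.ndarray,
    fixed: np.ndarray,
    fixed_values: np.ndarray,
    activation: float,
    lam_shift: np.ndarray,
    max_iter: int = 2000,
) -> np.ndarray:
    """Descend to a stable equilibrium by L-BFGS on the total potential.

    Newton can stall near unstable equilibria (saddles of the potential,
    e.g. local snap-through under active contraction); minimising
    ``E_int(u) - f_ext . u`` with the exact internal force as gradient
    restores a stable basin, after which Newton converges quadratically.
    """
    from scipy.optimize import minimize as _sp_minimize

    u = u0.copy()
    u[fixed] = fixed_values
    free = np.ones(model.n_dof, dtype=bool)
    free[fixed] = False

    def fun(x):
        uu = u.copy()
        uu[free] = x
        E = model.energy(uu, activation, lam_shift) - f_ext @ uu
        g = model.internal_force(uu, activation, lam_shift) - f_ext
        return E, g[free]

    res = _sp_minimize(
        fun,
        u[free],
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-18, "gtol": 1e-10},
    )
    out = u.copy()
    out[free] = res.x
    return out


def _state(model, u, activation, lam_shift, load_factor, fixed_sets):
    F = model.deformation_gradients(u)
    _, lam = model.stresses(F, activation, lam_shift)
    f_int = model.internal_force(u, activation, lam_shift)
    reactions = {}
    for name, dofs in fixed_sets.items():
        reactions[name] = f_int.reshape(-1, 3)[dofs].sum(axis=0)
    return DeformationState(
        displacements=u.reshape(-1, 3).copy(),
        F=F,
        lam_s=lam,
        activation=float(activation),
        lam_shift=lam_shift.copy(),
        load_factor=float(load_factor),
        reactions=reactions,
    )


def solve_quasistatic(
    mesh: TaggedTetMesh,
    fibre_field: ElementFibreField,
    materials: dict[int, MaterialParams] | None = None,
    load_case: LoadCase | None = None,
    tol: float = 1e-8,
) -> list[DeformationState]:
    """Run a load case and return the converged state at every load step.

    Load steps are ramped linearly; a step failing to converge is halved
    adaptively (down to 1/16 of the nominal increment) before the solver
    gives up with diagnostics.
    """
    if materials is None:
        materials = default_materials()
    if load_case is None:
        load_case = LoadCase()
    model = _Model(mesh, fibre_field, materials)
    if load_case.kind == "passive_stretch":
        return _run_passive(model, load_case, tol)
    return _run_isometric(model, load_case, tol)


def _fixed_dofs(mesh: TaggedTetMesh, names) -> tuple[np.ndarray, dict]:
    node_sets = {n: mesh.face_set_nodes(n) for n in names}
    dofs = np.concatenate(
        [np.add.outer(3 * ns, np.arange(3)).ravel() for ns in node_sets.values()]
    )
    return np.unique(dofs), node_sets


def _ramp_states(model, mesh, load_case, tol, schedule, fixed_names):
    """Shared incremental loop: ``schedule`` yields (factor, f_ext,
    activation, lam_shift)."""
    fixed, node_sets = _fixed_dofs(mesh, fixed_names)
    fixed_values = np.zeros(len(fixed))
    u = np.zeros(model.n_dof)
    states = []
    prev = (0.0, np.zeros(model.n_dof), 0.0, np.zeros(model.mesh.n_elements))
    for target in schedule:
        lo_f, lo_ext, lo_act, lo_shift = prev
        hi_f, hi_ext, hi_act, hi_shift = target
        frac_done = 0.0
        sub = 1.0
        while frac_done < 1.0 - 1e-12:
            frac_try = min(frac_done + sub, 1.0)
            w = frac_try
            f_ext = (1 - w) * lo_ext + w * hi_ext
            act = (1 - w) * lo_act + w * hi_act
            shift = (1 - w) * lo_shift + w * hi_shift
            u_new, ok = _newton(
                model, u, f_ext, fixed, fixed_values, act, shift, tol
            )
            if not ok:
                # Newton stalled (typically near an unstable equilibrium):
                # descend the potential to a stable basin and retry
                u_try = _minimise_energy(
                    model, u, f_ext, fixed, fixed_values, act, shift
                )
                u_new, ok = _newton(
                    model, u_try, f_ext, fixed, fixed_values, act, shift, tol
                )
            if ok:
                u = u_new
                frac_done = frac_try
                sub = min(sub * 2.0, 1.0 - frac_done + 1e-16)
            else:
                sub *= 0.5
                if sub < 1 / 16:
                    raise RuntimeError(
                        f"load step to factor {hi_f} failed to converge "
                        f"(stalled at sub-fraction {frac_done:.3f})"
                    )
        states.append(
            _state(model, u, hi_act, hi_shift, hi_f, node_sets)
        )
        prev = target
    return states


def _run_passive(model, load_case, tol):
    mesh = model.mesh
    outlet_nodes = mesh.face_set_nodes("outlet")
    f_unit = np.zeros(model.n_dof)
    # equal nodal shares of the axial force at the outlet disc
    f_unit.reshape(-1, 3)[outlet_nodes, 1] = 1.0 / len(outlet_nodes)
    schedule = []
    for k in range(1, load_case.n_steps + 1):
        f = load_case.f2_max * k / load_case.n_steps
        schedule.append(
            (f, f * f_unit, 0.0, np.zeros(mesh.n_elements))
        )
    return _ramp_states(model, mesh, load_case, tol, schedule, ("inlet",))


def _run_isometric(model, load_case, tol):
    mesh = model.mesh
    muscle = (mesh.region == REGION_IDS["muscle"]).astype(float)
    shift_full = (load_case.lam_app - 1.0) * muscle
    zero_f = np.zeros(model.n_dof)
    schedule = []
    for k in range(1, load_case.n_pre_steps + 1):
        w = k / load_case.n_pre_steps
        schedule.append((w, zero_f, 0.0, w * shift_full))
    for k in range(1, load_case.n_steps + 1):
        a = k / load_case.n_steps
        schedule.append((1.0 + a, zero_f, a, shift_full))
    return _ramp_states(
        model, mesh, load_case, tol, schedule, ("inlet", "outlet")
    )


def run_load_case_1(
    mesh: TaggedTetMesh,
    fibre_field: ElementFibreField,
    materials: dict[int, MaterialParams] | None = None,
    f2_max: float = 5.0,
    n_steps: int = 10,
    tol: float = 1e-8,
) -> tuple[list[DeformationState], dict]:
    """Passive stretch: inlet fixed, axial force ramp 0 -> f2_max at outlet.

    Returns the states and a force-displacement table (applied force in N
    vs mean axial displacement of the outlet face).
    """
    lc = LoadCase(kind="passive_stretch", f2_max=f2_max, n_steps=n_steps)
    states = solve_quasistatic(mesh, fibre_field, materials, lc, tol)
    outlet = mesh.face_set_nodes("outlet")
    table = {
        "force_N": [s.load_factor for s in states],
        "mean_outlet_displacement_mm": [
            float(s.displacements[outlet, 1].mean()) for s in states
        ],
    }
    return states, table


def run_load_case_2(
    mesh: TaggedTetMesh,
    fibre_field: ElementFibreField,
    materials: dict[int, MaterialParams] | None = None,
    lam_app: float = 1.25,
    n_steps: int = 10,
    n_pre_steps: int = 5,
    tol: float = 1e-8,
) -> tuple[list[DeformationState], dict]:
    """Isometric contraction: pre-stretch then activation, both ends fixed.

    Step 1 ramps the applied fibre pre-stretch to ``lam_app`` (muscle region
    only) and equilibrates; step 2 ramps activation 0 -> 1.  Returns the
    states and the proximal (inlet) axial reaction force vs activation.
    """
    lc = LoadCase(
        kind="isometric",
        lam_app=lam_app,
        n_steps=n_steps,
        n_pre_steps=n_pre_steps,
    )
    states = solve_quasistatic(mesh, fibre_field, materials, lc, tol)
    act_states = [s for s in states if s.load_factor >= 1.0 - 1e-12]
    table = {
        "activation": [s.activation for s in act_states],
        "inlet_reaction_N": [
            float(abs(s.reactions["inlet"][1])) for s in act_states
        ],
    }
    return states, table
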