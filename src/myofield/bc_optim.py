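"""Boundary-condition identification by space-filling design, RBF metamodel
and simulated annealing.

The thermal Dirichlet parameters s = (T1, alpha1, alpha2) are identified by
minimising the mean cosine distance between the heat-flux fibre field and a
reference field over a sub-region of the mesh (the full domain minus a
surface layer and the distal end, where tractography-derived references are
unreliable).  The loop mirrors standard surrogate-based optimisation: a
maximin Latin hypercube design over the box, one forward thermal solve per
design point, an interpolating radial-basis-function metamodel of the mean
deviation, simulated annealing on the metamodel under the constraint
alpha2 >= alpha1, and a local polish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.optimize import minimize
from scipy.spatial.distance import pdist
from scipy.stats import qmc

from .mesh import REGION_IDS, TaggedTetMesh
from .thermal import ElementFibreField, ThermalBCParams, thermal_fibre_field

__all__ = [
    "DesignSpace",
    "SubregionMask",
    "Metamodel",
    "make_subregion",
    "cosine_distance",
    "mean_deviation",
    "sample_designs",
    "fit_metamodel",
    "r2_score",
    "sensitivity",
    "optimise",
    "thermal_objective",
    "run_bc_optimisation",
]


@dataclass
class DesignSpace:
    """Box bounds, start point and linear constraint of the BC search.

    Defaults follow the admissible ranges of the identification problem:
    T1 in [-200, -1] (a purely numerical sink temperature), alpha1 and
    alpha2 in [0, 20], start (-100, 5, 10), constraint alpha2 - alpha1 >= 0.
    The constraint bounds the optimiser only; design sampling covers the
    full box so the metamodel is informed on both sides of the constraint.
    """

    t1_range: tuple[float, float] = (-200.0, -1.0)
    alpha1_range: tuple[float, float] = (0.0, 20.0)
    alpha2_range: tuple[float, float] = (0.0, 20.0)
    start: tuple[float, float, float] = (-100.0, 5.0, 10.0)
    n_designs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        s = np.asarray(self.start, dtype=float)
        if np.any(s < lo) or np.any(s > hi):
            raise ValueError("start point outside the design box")
        if self.alpha2_range[1] < self.alpha1_range[0]:
            raise ValueError("constraint alpha2 >= alpha1 infeasible")
        if self.n_designs < 4:
            raise ValueError("need at least dim + 1 = 4 design points")

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array(
            [self.t1_range[0], self.alpha1_range[0], self.alpha2_range[0]]
        )
        hi = np.array(
            [self.t1_range[1], self.alpha1_range[1], self.alpha2_range[1]]
        )
        return lo, hi

    def scale01(self, s: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds
        return (np.asarray(s, dtype=float) - lo) / (hi - lo)

    def unscale(self, u: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds
        return lo + np.asarray(u, dtype=float) * (hi - lo)

    def feasible(self, s: np.ndarray, tol: float = 0.0) -> bool:
        return s[2] - s[1] >= -tol

    def project(self, s: np.ndarray) -> np.ndarray:
        """Clip to the box and project onto alpha2 >= alpha1."""
        lo, hi = self.bounds
        s = np.clip(np.asarray(s, dtype=float), lo, hi)
        if s[2] < s[1]:
            m = 0.5 * (s[1] + s[2])
            s[1] = s[2] = m
            s = np.clip(s, lo, hi)
        return s


@dataclass
class SubregionMask:
    """Boolean per-element mask of the optimisation sub-region."""

    mask: np.ndarray
    excluded_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_elements(self) -> int:
        return int(self.mask.sum())


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Min distance from each point to each triangle; returns (np, nt).

    Standard region-wise closest-point computation on the triangle plane.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    P = points[:, None, :] - a[None, :, :]  # (np, nt, 3)
    d1 = np.einsum("pti,ti->pt", P, ab)
    d2 = np.einsum("pti,ti->pt", P, ac)
    aa = np.einsum("ti,ti->t", ab, ab)
    bb = np.einsum("ti,ti->t", ac, ac)
    abdot = np.einsum("ti,ti->t", ab, ac)
    denom = aa * bb - abdot**2
    denom = np.where(denom > 1e-300, denom, 1.0)
    v = (bb * d1 - abdot * d2) / denom
    w = (aa * d2 - abdot * d1) / denom
    v = np.clip(v, 0.0, 1.0)
    w = np.clip(w, 0.0, 1.0)
    s = np.maximum(v + w, 1.0)
    v = v / s
    w = w / s
    # clamped barycentric point is not exactly the closest point on edges,
    # so refine by also projecting on the three edges
    best = _dist_to_point(P, v[..., None] * ab + w[..., None] * ac)
    for p0, e in ((a * 0, ab), (a * 0, ac), (ab, ac - ab)):
        t = np.einsum("pti,ti->pt", P - p0, e) / np.maximum(
            np.einsum("ti,ti->t", e, e), 1e-300
        )
        t = np.clip(t, 0.0, 1.0)
        best = np.minimum(best, _dist_to_point(P, p0 + t[..., None] * e))
    return best


def _dist_to_point(P, Q):
    return np.linalg.norm(P - Q, axis=-1)


def distance_to_surface(
    points: np.ndarray, nodes: np.ndarray, faces: np.ndarray,
    chunk: int = 512, cutoff: float | None = None,
) -> np.ndarray:
    """Exact min point-triangle distance to a triangulated surface.

    With ``cutoff`` set, distances are exact below the cutoff and reported
    as ``inf`` beyond it; a KD-tree on triangle centroids prunes the exact
    tests, which keeps large meshes tractable.
    """
    tri = nodes[faces]
    out = np.empty(len(points))
    if cutoff is None:
        for i in range(0, len(points), chunk):
            out[i : i + chunk] = _point_triangle_distance(
                points[i : i + chunk], tri
            ).min(axis=1)
        return out
    from scipy.spatial import cKDTree

    tc = tri.mean(axis=1)
    r_max = np.linalg.norm(tri - tc[:, None, :], axis=2).max()
    tree = cKDTree(tc)
    neighbour_lists = tree.query_ball_point(points, cutoff + r_max + 1e-9)
    out.fill(np.inf)
    for i, nb in enumerate(neighbour_lists):
        if nb:
            d = _point_triangle_distance(points[i : i + 1], tri[nb]).min()
            out[i] = d if d <= cutoff else np.inf
    return out


def make_subregion(
    mesh: TaggedTetMesh,
    surface_offset_mm: float = 3.0,
    distal_cut_fraction: float = 0.1,
) -> SubregionMask:
    """Sub-region of muscle elements used as optimisation domain.

    Starts from all muscle elements and removes (i) elements whose centroid
    lies within ``surface_offset_mm`` of the exterior boundary surface and
    (ii) elements in the distal ``distal_cut_fraction`` of the mesh's axial
    extent, where reference fields from tractography are typically
    contaminated by neighbouring tissue.
    """
    muscle = mesh.region == REGION_IDS["muscle"]
    cen = mesh.centroids()
    keep = muscle.copy()
    if surface_offset_mm > 0:
        faces, _ = mesh.boundary_faces()
        d = distance_to_surface(
            cen[muscle], mesh.nodes, faces, cutoff=surface_offset_mm
        )
        sel = np.flatnonzero(muscle)
        keep[sel[d < surface_offset_mm]] = False
    if distal_cut_fraction > 0:
        y = cen[:, 1]
        ymax = mesh.nodes[:, 1].max()
        ymin = mesh.nodes[:, 1].min()
        cut = ymax - distal_cut_fraction * (ymax - ymin)
        keep &= y <= cut
    if not keep.any():
        raise ValueError("sub-region is empty; offsets too aggressive")
    excluded = 1.0 - keep.sum() / max(muscle.sum(), 1)
    return SubregionMask(mask=keep, excluded_fraction=float(excluded))


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
    """1 - cos(angle between a and b), in [0, 2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("cosine distance undefined for zero vectors")
    out = 1.0 - np.einsum("...i,...i->...", a, b) / (na * nb)
    return float(out) if out.ndim == 0 else out


def mean_deviation(
    field_a: ElementFibreField,
    field_b: ElementFibreField,
    subregion: SubregionMask,
) -> tuple[float, np.ndarray, int]:
    """Mean per-element cosine distance over the sub-region.

    Elements flagged invalid in either field are excluded (their number is
    returned as third output).  Also returns the per-element deviation
    angle in degrees, arccos(1 - y), over the used elements.
    """
    m = subregion.mask
    if not m.any():
        raise ValueError("empty sub-region mask")
    ok = m & field_a.valid & field_b.valid
    n_dropped = int(m.sum() - ok.sum())
    y = cosine_distance(field_a.vectors[ok], field_b.vectors[ok])
    angles = np.degrees(np.arccos(np.clip(1.0 - y, -1.0, 1.0)))
    return float(np.mean(y)), angles, n_dropped


def _maximin_improve(
    u: np.ndarray, rng: np.random.Generator, n_iter: int = 2000
) -> np.ndarray:
    """Coordinate-permutation hill climb on the maximin criterion.

    Swapping two values within one column preserves the Latin-hypercube
    stratification, so the result remains an LHS with a larger (never
    smaller) minimum pairwise distance.
    """
    u = u.copy()
    n, d = u.shape
    best = pdist(u).min()
    for _ in range(n_iter):
        col = rng.integers(d)
        i, j = rng.choice(n, 2, replace=False)
        u[[i, j], col] = u[[j, i], col]
        cand = pdist(u).min()
        if cand > best:
            best = cand
        else:
            u[[i, j], col] = u[[j, i], col]
    return u


def sample_designs(space: DesignSpace) -> np.ndarray:
    """Maximin-improved Latin hypercube design over the full box."""
    rng = np.random.default_rng(space.seed)
    lhs = qmc.LatinHypercube(d=3, seed=rng)
    u = lhs.random(space.n_designs)
    u = _maximin_improve(u, rng)
    return space.unscale(u)


@dataclass
class Metamodel:
    """Interpolating (or ridge-regularised) RBF surrogate.

    Inputs are mapped to the unit box before evaluating the kernel; the
    ramp exponents additionally pass through ``log(1 + alpha)``, since the
    power-law BC ``n^alpha`` responds multiplicatively to alpha and the
    objective consequently varies fastest at small exponents.
    """

    space: DesignSpace
    rbf: RBFInterpolator
    designs: np.ndarray
    responses: np.ndarray
    kernel: str
    input_scaling: str = "log_alpha"

    def _scale(self, s: np.ndarray) -> np.ndarray:
        u = self.space.scale01(s)
        if self.input_scaling == "log_alpha":
            s = np.atleast_2d(np.asarray(s, dtype=float))
            lo, hi = self.space.bounds
            for i in (1, 2):
                u[:, i] = np.log1p(s[:, i] - lo[i]) / np.log1p(hi[i] - lo[i])
        return u

    def predict(self, s: np.ndarray) -> float | np.ndarray:
        s = np.asarray(s, dtype=float)
        single = s.ndim == 1
        out = self.rbf(self._scale(np.atleast_2d(s)))
        return float(out[0]) if single else out


def fit_metamodel(
    space: DesignSpace,
    designs: np.ndarray,
    responses: np.ndarray,
    kernel: str = "thin_plate_spline",
    smoothing: float = 0.0,
    input_scaling: str = "log_alpha",
    degree: int | None = None,
) -> Metamodel:
    """Fit the RBF surrogate; exact interpolation when ``smoothing=0``."""
    designs = np.asarray(designs, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(designs) < designs.shape[1] + 1:
        raise ValueError("need at least dim + 1 designs")
    probe = Metamodel(space, None, designs, responses, kernel, input_scaling)
    u = probe._scale(designs)
    key = np.round(u, 12)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    if len(uniq) < len(u):
        for g in range(len(uniq)):
            r = responses[inv == g]
            if len(r) > 1 and np.ptp(r) > 1e-12:
                raise ValueError(
                    "duplicate design points with differing responses"
                )
    kw = {} if degree is None else {"degree": degree}
    rbf = RBFInterpolator(
        u, responses, kernel=kernel, smoothing=smoothing, **kw
    )
    probe.rbf = rbf
    return probe


def r2_score(predicted, simulated) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    p = np.asarray(predicted, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if p.shape != s.shape or p.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 values")
    ss_res = np.sum((s - p) ** 2)
    ss_tot = np.sum((s - s.mean()) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return float(1.0 - ss_res / ss_tot)


def sensitivity(
    model,
    space: DesignSpace,
    n_mc: int = 4096,
    seed: int = 0,
) -> dict[str, float]:
    """First-order variance-based (Sobol) influence fractions in percent.

    Pick-freeze Monte-Carlo estimate of S_i = Var(E[Y|X_i]) / Var(Y) on the
    metamodel, sampled uniformly over the box; ``model`` may be a Metamodel
    or any callable on design vectors.
    """
    predict = model.predict if hasattr(model, "predict") else model
    rng = np.random.default_rng(seed)
    A = space.unscale(rng.random((n_mc, 3)))
    B = space.unscale(rng.random((n_mc, 3)))
    yA = np.asarray(predict(A), dtype=float)
    yB = np.asarray(predict(B), dtype=float)
    var = np.var(np.concatenate([yA, yB]))
    names = ["T1", "alpha1", "alpha2"]
    out = {}
    for i, name in enumerate(names):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        yABi = np.asarray(predict(ABi), dtype=float)
        # Sobol' first-order estimator (Saltelli form)
        si = np.mean(yB * (yABi - yA)) / max(var, 1e-300)
        out[name] = float(np.clip(si, 0.0, 1.0) * 100.0)
    return out


def optimise(
    objective,
    space: DesignSpace,
    seed: int = 0,
    n_restarts: int = 5,
    n_steps: int = 400,
    cooling: float = 0.95,
    polish: bool = True,
) -> tuple[np.ndarray, float, dict]:
    """Constrained minimisation by seeded simulated annealing plus polish.

    Geometric cooling (factor ``cooling`` every ``n_steps/20`` proposals),
    Gaussian proposals with step size adapted towards a 40% acceptance
    rate, proposals projected onto the feasible set alpha2 >= alpha1, and
    ``n_restarts`` independent chains (first starts at ``space.start``).
    A final SLSQP polish enforces the constraint to tolerance.
    """
    lo, hi = space.bounds
    width = hi - lo
    rng = np.random.default_rng(seed)
    start = space.project(np.asarray(space.start, dtype=float))
    best_s, best_y = start, float(objective(start))
    log = {"restarts": [], "n_evals": 1}

    for restart in range(n_restarts):
        s = start if restart == 0 else space.project(
            space.unscale(rng.random(3))
        )
        y = float(objective(s))
        log["n_evals"] += 1
        cur_s, cur_y = s, y
        temp = max(abs(best_y), 0.1)
        step = 0.25
        accepted = 0
        window = max(n_steps // 20, 1)
        for it in range(n_steps):
            prop = space.project(cur_s + rng.normal(0, step, 3) * width)
            py = float(objective(prop))
            log["n_evals"] += 1
            if py < cur_y or rng.random() < np.exp(-(py - cur_y) / temp):
                cur_s, cur_y = prop, py
                accepted += 1
                if cur_y < best_y:
                    best_s, best_y = cur_s, cur_y
            if (it + 1) % window == 0:
                rate = accepted / window
                # adapt step towards ~40% acceptance
                step = float(np.clip(step * np.exp(rate - 0.4), 1e-3, 1.0))
                accepted = 0
                temp *= cooling
        log["restarts"].append({"best_y": best_y})

    if polish:
        s_p, y_p, nev = _polish(objective, space, best_s)
        log["n_evals"] += nev
        if y_p <= best_y:
            best_s, best_y = s_p, y_p
    best_s = space.project(best_s)
    if best_y > float(objective(start)) + 1e-12:
        # never worse than the prescribed start point
        best_s, best_y = start, float(objective(start))
    return best_s, best_y, log


def _polish(
    objective, space: DesignSpace, s0: np.ndarray, maxiter: int = 300
) -> tuple[np.ndarray, float, int]:
    """Constrained local descent in unit-box coordinates.

    The raw parameters are badly scaled (T1 spans hundreds, the exponents
    units) and the objective valley is narrow, so the polish runs SLSQP on
    the box-normalised coordinates with the alpha2 >= alpha1 constraint.
    Returns ``(s, y, n_evals)``; never worse than the start point.
    """
    nev = 0

    def uobj(u):
        nonlocal nev
        nev += 1
        return float(objective(space.unscale(np.clip(u, 0.0, 1.0))))

    u0 = space.scale01(space.project(np.asarray(s0, dtype=float)))
    # derivative-free stage first: the valley of the thermal objective is
    # narrow and curved, where quasi-Newton line searches stall easily
    nm = minimize(
        uobj,
        u0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-14},
    )
    res = minimize(
        uobj,
        np.clip(nm.x, 0.0, 1.0),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * 3,
        constraints=[
            {
                "type": "ineq",
                "fun": lambda u: space.unscale(u)[2] - space.unscale(u)[1],
            }
        ],
        options={"maxiter": maxiter, "ftol": 1e-14},
    )
    if nm.fun < res.fun:
        res = nm
    y0 = float(objective(space.project(np.asarray(s0, dtype=float))))
    s_best = space.project(space.unscale(np.clip(res.x, 0.0, 1.0)))
    y_best = float(objective(s_best))
    if y_best > y0:
        return space.project(np.asarray(s0, dtype=float)), y0, nev + 2
    return s_best, y_best, nev + 2


def thermal_objective(
    mesh: TaggedTetMesh,
    reference: ElementFibreField,
    subregion: SubregionMask,
    T0: float = 1.0,
):
    """Objective s = (T1, a1, a2) -> mean deviation, via a thermal solve."""

    def obj(s: np.ndarray) -> float:
        params = ThermalBCParams.from_vector(s, T0=T0)
        field, _ = thermal_fibre_field(mesh, params)
        y, _, _ = mean_deviation(field, reference, subregion)
        return y

    return obj


def run_bc_optimisation(
    mesh: TaggedTetMesh,
    reference: ElementFibreField,
    space: DesignSpace,
    subregion: SubregionMask | None = None,
    n_holdout: int = 0,
    mode: str = "metamodel",
    sensitivity_mc: int = 4096,
) -> dict:
    """Full identification loop; returns a JSON-able report.

    Samples the design, evaluates the thermal objective at every design
    point, fits the RBF metamodel, optimises over it (or directly over the
    solver with ``mode='direct'``), and finishes with a direct polish of
    the metamodel optimum against the true objective.  ``n_holdout``
    designs are evaluated but withheld from the fit to estimate the
    metamodel's predictive R^2.
    """
    if subregion is None:
        subregion = make_subregion(mesh)
    obj = thermal_objective(mesh, reference, subregion)
    designs = sample_designs(space)
    responses = np.array([obj(s) for s in designs])

    if n_holdout > 0:
        train_s, train_y = designs[:-n_holdout], responses[:-n_holdout]
        hold_s, hold_y = designs[-n_holdout:], responses[-n_holdout:]
    else:
        train_s, train_y = designs, responses
        hold_s = hold_y = None

    model = fit_metamodel(space, train_s, train_y)
    r2 = None
    if hold_s is not None:
        r2 = r2_score(model.predict(hold_s), hold_y)

    target = obj if mode == "direct" else model.predict
    s_opt, y_surrogate, log = optimise(target, space, seed=space.seed)

    # polish against the true (solver) objective from several starts: the
    # surrogate optimum and the best simulated design points, since the
    # thermal objective can exhibit secondary local minima along its valley
    starts = [s_opt] + [
        designs[i] for i in np.argsort(responses)[:3]
    ]
    s_opt, y_direct = None, np.inf
    for s0 in starts:
        s_c, y_c, _ = _polish(obj, space, s0)
        if y_c < y_direct:
            s_opt, y_direct = s_c, y_c

    sens = sensitivity(model, space, n_mc=sensitivity_mc, seed=space.seed)
    return {
        "designs": [[float(v) for v in s] for s in designs],
        "responses": [float(v) for v in responses],
        "s_opt": [float(v) for v in s_opt],
        "y_opt": float(y_direct),
        "y_surrogate": float(y_surrogate),
        "r2_holdout": r2,
        "sensitivity_percent": sens,
        "n_designs": int(len(train_s)),
        "n_holdout": int(n_holdout),
        "seed": int(space.seed),
        "mode": mode,
        "n_evaluations": log["n_evals"],
        "subregion_elements": subregion.n_elements,
        "subregion_excluded_fraction": subregion.excluded_fraction,
    }
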