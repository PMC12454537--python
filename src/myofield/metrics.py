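"""Comparison metrics between two element fibre fields.

The headline scalar is the relative fibre inclination: after aligning both
fields with the muscle's principal axis, the normalised difference vector of
each element pair is compared against the axis,

    incl = 90 deg - angle(difference_unit, e2),

so a positive value means the first (reference) field is steeper, i.e. more
axial, than the second, and a negative value flatter.  Under deformation the
vectors are pushed forward with the deformation gradient before the same
construction is applied, which is how the two architectures' mechanical
states are compared along a load path.
"""

from __future__ import annotations

import numpy as np

from .tract_fields import E2_DEFAULT

__all__ = [
    "align_to_axis",
    "relative_inclination",
    "deformed_inclination",
    "angle_histogram",
    "angular_deviation_deg",
]


def align_to_axis(vectors: np.ndarray, e2: np.ndarray = E2_DEFAULT) -> np.ndarray:
    """Sign-flip vectors so their ``e2`` component is non-negative.

    Vectors exactly orthogonal to the axis keep their sign.  Idempotent.
    """
    v = np.array(vectors, dtype=float, copy=True)
    e2 = np.asarray(e2, dtype=float)
    flip = (v @ e2) < 0.0
    v[flip] *= -1.0
    return v


def relative_inclination(
    a_ref: np.ndarray,
    a_other: np.ndarray,
    e2: np.ndarray = E2_DEFAULT,
    eps: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed relative inclination in degrees, per element.

    Both inputs must already be axis-aligned unit vectors.  Where the two
    vectors coincide (difference norm below ``eps``) the inclination is set
    to 0 and the element flagged degenerate; the construction is
    ill-conditioned there.  Returns ``(degrees, degenerate_mask)``.
    """
    a = np.atleast_2d(np.asarray(a_ref, dtype=float))
    b = np.atleast_2d(np.asarray(a_other, dtype=float))
    e2 = np.asarray(e2, dtype=float)
    d = a - b
    n = np.linalg.norm(d, axis=1)
    degen = n < eps
    safe = np.where(degen, 1.0, n)
    cosang = np.clip((d @ e2) / safe, -1.0, 1.0)
    incl = 90.0 - np.degrees(np.arccos(cosang))
    incl[degen] = 0.0
    return incl, degen


def deformed_inclination(
    a_ref: np.ndarray,
    a_other: np.ndarray,
    F: np.ndarray,
    e2: np.ndarray = E2_DEFAULT,
    eps: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative inclination of the push-forwards ``F a`` per element.

    ``F`` is one deformation gradient per element (m, 3, 3) with positive
    determinant; the pushed vectors are re-normalised and re-aligned before
    the inclination construction, so a pure rescaling of F has no effect.
    """
    F = np.asarray(F, dtype=float)
    if np.any(np.linalg.det(F) <= 0):
        raise ValueError("deformation gradients must have positive determinant")
    fa = np.einsum("eij,ej->ei", F, np.atleast_2d(a_ref))
    fb = np.einsum("eij,ej->ei", F, np.atleast_2d(a_other))
    fa /= np.linalg.norm(fa, axis=1, keepdims=True)
    fb /= np.linalg.norm(fb, axis=1, keepdims=True)
    return relative_inclination(
        align_to_axis(fa, e2), align_to_axis(fb, e2), e2, eps
    )


def angle_histogram(
    values: np.ndarray,
    bin_edges: np.ndarray,
    normalise: bool = False,
) -> dict:
    """Histogram with half-open bins [lo, hi), last bin closed.

    Returns a JSON-able dict with edges, counts and (optionally) the
    count fractions.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("histogram values must be finite")
    edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(v, bins=edges)
    out = {
        "bin_edges": edges.tolist(),
        "counts": counts.tolist(),
        "n_values": int(len(v)),
    }
    if normalise:
        total = max(len(v), 1)
        out["fractions"] = (counts / total).tolist()
    return out


def angular_deviation_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Unsigned angle between paired unit vectors, in degrees."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    c = np.clip(np.einsum("ei,ei->e", a, b), -1.0, 1.0)
    return np.degrees(np.arccos(c))
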