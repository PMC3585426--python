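"""Rigid-body collective variables for helix bundles: piston, rotation, tilt.

Each helix is represented by a vector ``V = H - T`` between the unweighted
centers of mass of four consecutive C-alpha atoms at its head (``H``) and
tail (``T``); ``M = (H + T)/2`` is the helix midpoint.  Against a reference
structure (aligned onto the current frame to remove global rigid motion)
three collective variables are defined:

* **piston** (A): displacement of the helix along its own axis,
  ``Z = (M - M0') . V/|V|`` with ``M0'`` the aligned reference midpoint.
* **rotation** (deg, signed): azimuthal angle of a rotational-reference
  group ``R`` about the helix axis, measured relative to the aligned
  reference group ``R0'``; both offsets are projected onto the plane normal
  to ``V`` and the signed angle follows the right-hand rule about ``V``.
* **tilt** (deg): the angle ``arccos(V1.V2 / |V1||V2|)`` between two helix
  (or pooled monomer) vectors; no reference is needed.

All three come with analytic gradients with respect to the contributing
atom coordinates.  Gradients treat the aligned reference pose as fixed
(the optimal superposition is not differentiated through); the
finite-difference validator in :func:`numeric_gradient_check` freezes the
alignment in the same way, which is how the implementation is verified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Frame, GeometryError, RigidTransform, kabsch_superpose

RAD2DEG = 180.0 / math.pi


class CVError(ValueError):
    """Raised for degenerate collective-variable evaluations."""


@dataclass
class HelixDefinition:
    """Atom groups defining one helix for the collective variables.

    ``head_atoms`` and ``tail_atoms`` are each four consecutive C-alpha
    atoms at the two ends of the helix; by convention the *head* group
    defines the positive axis direction (``V = H - T`` points from tail to
    head, and positive piston displaces the helix toward its head).
    ``rotref_atoms`` is a group of C-alpha atoms spaced four residues apart
    whose center of mass lies off the helix axis; it anchors the rotation
    angle.
    """

    head_atoms: np.ndarray
    tail_atoms: np.ndarray
    rotref_atoms: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.head_atoms = np.asarray(self.head_atoms, dtype=int)
        self.tail_atoms = np.asarray(self.tail_atoms, dtype=int)
        self.rotref_atoms = np.asarray(self.rotref_atoms, dtype=int)
        if self.head_atoms.size != 4 or self.tail_atoms.size != 4:
            raise CVError(f"helix {self.label!r}: head and tail need exactly 4 atoms")
        if np.intersect1d(self.head_atoms, self.tail_atoms).size:
            raise CVError(f"helix {self.label!r}: head and tail groups overlap")
        if self.rotref_atoms.size == 0:
            raise CVError(f"helix {self.label!r}: rotational reference group is empty")

    @property
    def all_atoms(self) -> np.ndarray:
        return np.concatenate([self.head_atoms, self.tail_atoms, self.rotref_atoms])


@dataclass
class CVResult:
    """A collective-variable value and its gradient.

    ``gradient`` maps atom index to the 3-vector d(value)/d(position); units
    are 1/A-per-A (dimensionless) for piston and deg/A for the angles.
    ``meta`` records the sign/axis conventions used.
    """

    value: float
    gradient: dict[int, np.ndarray]
    units: str
    meta: dict = field(default_factory=dict)


class ReferenceModel:
    """A reference structure with cached per-helix geometry.

    The reference (e.g. an experimental bundle structure) supplies the zero
    point of the piston and rotation collective variables.  Before each CV
    evaluation it is superposed onto the current frame over
    ``alignment_selection`` (typically the helical C-alpha atoms of the
    whole bundle) so that global translation and rotation drop out.
    """

    def __init__(self, ref_frame: Frame, alignment_selection) -> None:
        self.ref_frame = ref_frame
        self.alignment_selection = np.asarray(alignment_selection, dtype=int)
        if self.alignment_selection.size < 3:
            raise CVError("alignment selection needs at least 3 atoms")

    def reference_constants(self, hd: HelixDefinition,
                            frame: Frame | None = None,
                            align: bool = True) -> dict[str, np.ndarray]:
        """Per-helix reference quantities, optionally aligned onto ``frame``.

        Returns head COM ``H0``, tail COM ``T0``, midpoint ``M0`` and
        rotational-reference COM ``R0`` of the reference structure, in the
        frame's coordinate system when ``align`` is true.
        """
        coords = self.ref_frame.coords
        if align:
            if frame is None:
                raise CVError("alignment requested but no frame given")
            tf, _ = kabsch_superpose(self.ref_frame, frame, self.alignment_selection)
            coords = tf.apply(coords)
        h0 = coords[hd.head_atoms].mean(axis=0)
        t0 = coords[hd.tail_atoms].mean(axis=0)
        return {"H0": h0, "T0": t0, "M0": 0.5 * (h0 + t0),
                "V0": h0 - t0, "R0": coords[hd.rotref_atoms].mean(axis=0)}


# ---------------------------------------------------------------------------
# axis vector

def helix_axis_vector(frame: Frame, hd: HelixDefinition):
    """Head COM, tail COM, axis vector ``V = H - T`` and midpoint ``M``."""
    for grp, name in ((hd.head_atoms, "head"), (hd.tail_atoms, "tail")):
        if grp.max(initial=0) >= frame.n_atoms:
            raise CVError(f"helix {hd.label!r}: {name} group atom missing from frame")
    h = frame.coords[hd.head_atoms].mean(axis=0)
    t = frame.coords[hd.tail_atoms].mean(axis=0)
    return h, t, h - t, 0.5 * (h + t)


# ---------------------------------------------------------------------------
# core evaluators on raw coordinates (reference pose frozen)
#
# These take the full coordinate array plus the frozen (already aligned)
# reference constants, and return (value, per-group COM gradients).  The
# public CV functions wrap them with alignment and per-atom fan-out; the
# finite-difference validator calls them directly so that the alignment is
# frozen during differencing.

def _piston_eval(coords: np.ndarray, hd: HelixDefinition, m0: np.ndarray):
    h = coords[hd.head_atoms].mean(axis=0)
    t = coords[hd.tail_atoms].mean(axis=0)
    v = h - t
    nv = np.linalg.norm(v)
    if nv < 1e-10:
        raise CVError(f"helix {hd.label!r}: zero-length axis vector")
    u = v / nv
    m = 0.5 * (h + t)
    d = m - m0
    value = float(d @ u)
    proj = np.eye(3) - np.outer(u, u)
    pd = proj @ d / nv
    g_h = 0.5 * u + pd
    g_t = 0.5 * u - pd
    return value, {"H": g_h, "T": g_t}


def _tilt_eval(coords: np.ndarray, heads_a, tails_a, heads_b, tails_b):
    v1 = coords[heads_a].mean(axis=0) - coords[tails_a].mean(axis=0)
    v2 = coords[heads_b].mean(axis=0) - coords[tails_b].mean(axis=0)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-10 or n2 < 1e-10:
        raise CVError("tilt: zero-length axis vector")
    c = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    theta = math.acos(c)
    s = math.sqrt(max(1.0 - c * c, 0.0))
    if s < 1e-8:
        # parallel/antiparallel: value is fine, gradient direction undefined
        g1 = np.zeros(3)
        g2 = np.zeros(3)
    else:
        g1 = -(v2 / (n1 * n2) - c * v1 / n1**2) / s
        g2 = -(v1 / (n1 * n2) - c * v2 / n2**2) / s
    return theta * RAD2DEG, {"V1": g1 * RAD2DEG, "V2": g2 * RAD2DEG}


def _rotation_eval(coords: np.ndarray, hd: HelixDefinition, r0_ref: np.ndarray,
                   m0_ref: np.ndarray | None = None):
    """Signed rotation angle and COM-level gradients.

    ``r0_ref`` is the aligned reference rotational-reference COM.  By
    default the reference offset is taken from the *current* midpoint
    (``r0 = R0' - M``); passing ``m0_ref`` switches to the reference
    midpoint (``r0 = R0' - M0'``), in which case ``r0`` is a constant.
    """
    eye = np.eye(3)
    half = 0.5 * eye
    h = coords[hd.head_atoms].mean(axis=0)
    t = coords[hd.tail_atoms].mean(axis=0)
    rr = coords[hd.rotref_atoms].mean(axis=0)
    v = h - t
    nv = np.linalg.norm(v)
    if nv < 1e-10:
        raise CVError(f"helix {hd.label!r}: zero-length axis vector")
    n = v / nv
    m = 0.5 * (h + t)
    proj = eye - np.outer(n, n)

    r = rr - m
    if m0_ref is None:
        r0 = r0_ref - m
        j_r0 = {"H": -half, "T": -half, "R": np.zeros((3, 3))}
    else:
        r0 = r0_ref - m0_ref
        j_r0 = {"H": np.zeros((3, 3)), "T": np.zeros((3, 3)), "R": np.zeros((3, 3))}
    j_r = {"H": -half, "T": -half, "R": eye}
    j_n = {"H": proj / nv, "T": -proj / nv, "R": np.zeros((3, 3))}

    a = proj @ r      # current offset, in-plane
    b = proj @ r0     # reference offset, in-plane
    if np.linalg.norm(a) < 1e-6 or np.linalg.norm(b) < 1e-6:
        raise CVError(
            f"helix {hd.label!r}: rotational reference lies on the helix axis; "
            "the rotation angle is undefined")

    # d a = P dr - (n r^T + (r.n) I) dn, same for b with r0
    ka = np.outer(n, r) + (r @ n) * eye
    kb = np.outer(n, r0) + (r0 @ n) * eye
    j_a = {g: proj @ j_r[g] - ka @ j_n[g] for g in ("H", "T", "R")}
    j_b = {g: proj @ j_r0[g] - kb @ j_n[g] for g in ("H", "T", "R")}

    bxa = np.cross(b, a)
    s = float(n @ bxa)          # sin-like term: positive for right-hand rotation
    c = float(a @ b)            # cos-like term
    value = math.atan2(s, c)

    axn = np.cross(a, n)
    nxb = np.cross(n, b)
    denom = s * s + c * c
    grads = {}
    for g in ("H", "T", "R"):
        ds = bxa @ j_n[g] + axn @ j_b[g] + nxb @ j_a[g]
        dc = b @ j_a[g] + a @ j_b[g]
        grads[g] = (c * ds - s * dc) / denom * RAD2DEG
    return value * RAD2DEG, grads


# ---------------------------------------------------------------------------
# public CV functions

def _fan_out(groups: list[tuple[np.ndarray, np.ndarray]]) -> dict[int, np.ndarray]:
    """Distribute COM-level gradients to atoms (unweighted COMs)."""
    grad: dict[int, np.ndarray] = {}
    for atoms, g in groups:
        per_atom = np.asarray(g, dtype=float) / atoms.size
        for idx in atoms:
            grad[int(idx)] = grad.get(int(idx), np.zeros(3)) + per_atom
    return grad


def piston_cv(frame: Frame, ref: ReferenceModel, hd: HelixDefinition,
              align: bool = True) -> CVResult:
    """Piston displacement (A) of a helix along its own axis.

    ``Z = (M - M0') . V/|V|``: the projection of the midpoint displacement
    (relative to the aligned reference midpoint ``M0'``) onto the current
    helix axis.  Positive values displace the helix toward its head group.
    With ``align=False`` the reference coordinates are used as-is, which is
    appropriate when frame and reference already share a coordinate system
    (e.g. synthetic fixtures).
    """
    consts = ref.reference_constants(hd, frame, align=align)
    value, g = _piston_eval(frame.coords, hd, consts["M0"])
    grad = _fan_out([(hd.head_atoms, g["H"]), (hd.tail_atoms, g["T"])])
    return CVResult(value, grad, "A",
                    meta={"helix": hd.label, "convention": "positive toward head",
                          "aligned": align})


def rotation_cv(frame: Frame, ref: ReferenceModel, hd: HelixDefinition,
                align: bool = True, reference_midpoint: str = "current") -> CVResult:
    """Signed axial rotation (deg) of a helix about its own axis.

    The angle between the in-plane offsets of the rotational-reference
    group in the current frame and in the aligned reference, measured with
    the right-hand rule about ``V`` (positive = counterclockwise looking
    from tail to head).  ``reference_midpoint`` selects whether the
    reference offset is taken from the current midpoint (``"current"``,
    default) or the aligned reference midpoint (``"reference"``).
    """
    if reference_midpoint not in ("current", "reference"):
        raise CVError("reference_midpoint must be 'current' or 'reference'")
    consts = ref.reference_constants(hd, frame, align=align)
    m0 = consts["M0"] if reference_midpoint == "reference" else None
    value, g = _rotation_eval(frame.coords, hd, consts["R0"], m0)
    grad = _fan_out([(hd.head_atoms, g["H"]), (hd.tail_atoms, g["T"]),
                     (hd.rotref_atoms, g["R"])])
    return CVResult(value, grad, "deg",
                    meta={"helix": hd.label, "convention": "right-hand about V",
                          "reference_midpoint": reference_midpoint, "aligned": align})


def _pool_groups(hd) -> tuple[np.ndarray, np.ndarray, str]:
    """Head/tail atoms for a HelixDefinition or a monomer (sequence of them)."""
    if isinstance(hd, HelixDefinition):
        return hd.head_atoms, hd.tail_atoms, hd.label
    heads = np.concatenate([h.head_atoms for h in hd])
    tails = np.concatenate([h.tail_atoms for h in hd])
    label = "+".join(h.label for h in hd)
    return heads, tails, label


def tilt_cv(frame: Frame, hd_a, hd_b) -> CVResult:
    """Tilt angle (deg, in [0, 180]) between two helix or monomer vectors.

    Each argument is a :class:`HelixDefinition` or a sequence of them; for a
    sequence the vector is built from the pooled head and tail C-alpha atoms
    of all its helices (the monomer variant).  No reference structure is
    involved, so the tilt is invariant to global rigid motion by
    construction.
    """
    heads_a, tails_a, lab_a = _pool_groups(hd_a)
    heads_b, tails_b, lab_b = _pool_groups(hd_b)
    value, g = _tilt_eval(frame.coords, heads_a, tails_a, heads_b, tails_b)
    grad = _fan_out([(heads_a, g["V1"]), (tails_a, -g["V1"]),
                     (heads_b, g["V2"]), (tails_b, -g["V2"])])
    return CVResult(value, grad, "deg", meta={"pair": (lab_a, lab_b)})


# ---------------------------------------------------------------------------
# finite-difference validation

def frozen_cv_evaluator(kind: str, frame: Frame, ref: ReferenceModel | None,
                        hd, align: bool = True,
                        reference_midpoint: str = "current"):
    """Build an evaluator ``f(coords) -> (value, grad dict)`` with the
    reference alignment frozen at the given frame.

    Used by :func:`numeric_gradient_check`: the central differences must not
    re-run the superposition, because the analytic gradients treat the
    aligned reference pose as fixed.
    """
    if kind == "piston":
        consts = ref.reference_constants(hd, frame, align=align)
        m0 = consts["M0"]

        def f(coords):
            value, g = _piston_eval(coords, hd, m0)
            return value, _fan_out([(hd.head_atoms, g["H"]), (hd.tail_atoms, g["T"])])
        return f
    if kind == "rotation":
        consts = ref.reference_constants(hd, frame, align=align)
        r0 = consts["R0"]
        m0 = consts["M0"] if reference_midpoint == "reference" else None

        def f(coords):
            value, g = _rotation_eval(coords, hd, r0, m0)
            return value, _fan_out([(hd.head_atoms, g["H"]), (hd.tail_atoms, g["T"]),
                                    (hd.rotref_atoms, g["R"])])
        return f
    if kind == "tilt":
        heads_a, tails_a, _ = _pool_groups(hd[0])
        heads_b, tails_b, _ = _pool_groups(hd[1])

        def f(coords):
            value, g = _tilt_eval(coords, heads_a, tails_a, heads_b, tails_b)
            return value, _fan_out([(heads_a, g["V1"]), (tails_a, -g["V1"]),
                                    (heads_b, g["V2"]), (tails_b, -g["V2"])])
        return f
    raise CVError(f"unknown CV kind {kind!r}")


def numeric_gradient_check(kind: str, frame: Frame, ref: ReferenceModel | None,
                           hd, step: float = 1e-5, align: bool = True,
                           reference_midpoint: str = "current") -> float:
    """Maximum discrepancy between analytic and central-difference gradients.

    Perturbs every contributing atom by ``+-step`` Angstrom along each axis
    (alignment frozen) and returns the largest per-component difference, in
    CV units per Angstrom.
    """
    if not (1e-6 <= step <= 1e-3):
        raise CVError("step must lie in [1e-6, 1e-3] A")
    f = frozen_cv_evaluator(kind, frame, ref, hd, align=align,
                            reference_midpoint=reference_midpoint)
    _, grad = f(frame.coords)
    worst = 0.0
    for idx, g in grad.items():
        for axis in range(3):
            plus = frame.coords.copy()
            plus[idx, axis] += step
            minus = frame.coords.copy()
            minus[idx, axis] -= step
            fd = (f(plus)[0] - f(minus)[0]) / (2.0 * step)
            worst = max(worst, abs(fd - g[axis]))
    return worst
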