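"""Rigid-body superposition and RMSD primitives.

Everything downstream (collective variables, bundle analyses, reference
alignment) is built on unweighted Kabsch superposition over an atom
selection.  Coordinates are treated as unwrapped Cartesian positions in
Angstrom; no periodic-image handling happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric input."""


@dataclass
class Frame:
    """One set of atomic coordinates with per-atom metadata.

    Parameters
    ----------
    coords : (N, 3) float array
        Cartesian coordinates in Angstrom.
    chains : (N,) str array
        Chain identifier per atom.
    resids : (N,) int array
        Residue number per atom (author numbering).
    names : (N,) str array
        Atom name per atom (e.g. ``CA``, ``N``, ``C``, ``O``).
    box : optional (3,) float array
        Orthorhombic box lengths in Angstrom; informational only.
    time : optional float
        Frame time in ps, propagated from trajectory readers.
    """

    coords: np.ndarray
    chains: np.ndarray
    resids: np.ndarray
    names: np.ndarray
    box: np.ndarray | None = None
    time: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.chains = np.asarray(self.chains)
        self.resids = np.asarray(self.resids, dtype=int)
        self.names = np.asarray(self.names)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise GeometryError("coords must have shape (N, 3)")
        n = self.coords.shape[0]
        if n < 1:
            raise GeometryError("a Frame needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("coordinates must be finite")
        for arr, label in ((self.chains, "chains"), (self.resids, "resids"),
                           (self.names, "names")):
            if arr.shape != (n,):
                raise GeometryError(f"atom metadata '{label}' must have length {n}")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.coords.copy(), self.chains.copy(), self.resids.copy(),
                     self.names.copy(),
                     None if self.box is None else np.array(self.box, dtype=float),
                     self.time)

    def select(self, chain: str | None = None,
               resid_range: tuple[int, int] | None = None,
               name: str | None = None) -> np.ndarray:
        """Return atom indices matching the given chain / residue range / name."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chains == chain
        if resid_range is not None:
            lo, hi = resid_range
            mask &= (self.resids >= lo) & (self.resids <= hi)
        if name is not None:
            mask &= self.names == name
        return np.flatnonzero(mask)


@dataclass
class RigidTransform:
    """A proper rigid motion ``x -> R x + t`` (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise GeometryError("RigidTransform needs a 3x3 rotation and a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise GeometryError("rotation must be proper (det = +1)")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation must be orthonormal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _check_selection(mobile: Frame, target: Frame, selection) -> np.ndarray:
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise GeometryError("selection is empty")
    if sel.max(initial=0) >= mobile.n_atoms or sel.max(initial=0) >= target.n_atoms:
        raise GeometryError("selection index out of range")
    return sel


def kabsch_superpose(mobile: Frame, target: Frame, selection) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns the proper rigid transform minimizing the RMSD of the selected
    atoms, together with the residual RMSD after the transform.  Reflections
    are excluded by sign-correcting the smallest singular value, so the
    result is always a physical rigid motion.

    Raises
    ------
    GeometryError
        If the selections mismatch, have fewer than three atoms, or the
        selected atoms are (near-)collinear so the rotation is undetermined.
    """
    sel = _check_selection(mobile, target, selection)
    if sel.size < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    x = mobile.coords[sel]
    y = target.coords[sel]
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    # collinearity check: second singular value of the covariance vanishes
    scale = max(np.linalg.norm(x0), 1e-12)
    if s[1] <= 1e-8 * scale**2 / sel.size:
        raise GeometryError(
            "selection is collinear or otherwise degenerate: the optimal "
            "rotation about the line is undetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = yc - rot @ xc
    tf = RigidTransform(rot, trans)
    moved = tf.apply(x)
    rmsd_after = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return tf, rmsd_after


def rmsd(a: Frame, b: Frame, selection, superpose: bool = False) -> float:
    """Root-mean-square deviation between two frames over a selection.

    With ``superpose=True`` the optimal rigid superposition of ``a`` onto
    ``b`` (over the same selection) is removed first.
    """
    sel = _check_selection(a, b, selection)
    if superpose:
        _, value = kabsch_superpose(a, b, sel)
        return value
    diff = a.coords[sel] - b.coords[sel]
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
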