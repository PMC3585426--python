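"""Trajectory-level bundle analyses.

Helical RMSD against a reference structure, backbone i -> i+4 hydrogen
bonds, per-residue Crick-angle deviation from an ideal knobs-into-holes
ladder, the four-state piston classifier (P00/P10/P01/P11) and negative
log-probability surfaces of collective-variable time series.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cv import CVError, HelixDefinition, ReferenceModel
from .geometry import Frame, GeometryError, kabsch_superpose, rmsd

log = logging.getLogger(__name__)

STATE_LABELS = ("P00", "P10", "P01", "P11", "OTHER")

# canonical Crick-angle ladder: position 'a' at +19.5 deg, advancing by
# 720/7 deg per residue (two turns per heptad); supplied as a default and
# overridable through configuration
IDEAL_A_ANGLE = 19.5
CRICK_STEP = 720.0 / 7.0


def ideal_crick_ladder(a_angle: float = IDEAL_A_ANGLE) -> dict[str, float]:
    """Ideal Crick angle per heptad position for a canonical coiled coil."""
    return {pos: _wrap_deg(a_angle + k * CRICK_STEP)
            for k, pos in enumerate("abcdefg")}


def _wrap_deg(x):
    return (np.asarray(x) + 180.0) % 360.0 - 180.0


@dataclass
class BundleDefinition:
    """Atom bookkeeping for one four-helix bundle.

    ``helices`` maps labels N1, C1, N2, C2 to their CV atom groups;
    ``helical_selection`` holds the C-alpha atoms with stable helical
    structure (used for RMSD and reference alignment); ``helix_ca`` maps
    each label to all its C-alpha atoms in residue order; ``hbond_ranges``
    maps chain id to residue ranges scanned for i -> i+4 hydrogen bonds;
    ``register_a`` pins the heptad register (residue number of an 'a'
    position per helix).
    """

    helices: dict[str, HelixDefinition]
    helical_selection: np.ndarray
    helix_ca: dict[str, np.ndarray]
    hbond_ranges: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    register_a: dict[str, int] = field(default_factory=dict)
    tilt_pivot: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.helical_selection = np.asarray(self.helical_selection, dtype=int)
        if len(set(self.helices)) != len(self.helices):
            raise GeometryError("helix labels must be unique")

    @property
    def monomers(self) -> dict[str, list[HelixDefinition]]:
        return {"M1": [self.helices["N1"], self.helices["C1"]],
                "M2": [self.helices["N2"], self.helices["C2"]]}

    def helix_atoms(self, frame: Frame, label: str) -> np.ndarray:
        """All atoms belonging to one helix (by chain and residue range)."""
        ca = self.helix_ca[label]
        chain = frame.chains[ca[0]]
        lo, hi = int(frame.resids[ca].min()), int(frame.resids[ca].max())
        return frame.select(chain=chain, resid_range=(lo, hi))


@dataclass
class StateLabel:
    """Categorical piston state of one frame."""

    label: str
    out_of_register: bool = False

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.label!r}")


@dataclass
class SurfaceGrid:
    """A 1D or 2D gridded surface (negative log probability or free energy).

    ``edges`` holds the bin edges per axis, ``values`` the surface with
    empty bins masked, ``units`` either ``kT`` or ``kJ/mol``.
    """

    edges: list[np.ndarray]
    values: np.ma.MaskedArray
    units: str = "kT"
    axis_labels: list[str] = field(default_factory=list)
    low_information: bool = False

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]


# ---------------------------------------------------------------------------
# helical RMSD

def helical_rmsd(frame: Frame, ref: ReferenceModel, bundle: BundleDefinition) -> float:
    """C-alpha RMSD (A) over the helical selection, after superposition.

    The selection deliberately covers only residues with stable helical
    structure: the flexible termini and the inter-helix connector are
    excluded by construction of ``bundle.helical_selection``.
    """
    sel = bundle.helical_selection
    if sel.max(initial=0) >= frame.n_atoms:
        missing = sel[sel >= frame.n_atoms]
        raise GeometryError(f"helical selection atoms missing from frame: {missing[:5]}")
    return rmsd(frame, ref.ref_frame, sel, superpose=True)


# ---------------------------------------------------------------------------
# hydrogen bonds

def _backbone_index(frame: Frame):
    table: dict[tuple[str, int], dict[str, int]] = {}
    for i, (ch, rid, nm) in enumerate(zip(frame.chains, frame.resids, frame.names)):
        table.setdefault((str(ch), int(rid)), {})[str(nm)] = i
    return table


def reconstruct_amide_h(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray,
                        bond: float = 1.01) -> np.ndarray:
    """Place the amide hydrogen on the bisector opposite C(i-1) and CA."""
    u = (n - ca) / np.linalg.norm(n - ca)
    v = (n - c_prev) / np.linalg.norm(n - c_prev)
    d = u + v
    return n + bond * d / np.linalg.norm(d)


def count_helical_hbonds(frame: Frame, bundle: BundleDefinition,
                         dist_cutoff: float = 3.5,
                         angle_cutoff: float = 30.0) -> int:
    """Number of backbone i -> i+4 hydrogen bonds in the scanned ranges.

    A bond is counted when the O(i)-N(i+4) distance is below ``dist_cutoff``
    and the acceptor-donor-hydrogen angle (at the donor nitrogen, between
    the N->O and N->H directions) is below ``angle_cutoff``.  If no explicit
    amide hydrogen is present it is reconstructed from the local backbone
    geometry.  Pairs with missing backbone atoms are skipped with a logged
    warning.
    """
    table = _backbone_index(frame)
    count = 0
    for chain, ranges in bundle.hbond_ranges.items():
        for lo, hi in ranges:
            for i in range(lo, hi - 3):
                acc = table.get((chain, i))
                don = table.get((chain, i + 4))
                prev = table.get((chain, i + 3))
                if (acc is None or don is None or "O" not in acc
                        or "N" not in don):
                    log.warning("h-bond scan: missing backbone atoms for "
                                "%s %d -> %d; pair skipped", chain, i, i + 4)
                    continue
                o = frame.coords[acc["O"]]
                n = frame.coords[don["N"]]
                if np.linalg.norm(o - n) >= dist_cutoff:
                    continue
                if "H" in don:
                    h = frame.coords[don["H"]]
                elif "CA" in don and prev is not None and "C" in prev:
                    h = reconstruct_amide_h(n, frame.coords[don["CA"]],
                                            frame.coords[prev["C"]])
                else:
                    log.warning("h-bond scan: cannot place amide H for %s %d; "
                                "pair skipped", chain, i + 4)
                    continue
                u = o - n
                v = h - n
                cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                if math.degrees(math.acos(np.clip(cosang, -1, 1))) < angle_cutoff:
                    count += 1
    return count


# ---------------------------------------------------------------------------
# Crick angles

def _fit_axis(points: np.ndarray, orient: np.ndarray):
    """Principal axis (unit vector + point on the axis) of a helical cloud.

    The direction comes from the second differences of consecutive points:
    for a regular helix the central second difference points exactly
    radially inward, so cross products of consecutive second differences
    are parallel to the axis (a leading-principal-component direction is
    biased for a discrete helix, whose azimuth correlates with the axial
    coordinate).  The axis position is then a least-squares circle fit of
    the points projected onto the normal plane.
    """
    centroid = points.mean(axis=0)
    sec = points[2:] + points[:-2] - 2.0 * points[1:-1]
    norms = np.linalg.norm(sec, axis=1)
    if np.any(norms <= 1e-10):
        raise GeometryError("axis fit degenerate: collinear points")
    sec = sec / norms[:, None]
    crosses = np.cross(sec[:-1], sec[1:])
    cn = np.linalg.norm(crosses, axis=1)
    if np.all(cn <= 1e-10):
        raise GeometryError("axis fit degenerate: no helical turn")
    crosses = crosses[cn > 1e-10] / cn[cn > 1e-10, None]
    crosses[crosses @ np.asarray(orient, dtype=float) < 0] *= -1.0
    axis = crosses.mean(axis=0)
    na = np.linalg.norm(axis)
    if na <= 1e-8:
        raise GeometryError("axis fit degenerate: inconsistent turn directions")
    axis = axis / na
    if axis @ orient < 0:
        axis = -axis
    # orthonormal in-plane basis
    e1 = np.eye(3)[np.argmin(np.abs(axis))]
    e1 = e1 - (e1 @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    rel = points - centroid
    x = rel @ e1
    y = rel @ e2
    a = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    try:
        (cx, cy, _), *_ = np.linalg.lstsq(a, b, rcond=None)
    except np.linalg.LinAlgError as exc:
        raise GeometryError("axis fit degenerate: circle fit failed") from exc
    center = centroid + cx * e1 + cy * e2
    return axis, center


def crick_deviation_profile(frame: Frame, bundle: BundleDefinition,
                            ideal_ladder: dict[str, float] | None = None):
    """Per-residue Crick angle and deviation from the ideal ladder.

    For each residue the Crick angle is the signed angle (right-hand rule
    about the helix axis) between the direction from the helix axis to the
    residue's C-alpha and the direction from the helix axis to the bundle
    axis, both projected onto the plane normal to the helix axis.  The
    deviation subtracts the ideal knobs-into-holes angle for the residue's
    heptad position.

    Returns a dict ``label -> list of (resid, heptad_position, crick_deg,
    deviation_deg)``.
    """
    ideal = ideal_ladder or ideal_crick_ladder()
    fits = {}
    for label, ca_idx in bundle.helix_ca.items():
        if ca_idx.size < 7:
            raise GeometryError(f"helix {label}: too few C-alpha for an axis fit")
        hd = bundle.helices[label]
        orient = (frame.coords[hd.head_atoms].mean(axis=0)
                  - frame.coords[hd.tail_atoms].mean(axis=0))
        fits[label] = _fit_axis(frame.coords[ca_idx], orient)
    # bundle axis from the four helix axes (mean direction and center)
    dirs = np.array([a for a, _ in fits.values()])
    bundle_axis = dirs.mean(axis=0)
    bundle_axis /= np.linalg.norm(bundle_axis)
    bundle_center = np.mean([c for _, c in fits.values()], axis=0)

    profiles: dict[str, list] = {}
    for label, ca_idx in bundle.helix_ca.items():
        axis, center = fits[label]
        a_resid = bundle.register_a.get(label)
        rows = []
        for idx in ca_idx:
            x = frame.coords[idx]
            resid = int(frame.resids[idx])
            p = center + ((x - center) @ axis) * axis      # axis point for residue
            b = bundle_center + ((p - bundle_center) @ bundle_axis) * bundle_axis
            u = x - p
            w = b - p
            u -= (u @ axis) * axis
            w -= (w @ axis) * axis
            if np.linalg.norm(u) < 1e-8 or np.linalg.norm(w) < 1e-8:
                raise GeometryError(f"helix {label}: degenerate Crick geometry "
                                    f"at residue {resid}")
            sin_t = axis @ np.cross(w, u)
            cos_t = u @ w
            crick = math.degrees(math.atan2(sin_t, cos_t))
            if a_resid is None:
                pos, dev = "?", float("nan")
            else:
                pos = "abcdefg"[(resid - a_resid) % 7]
                dev = float(_wrap_deg(crick - ideal[pos]))
            rows.append((resid, pos, crick, dev))
        profiles[label] = rows
    return profiles


# ---------------------------------------------------------------------------
# piston-state classifier

def classify_piston_state(z, threshold: float = 0.5,
                          out_of_register_cut: float = 3.0) -> StateLabel:
    """Classify a frame by its four piston values (N1, C1, N2, C2).

    The two diagonal helix pairs (N1 with C2, N2 with C1) move together: a
    pair counts as *shifted* when its N helix moved up (> +threshold) and
    its partner C helix moved down (< -threshold).  P00 = neither pair
    shifted and all pistons small; P10 = only the N1/C2 pair; P01 = only
    the N2/C1 pair; P11 = both; anything else is OTHER.  Candidates with
    any |z| at or beyond ``out_of_register_cut`` are OTHER with the
    out-of-register flag set (a register slip of the hydrophobic layers,
    treated as misfolded rather than functional).
    """
    z = np.asarray(z, dtype=float)
    if z.shape != (4,) or not np.all(np.isfinite(z)):
        raise ValueError("need four finite piston values (N1, C1, N2, C2)")
    n1, c1, n2, c2 = z
    if np.any(np.abs(z) >= out_of_register_cut):
        return StateLabel("OTHER", out_of_register=True)
    pair1 = n1 > threshold and c2 < -threshold      # N1 up, C2 down
    pair2 = n2 > threshold and c1 < -threshold      # N2 up, C1 down
    small = np.abs(z) < threshold
    if small.all():
        return StateLabel("P00")
    if pair1 and pair2:
        return StateLabel("P11")
    if pair1 and small[1] and small[2]:
        return StateLabel("P10")
    if pair2 and small[0] and small[3]:
        return StateLabel("P01")
    return StateLabel("OTHER")


# ---------------------------------------------------------------------------
# probability surfaces

def neg_log_probability_surface(samples, bins: int = 50,
                                ranges=None, weights=None,
                                axis_labels=None,
                                pad_fraction: float = 0.05) -> SurfaceGrid:
    """Negative log of the (optionally weighted) probability histogram, in kT.

    ``samples`` is (n,) for 1D or (n, d) with d <= 2; bins default to 50
    per axis over the observed range padded by 5%.  Bins sum to one before
    the log; empty bins are masked; the minimum is shifted to zero.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 1 or x.shape[1] > 2:
        raise ValueError("need >= 1 sample on 1 or 2 axes")
    d = x.shape[1]
    if ranges is None:
        ranges = []
        for k in range(d):
            lo, hi = x[:, k].min(), x[:, k].max()
            pad = (hi - lo) * pad_fraction
            if pad == 0.0:
                pad = max(abs(lo), 1.0) * 1e-6
            ranges.append((lo - pad, hi + pad))
    hist, edges = np.histogramdd(x, bins=bins, range=ranges, weights=weights)
    total = hist.sum()
    p = hist / total
    occupied = int((hist > 0).sum())
    low_info = occupied <= 1
    if low_info:
        warnings.warn("all samples fall in a single bin; surface carries "
                      "little information", stacklevel=2)
    vals = np.ma.masked_where(p <= 0.0, -np.log(p, where=p > 0,
                                                out=np.zeros_like(p)))
    vals = vals - vals.min()
    return SurfaceGrid(edges=[np.asarray(e) for e in edges],
                       values=vals, units="kT",
                       axis_labels=list(axis_labels or []),
                       low_information=low_info)
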