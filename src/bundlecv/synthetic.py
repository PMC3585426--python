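"""Synthetic alpha-helices and four-helix bundles with injectable motions.

The generator emulates a parallel four-helix bundle of the kind found in
dimeric signal-relay domains: two monomers, each contributing an N-terminal
helix (labels N1, N2) and a C-terminal helix (C1, C2), packed around a
common axis with a small inter-monomer tilt so the bundle resembles a cone.
Piston shifts, axial rotations, monomer tilts and Gaussian positional noise
can be injected with known magnitudes, which makes the bundle the ground
truth for validating the collective variables and analyses.

Helix backbones are built on an exact cylindrical parametrization of the
C-alpha trace; N, C and O are placed at fixed cylindrical offsets derived
from ideal internal coordinates (phi = -57.8 deg, psi = -47 deg), which is
accurate enough for the i -> i+4 hydrogen-bond criterion to hold along the
whole helix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .analysis import BundleDefinition
from .cv import HelixDefinition, ReferenceModel
from .geometry import Frame, GeometryError, kabsch_superpose

# cylindrical offsets (radius A, phase deg, axial offset A) of backbone atoms
# relative to the C-alpha helix, for a right-handed helix winding +phase per
# residue along +z; derived from ideal internal coordinates
BACKBONE_OFFSETS = {
    "N": (1.565, -26.89, -0.913),
    "C": (1.678, +26.84, +1.064),
    "O": (1.935, +20.70, +2.252),
}

HEPTAD = "abcdefg"


@dataclass
class IdealHelixParams:
    """Geometry of one ideal alpha-helix."""

    n_residues: int = 22
    rise: float = 1.5          # A per residue
    twist: float = 100.0       # deg per residue
    radius: float = 2.3        # A, C-alpha helix radius
    chain: str = "A"
    start_resid: int = 1
    phase: float = 0.0         # deg, azimuth of the first C-alpha

    def __post_init__(self) -> None:
        if self.n_residues < 8:
            raise ValueError("need at least 8 residues per helix")
        if self.rise <= 0 or self.radius <= 0:
            raise ValueError("rise and radius must be positive")
        if not 0 < self.twist < 180:
            raise ValueError("twist must lie in (0, 180) deg")


@dataclass
class BundleLayout:
    """Placement of the four helices of a HAMP-like parallel bundle.

    The four helix axes start parallel to +z at the corners of a square of
    side ``interhelix_distance`` (N1 and N2 on one diagonal, C1 and C2 on
    the other, so each monomer occupies one side).  Both monomers are then
    tilted toward each other by ``cone_half_angle`` about an axis through
    the bundle tip (the C-terminal end), giving an inter-monomer tilt of
    twice the half-angle.  All chains run N -> C along +z, the parallel
    arrangement characteristic of HAMP bundles.
    """

    interhelix_distance: float = 10.1   # A between adjacent helix axes
    cone_half_angle: float = 9.0        # deg; monomer tilt = 2x this
    n_residues: int = 22                # phase-commensurate: head and tail
                                        # 4-Ca groups share the same azimuth,
                                        # so helix vectors are exactly axial
    helical_margin: int = 4             # residues outside the analysis selection

    def __post_init__(self) -> None:
        if self.interhelix_distance <= 4.0:
            raise ValueError("helices would collapse: interhelix distance too small")
        if not 0 <= self.cone_half_angle < 45:
            raise ValueError("cone half-angle must lie in [0, 45) deg")


# residue numbering follows the HAMP convention: N helices around 278-298,
# C helices around 308-328, with the analysis selections 282-296 / 312-326
N_START, C_START = 278, 308
ROTREF_N = (283, 287, 291, 295)
ROTREF_C = (313, 317, 321, 325)
HELICAL_N = (282, 296)
HELICAL_C = (312, 326)


def build_ideal_helix(p: IdealHelixParams) -> Frame:
    """An ideal alpha-helix (backbone N, CA, C, O) along +z, base at z = 0."""
    names, chains, resids, coords = [], [], [], []
    for i in range(p.n_residues):
        theta = math.radians(p.phase + i * p.twist)
        z = i * p.rise
        for name in ("N", "CA", "C", "O"):
            if name == "CA":
                r, dphi, dz = p.radius, 0.0, 0.0
            else:
                r, dphi, dz = BACKBONE_OFFSETS[name]
            ang = theta + math.radians(dphi)
            coords.append([r * math.cos(ang), r * math.sin(ang), z + dz])
            names.append(name)
            chains.append(p.chain)
            resids.append(p.start_resid + i)
    return Frame(np.array(coords), np.array(chains), np.array(resids, dtype=int),
                 np.array(names))


def _rotation_about(axis: np.ndarray, angle_deg: float, pivot: np.ndarray):
    rot = Rotation.from_rotvec(np.asarray(axis, dtype=float) /
                               np.linalg.norm(axis) * math.radians(angle_deg))

    def apply(x: np.ndarray) -> np.ndarray:
        return rot.apply(x - pivot) + pivot
    return apply


def build_bundle(layout: BundleLayout | None = None,
                 helix_params: dict[str, IdealHelixParams] | None = None,
                 register_a: dict[str, int] | None = None,
                 ideal_a_angle: float = 19.5,
                 ) -> tuple[Frame, BundleDefinition, ReferenceModel]:
    """Build the reference four-helix bundle.

    Returns the frame, a :class:`BundleDefinition` with auto-generated helix
    definitions (head = C-terminal four C-alpha, tail = N-terminal four,
    rotational reference at the conventional residues), and a
    :class:`ReferenceModel` aligned over the helical C-alpha selection.  By
    construction all four piston and rotation CVs evaluate to zero on the
    returned frame, and the monomer tilt equals ``2 * cone_half_angle``.

    ``register_a`` optionally pins the heptad register (residue number of an
    'a' position per helix label); the helix phase is then chosen so that
    the Crick angle of 'a' residues equals ``ideal_a_angle``.
    """
    layout = layout or BundleLayout()
    w = layout.interhelix_distance / 2.0
    n_res = layout.n_residues
    # (x, y) base positions; monomer 1 at x < 0, N helices on one diagonal
    placements = {
        "N1": (np.array([-w, -w]), "A", N_START),
        "C1": (np.array([-w, +w]), "A", C_START),
        "N2": (np.array([+w, +w]), "B", N_START),
        "C2": (np.array([+w, -w]), "B", C_START),
    }
    helix_params = helix_params or {}
    register_a = register_a or {}

    frames: dict[str, Frame] = {}
    for label, (xy, chain, start) in placements.items():
        p = helix_params.get(label)
        if p is None:
            p = IdealHelixParams(n_residues=n_res, chain=chain, start_resid=start)
        # phase: point the core face ('a' layer) toward the bundle axis
        az_center = math.degrees(math.atan2(-xy[1], -xy[0]))
        a_resid = register_a.get(label, start + layout.helical_margin)
        p.phase = (az_center + ideal_a_angle
                   - (a_resid - p.start_resid) * p.twist)
        helix = build_ideal_helix(p)
        helix.coords[:, 0] += xy[0]
        helix.coords[:, 1] += xy[1]
        frames[label] = helix

    # tilt the monomers toward each other about the bundle tip (C-terminal
    # end, top of the bundle since chains run N -> C along +z)
    tip = np.array([0.0, 0.0, (n_res - 1) * 1.5])
    if layout.cone_half_angle != 0.0:
        rot1 = _rotation_about([0, 1, 0], +layout.cone_half_angle, tip)
        rot2 = _rotation_about([0, 1, 0], -layout.cone_half_angle, tip)
        for label in ("N1", "C1"):
            frames[label].coords[:] = rot1(frames[label].coords)
        for label in ("N2", "C2"):
            frames[label].coords[:] = rot2(frames[label].coords)

    order = ("N1", "C1", "N2", "C2")
    frame = Frame(
        np.concatenate([frames[k].coords for k in order]),
        np.concatenate([frames[k].chains for k in order]),
        np.concatenate([frames[k].resids for k in order]),
        np.concatenate([frames[k].names for k in order]),
    )

    # steric sanity: no two C-alpha from different helices closer than 2 A
    offsets = np.cumsum([0] + [frames[k].n_atoms for k in order])
    ca_by_helix = {}
    for k, label in enumerate(order):
        lo, hi = offsets[k], offsets[k + 1]
        local = np.flatnonzero(frame.names[lo:hi] == "CA") + lo
        ca_by_helix[label] = local
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            d = np.linalg.norm(frame.coords[ca_by_helix[a], None, :] -
                               frame.coords[None, ca_by_helix[b], :], axis=-1)
            if d.min() < 2.0:
                raise GeometryError(f"steric collapse between helices {a} and {b}")

    helices = {}
    helix_ca = {}
    for label in order:
        ca = ca_by_helix[label]
        resids = frame.resids[ca]
        rotref_resids = ROTREF_N if label.startswith("N") else ROTREF_C
        rotref = ca[np.isin(resids, rotref_resids)]
        helices[label] = HelixDefinition(
            head_atoms=ca[-4:], tail_atoms=ca[:4], rotref_atoms=rotref, label=label)
        helix_ca[label] = ca

    sel_parts = []
    for label in order:
        lo, hi = (HELICAL_N if label.startswith("N") else HELICAL_C)
        ca = ca_by_helix[label]
        resids = frame.resids[ca]
        sel_parts.append(ca[(resids >= lo) & (resids <= hi)])
    helical_selection = np.concatenate(sel_parts)

    bundle = BundleDefinition(
        helices=helices, helical_selection=helical_selection, helix_ca=helix_ca,
        hbond_ranges={"A": [(N_START, N_START + n_res - 1),
                            (C_START, C_START + n_res - 1)],
                      "B": [(N_START, N_START + n_res - 1),
                            (C_START, C_START + n_res - 1)]},
        register_a={label: register_a.get(
            label, placements[label][2] + layout.helical_margin)
            for label in order},
        tilt_pivot=tip,
    )
    ref = ReferenceModel(frame.copy(), helical_selection)
    return frame, bundle, ref


def _helix_axis(frame: Frame, bundle: BundleDefinition, label: str):
    hd = bundle.helices[label]
    h = frame.coords[hd.head_atoms].mean(axis=0)
    t = frame.coords[hd.tail_atoms].mean(axis=0)
    return h, t


def inject_motion(frame: Frame, bundle: BundleDefinition,
                  piston: dict[str, float] | None = None,
                  rotation: dict[str, float] | None = None,
                  tilt: float = 0.0,
                  noise_sd: float = 0.0,
                  seed: int | None = None) -> Frame:
    """Apply rigid per-helix / per-monomer motions plus Gaussian noise.

    ``piston`` maps helix label to a displacement (A) along the helix's own
    axis (positive toward the head); ``rotation`` maps label to an axial
    rotation (deg, right-hand rule about the head-tail axis); ``tilt`` is an
    increment (deg) of the inter-monomer tilt, applied symmetrically by
    rotating each monomer about the bundle tilt pivot.  Noise is i.i.d.
    Gaussian with the given standard deviation, deterministic under
    ``seed``.
    """
    piston = piston or {}
    rotation = rotation or {}
    for val, limit, what in ((max(map(abs, piston.values()), default=0.0), 3.0, "piston"),
                             (max(map(abs, rotation.values()), default=0.0), 45.0, "rotation"),
                             (abs(tilt), 45.0, "tilt")):
        if val > limit:
            raise ValueError(f"{what} motion exceeds the supported range")
    out = frame.copy()
    monomers = {"1": ("N1", "C1"), "2": ("N2", "C2")}
    if tilt != 0.0:
        pivot = bundle.tilt_pivot
        for sign, labels in ((+1.0, monomers["1"]), (-1.0, monomers["2"])):
            rot = _rotation_about([0, 1, 0], sign * tilt / 2.0, pivot)
            for label in labels:
                idx = bundle.helix_atoms(out, label)
                out.coords[idx] = rot(out.coords[idx])
    for label, delta in piston.items():
        h, t = _helix_axis(out, bundle, label)
        axis = (h - t) / np.linalg.norm(h - t)
        idx = bundle.helix_atoms(out, label)
        out.coords[idx] += delta * axis
    for label, phi in rotation.items():
        h, t = _helix_axis(out, bundle, label)
        rot = _rotation_about(h - t, phi, 0.5 * (h + t))
        idx = bundle.helix_atoms(out, label)
        out.coords[idx] = rot(out.coords[idx])
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        out.coords = out.coords + rng.normal(0.0, noise_sd, out.coords.shape)
    return out


def generate_trajectory(start: Frame, end: Frame, bundle: BundleDefinition,
                        n_frames: int, noise_sd: float = 0.0,
                        seed: int | None = None) -> list[Frame]:
    """Linear rigid-motion interpolation between two bundle conformations.

    For each helix the start -> end map is expressed as a rigid transform
    (via Kabsch superposition) and interpolated with a rotation slerp and a
    linear translation; i.i.d. Gaussian noise is then added per frame.
    ``n_frames=1`` returns the start frame.
    """
    if start.n_atoms != end.n_atoms or not np.array_equal(start.names, end.names):
        raise GeometryError("start and end frames have incompatible atom sets")
    rng = np.random.default_rng(seed)
    fractions = np.linspace(0.0, 1.0, n_frames) if n_frames > 1 else np.array([0.0])
    per_helix = {}
    for label in bundle.helices:
        idx = bundle.helix_atoms(start, label)
        tf, _ = kabsch_superpose(start, end, idx)
        rot = Rotation.from_matrix(tf.rotation)
        c0 = start.coords[idx].mean(axis=0)
        c1 = end.coords[idx].mean(axis=0)
        slerp = Slerp([0.0, 1.0], Rotation.concatenate(
            [Rotation.identity(), rot]))
        per_helix[label] = (idx, c0, c1 - c0, slerp)
    frames = []
    for k, f in enumerate(fractions):
        out = start.copy()
        for idx, c0, t, slerp in per_helix.values():
            r = slerp([f])[0]
            out.coords[idx] = r.apply(start.coords[idx] - c0) + c0 + f * t
        if noise_sd > 0.0:
            out.coords = out.coords + rng.normal(0.0, noise_sd, out.coords.shape)
        out.time = float(k)
        frames.append(out)
    return frames
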