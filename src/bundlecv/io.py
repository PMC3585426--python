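"""Readers and writers: PDB/XTC/DCD structures and trajectories (through
MDAnalysis), COLVAR/HILLS whitespace tables, gridded surface text files and
the YAML run configuration."""

from __future__ import annotations

import hashlib
import logging
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import BundleDefinition, SurfaceGrid
from .cv import HelixDefinition
from .geometry import Frame, GeometryError
from .metad import Hill, MetadError, WTMetadParams

log = logging.getLogger(__name__)


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _universe_to_frame(u, atoms=None, time=None) -> Frame:
    atoms = u.atoms if atoms is None else atoms
    chains = (atoms.chainIDs if hasattr(atoms, "chainIDs") else atoms.segids)
    return Frame(atoms.positions.astype(float).copy(),
                 np.asarray(chains), atoms.resids.copy(),
                 np.asarray(atoms.names),
                 time=time)


def _filter_altlocs(u):
    """Keep the highest-occupancy altloc per (chain, resid, name)."""
    mda_atoms = u.atoms
    if not hasattr(mda_atoms, "altLocs"):
        return mda_atoms
    alt = np.asarray(mda_atoms.altLocs)
    if np.all((alt == "") | (alt == " ")):
        return mda_atoms
    occ = (mda_atoms.occupancies if hasattr(mda_atoms, "occupancies")
           else np.ones(len(mda_atoms)))
    chains = (mda_atoms.chainIDs if hasattr(mda_atoms, "chainIDs")
              else mda_atoms.segids)
    best: dict[tuple, tuple[float, int]] = {}
    for i, key in enumerate(zip(chains, mda_atoms.resids, mda_atoms.names)):
        if key not in best or occ[i] > best[key][0]:
            best[key] = (occ[i], i)
    keep = sorted(i for _, i in best.values())
    n_drop = len(mda_atoms) - len(keep)
    if n_drop:
        log.info("dropped %d alternate-location atoms (kept highest occupancy)",
                 n_drop)
    return mda_atoms[keep]


def read_structure(path, model: int = 0) -> Frame:
    """Read a structure file into a :class:`Frame`.

    Multi-model files expose ``model`` selection (0-based).  Alternate
    locations are reduced to the highest-occupancy copy.
    """
    mda = _import_mda()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        u = mda.Universe(str(path))
    except Exception as exc:
        raise GeometryError(f"could not parse structure {path}: {exc}") from exc
    if model:
        try:
            u.trajectory[model]
        except (IndexError, IOError) as exc:
            raise GeometryError(f"{path} has no model {model}") from exc
    atoms = _filter_altlocs(u)
    return _universe_to_frame(u, atoms)


def read_trajectory(path, topology=None):
    """Iterate the frames of a trajectory (multi-model PDB, XTC or DCD).

    XTC/DCD need a ``topology`` structure file.  Frame times (ps) are
    propagated when the format records them.  Yields :class:`Frame`.
    """
    mda = _import_mda()
    path = Path(path)
    try:
        if topology is None:
            u = mda.Universe(str(path))
        else:
            u = mda.Universe(str(topology), str(path))
    except Exception as exc:
        raise GeometryError(f"could not open trajectory {path}: {exc}") from exc
    for ts in u.trajectory:
        with warnings.catch_warnings():
            # formats without time metadata fall back to a frame counter
            warnings.simplefilter("ignore", UserWarning)
            t = float(ts.time) if ts.time is not None else None
        yield _universe_to_frame(u, time=t)


def write_pdb(frames, path) -> None:
    """Write one frame (or a sequence, as a multi-model PDB)."""
    mda = _import_mda()
    if isinstance(frames, Frame):
        frames = [frames]
    first = frames[0]
    n = first.n_atoms
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("names", list(first.names))
    u.add_TopologyAttr("resids", list(first.resids))
    u.add_TopologyAttr("chainIDs", [str(c)[:1] or "A" for c in first.chains])
    u.add_TopologyAttr("resnames", ["ALA"] * n)
    u.add_TopologyAttr("elements", [str(nm)[:1] for nm in first.names])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n, multiframe=len(frames) > 1) as w:
            for fr in frames:
                u.atoms.positions = fr.coords
                w.write(u.atoms)


def write_trajectory(frames, path, dt: float = 1.0) -> None:
    """Write frames to a coordinate trajectory (XTC or DCD by extension)."""
    mda = _import_mda()
    frames = list(frames)
    n = frames[0].n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n) as w:
            u = mda.Universe.empty(n, trajectory=True)
            for k, fr in enumerate(frames):
                u.atoms.positions = fr.coords
                u.trajectory.ts.time = fr.time if fr.time is not None else k * dt
                u.trajectory.ts.frame = k
                u.trajectory.ts.dimensions = [200, 200, 200, 90, 90, 90]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# COLVAR / HILLS dialect

def provenance_lines(seed=None, config_hash=None) -> list[str]:
    lines = [f"#! SET bundlecv_version {__version__}"]
    if seed is not None:
        lines.append(f"#! SET seed {seed}")
    if config_hash is not None:
        lines.append(f"#! SET config_hash {config_hash}")
    return lines


def write_colvar(path, fields: list[str], rows: np.ndarray,
                 seed=None, config_hash=None) -> None:
    """Whitespace COLVAR table with a ``#! FIELDS`` header."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for line in provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        for row in rows:
            fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


def read_colvar(path):
    """Read a COLVAR table; returns (fields, data array)."""
    fields = None
    data = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#! FIELDS"):
                fields = line.split()[2:]
            elif line.startswith("#"):
                continue
            else:
                data.append([float(x) for x in line.split()])
    if fields is None:
        raise MetadError(f"{path}: missing '#! FIELDS' header")
    return fields, np.asarray(data)


def write_hills(path, hills: list[Hill], params: WTMetadParams,
                cv_names=None, seed=None, config_hash=None) -> None:
    """HILLS table: time, centers, sigmas, height, bias factor."""
    ndim = len(params.widths)
    cv_names = list(cv_names or [f"cv{k+1}" for k in range(ndim)])
    fields = (["time"] + cv_names + [f"sigma_{n}" for n in cv_names]
              + ["height", "biasf"])
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for line in provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        for h in hills:
            row = ([h.time] + list(h.center) + list(h.width)
                   + [h.height, params.bias_factor])
            # %.17g: exact float round-trip, so replaying an emitted HILLS
            # file reproduces the in-run bias bit for bit
            fh.write(" ".join(f"{x:.17g}" for x in row) + "\n")


def read_hills(path):
    """Read a HILLS table; returns (hills list, bias factor, cv names)."""
    fields, data = read_colvar(path)
    if "height" not in fields or "biasf" not in fields:
        raise MetadError(f"{path}: not a HILLS table (missing height/biasf)")
    h_col = fields.index("height")
    ndim = (h_col - 1) // 2
    cv_names = fields[1:1 + ndim]
    hills = [Hill(row[0], row[1:1 + ndim], row[1 + ndim:1 + 2 * ndim], row[h_col])
             for row in data]
    biasf = float(data[0, fields.index("biasf")]) if len(data) else None
    return hills, biasf, cv_names


def write_surface(path, surface: SurfaceGrid, seed=None, config_hash=None) -> None:
    """Gridded surface as text: bin centers per axis, then the value."""
    ndim = len(surface.edges)
    labels = surface.axis_labels or [f"cv{k+1}" for k in range(ndim)]
    centers = surface.centers
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(labels)
                 + f" value({surface.units})\n")
        for line in provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        it = np.ndindex(*surface.values.shape)
        for idx in it:
            if np.ma.is_masked(surface.values[idx]):
                continue
            coords = [centers[k][idx[k]] for k in range(ndim)]
            fh.write(" ".join(f"{x:.10g}" for x in coords)
                     + f" {float(surface.values[idx]):.10g}\n")


def plot_surface(surface: SurfaceGrid, path, contour_interval: float = 1.0) -> None:
    """Contour (2D) or line (1D) rendering of a surface, written to a file.

    Contour lines are drawn every ``contour_interval`` in the surface's
    units (conventionally 1 kT).  Requires matplotlib.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = surface.axis_labels or [f"cv{k+1}" for k in range(len(surface.edges))]
    if len(surface.edges) == 1:
        ax.plot(surface.centers[0], surface.values)
        ax.set_xlabel(labels[0])
        ax.set_ylabel(f"value ({surface.units})")
    else:
        top = float(surface.values.max())
        levels = np.arange(0.0, top + contour_interval, contour_interval)
        cs = ax.contour(surface.centers[0], surface.centers[1],
                        surface.values.T, levels=levels)
        ax.clabel(cs, inline=True, fontsize=7)
        ax.set_xlabel(labels[0])
        ax.set_ylabel(labels[1])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# configuration

_KNOWN_KEYS = {"structure", "trajectory", "helices", "helical_selection",
               "hbond_ranges", "register_a", "output", "seed", "log_level",
               "metad", "analysis"}
_KNOWN_HELIX_KEYS = {"chain", "start", "end", "rotref"}


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path) -> dict:
    """Load and validate the YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for label, spec in (cfg.get("helices") or {}).items():
        bad = set(spec) - _KNOWN_HELIX_KEYS
        if bad:
            raise ValueError(f"helix {label}: unknown keys {sorted(bad)}")
    for key in ("structure", "trajectory"):
        val = cfg.get(key)
        paths = val if isinstance(val, list) else [val] if val else []
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"{key} path does not exist: {p}")
    return cfg


def compile_bundle(cfg: dict, frame: Frame) -> BundleDefinition:
    """Compile helix/selection residue ranges from a config into atom indices."""
    helices = {}
    helix_ca = {}
    for label, spec in (cfg.get("helices") or {}).items():
        chain = str(spec["chain"])
        lo, hi = int(spec["start"]), int(spec["end"])
        ca = frame.select(chain=chain, resid_range=(lo, hi), name="CA")
        if ca.size < 8:
            raise GeometryError(
                f"helix {label}: fewer than 8 C-alpha atoms in {chain}:{lo}-{hi}")
        order = np.argsort(frame.resids[ca])
        ca = ca[order]
        rotref_resids = [int(r) for r in spec["rotref"]]
        rotref = ca[np.isin(frame.resids[ca], rotref_resids)]
        helices[label] = HelixDefinition(ca[-4:], ca[:4], rotref, label=label)
        helix_ca[label] = ca
    sel_parts = []
    for item in cfg.get("helical_selection") or []:
        ca = frame.select(chain=str(item["chain"]),
                          resid_range=(int(item["start"]), int(item["end"])),
                          name="CA")
        sel_parts.append(ca)
    if not sel_parts:
        sel_parts = list(helix_ca.values())
    hbond_ranges: dict[str, list[tuple[int, int]]] = {}
    for item in cfg.get("hbond_ranges") or []:
        hbond_ranges.setdefault(str(item["chain"]), []).append(
            (int(item["start"]), int(item["end"])))
    return BundleDefinition(
        helices=helices, helical_selection=np.concatenate(sel_parts),
        helix_ca=helix_ca, hbond_ranges=hbond_ranges,
        register_a={k: int(v) for k, v in (cfg.get("register_a") or {}).items()})
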