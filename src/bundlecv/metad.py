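"""Well-tempered metadynamics: hills, walls, Langevin driver, reweighting.

The engine biases 1-4 collective variables with Gaussian hills whose height
decays exponentially with the accumulated bias (well-tempered rescaling,
``h = h0 exp(-V(s,t) / kB dT)`` with ``dT = (gamma - 1) T``).  At
convergence the bias relates to the free energy as
``F(s) = -(T + dT)/dT V(s)``.  Half-sided polynomial wall potentials keep
the CVs inside a chosen window.  The time-dependent bias offset ``c(t)``
turns instantaneous bias values into per-frame weights
``w ~ exp(+beta [V(s_t, t) - c(t)])`` for reweighting unbiased observables.

The dynamical backend is a BAOAB Langevin integrator on analytic toy
potentials; the engine can equally post-process externally produced HILLS
and CV records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

KB = 0.008314462618  # kJ/mol/K


class MetadError(ValueError):
    """Raised for invalid metadynamics setups."""


@dataclass
class Hill:
    """One deposited Gaussian: center/width per CV, height in kJ/mol."""

    time: float
    center: np.ndarray
    width: np.ndarray
    height: float

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.width = np.atleast_1d(np.asarray(self.width, dtype=float))
        if np.any(self.width <= 0):
            raise MetadError("hill widths must be positive")
        if self.height < 0:
            raise MetadError("hill height must be non-negative")


@dataclass
class WTMetadParams:
    """Well-tempered metadynamics parameters.

    ``bias_factor`` is gamma = (T + dT)/T; the fictitious CV temperature
    excess is ``dT = (gamma - 1) T``.  ``pace`` is the hill deposition
    interval in ps, ``initial_height`` in kJ/mol, ``widths`` one sigma per
    CV in CV units.
    """

    temperature: float = 298.0
    bias_factor: float = 10.0
    pace: float = 2.0
    initial_height: float = 0.25
    widths: tuple = (0.2,)

    def __post_init__(self) -> None:
        if self.bias_factor <= 1.0:
            raise MetadError("bias factor must exceed 1")
        if self.pace <= 0 or self.initial_height <= 0:
            raise MetadError("pace and initial height must be positive")
        self.widths = tuple(float(w) for w in self.widths)
        if any(w <= 0 for w in self.widths):
            raise MetadError("hill widths must be positive")

    @property
    def delta_t(self) -> float:
        return (self.bias_factor - 1.0) * self.temperature


@dataclass
class WallSpec:
    """Half-sided polynomial wall: ``kappa ((s - s0)/r)^e`` beyond the bound."""

    cv_index: int
    bound: float
    side: str                  # "upper" or "lower"
    kappa: float = 500.0
    rescale: float = 1.0
    exponent: int = 4

    def __post_init__(self) -> None:
        if self.side not in ("upper", "lower"):
            raise MetadError("wall side must be 'upper' or 'lower'")
        if self.kappa <= 0 or self.rescale <= 0:
            raise MetadError("wall kappa and rescale must be positive")
        if self.exponent < 2 or self.exponent % 2:
            raise MetadError("wall exponent must be an even integer >= 2")

    def energy(self, s: float) -> float:
        x = self._excess(s)
        return 0.0 if x == 0.0 else self.kappa * x ** self.exponent

    def force(self, s: float) -> float:
        """-dE/ds at the scalar CV value."""
        x = self._excess(s)
        if x == 0.0:
            return 0.0
        sign = 1.0 if self.side == "upper" else -1.0
        return -sign * self.kappa * self.exponent * x ** (self.exponent - 1) / self.rescale

    def _excess(self, s: float) -> float:
        if self.side == "upper":
            return max(s - self.bound, 0.0) / self.rescale
        return max(self.bound - s, 0.0) / self.rescale


def wall_energy(spec: WallSpec, s: float) -> float:
    """Wall energy (kJ/mol) at a scalar CV value; exactly zero inside."""
    return spec.energy(s)


class BiasState:
    """Accumulated hills + walls + parameters of one metadynamics run.

    Hills are stored in deposition order in growable arrays.  When a grid is
    attached the summed bias on the grid is maintained incrementally with
    the same accumulation routine used to replay a HILLS record, so an
    in-run grid and a replayed grid are bit-identical.
    """

    def __init__(self, params: WTMetadParams, walls: list[WallSpec] | None = None,
                 grid_edges: list[np.ndarray] | None = None) -> None:
        self.params = params
        self.walls = list(walls or [])
        self.ndim = len(params.widths)
        self._times: list[float] = []
        self._centers: list[np.ndarray] = []
        self._widths: list[np.ndarray] = []
        self._heights: list[float] = []
        self._carr = np.zeros((0, self.ndim))
        self._warr = np.zeros((0, self.ndim))
        self._harr = np.zeros((0,))
        self.c_of_t: list[float] = []
        self.c_times: list[float] = []
        self.grid_edges = grid_edges
        self.grid_centers = None
        self.grid_bias = None
        if grid_edges is not None:
            self.grid_centers = [0.5 * (e[1:] + e[:-1]) for e in grid_edges]
            shape = tuple(len(c) for c in self.grid_centers)
            self.grid_bias = np.zeros(shape)
            self._mesh = np.stack(np.meshgrid(*self.grid_centers, indexing="ij"),
                                  axis=-1)

    # -- hills ------------------------------------------------------------
    @property
    def n_hills(self) -> int:
        return len(self._heights)

    @property
    def hills(self) -> list[Hill]:
        return [Hill(t, c, w, h) for t, c, w, h in
                zip(self._times, self._centers, self._widths, self._heights)]

    def add_hill(self, hill: Hill) -> None:
        if self._times and hill.time < self._times[-1]:
            raise MetadError("hills must be added in time order")
        if hill.center.size != self.ndim:
            raise MetadError("hill dimensionality mismatch")
        self._times.append(float(hill.time))
        self._centers.append(hill.center)
        self._widths.append(hill.width)
        self._heights.append(float(hill.height))
        self._carr = np.asarray(self._centers)
        self._warr = np.asarray(self._widths)
        self._harr = np.asarray(self._heights)
        if self.grid_bias is not None:
            _accumulate_hill_on_grid(self.grid_bias, self._mesh,
                                     hill.center, hill.width, hill.height)
            self._update_c(hill.time)

    def _update_c(self, time: float) -> None:
        beta = 1.0 / (KB * self.params.temperature)
        gamma = self.params.bias_factor
        v = self.grid_bias
        vmax = v.max()
        edge = max(float(v.flat[0]), float(v.flat[-1]))
        if edge > v.min() + KB * self.params.temperature:
            warnings.warn("bias at the grid edge exceeds the minimum by "
                          "more than kT; the grid may be too narrow",
                          stacklevel=2)
        num = np.exp(beta * gamma / (gamma - 1.0) * (v - vmax)).sum()
        den = np.exp(beta / (gamma - 1.0) * (v - vmax)).sum()
        c = (math.log(num / den)) / beta + vmax
        self.c_of_t.append(c)
        self.c_times.append(float(time))

    # -- evaluation -------------------------------------------------------
    def hills_value(self, s) -> float:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self.n_hills == 0:
            return 0.0
        z = (s[None, :] - self._carr) / self._warr
        return float(np.sum(self._harr * np.exp(-0.5 * np.sum(z * z, axis=1))))

    def hills_value_and_force(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self.n_hills == 0:
            return 0.0, np.zeros(self.ndim)
        diff = s[None, :] - self._carr
        z = diff / self._warr
        g = self._harr * np.exp(-0.5 * np.sum(z * z, axis=1))
        value = float(g.sum())
        force = np.sum(g[:, None] * diff / self._warr ** 2, axis=0)
        return value, force

    def walls_value_and_force(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        value = 0.0
        force = np.zeros(self.ndim)
        for w in self.walls:
            value += w.energy(float(s[w.cv_index]))
            force[w.cv_index] += w.force(float(s[w.cv_index]))
        return value, force

    def current_c(self) -> float:
        return self.c_of_t[-1] if self.c_of_t else 0.0


def _accumulate_hill_on_grid(grid: np.ndarray, mesh: np.ndarray,
                             center: np.ndarray, width: np.ndarray,
                             height: float) -> None:
    z = (mesh - center) / width
    grid += height * np.exp(-0.5 * np.sum(z * z, axis=-1))


def bias_value_and_force(state: BiasState, s):
    """Total bias V(s) = hills + walls (kJ/mol) and the force -dV/ds."""
    v_h, f_h = state.hills_value_and_force(s)
    v_w, f_w = state.walls_value_and_force(s)
    return v_h + v_w, f_h + f_w


def next_hill_height(state: BiasState, s) -> float:
    """Well-tempered height ``h0 exp(-V(s,t)/(kB dT))`` (hills bias only)."""
    v = state.hills_value(s)
    return state.params.initial_height * math.exp(
        -v / (KB * state.params.delta_t))


def _grid_from_edges(edges):
    centers = [0.5 * (np.asarray(e)[1:] + np.asarray(e)[:-1]) for e in edges]
    mesh = np.stack(np.meshgrid(*centers, indexing="ij"), axis=-1)
    return centers, mesh


def accumulate_hills_on_grid(hills: list[Hill], edges) -> np.ndarray:
    """Sum hills onto a grid, in deposition order (replay of a HILLS record)."""
    centers, mesh = _grid_from_edges(edges)
    grid = np.zeros(mesh.shape[:-1])
    for h in hills:
        _accumulate_hill_on_grid(grid, mesh, h.center, h.width, h.height)
    return grid


def free_energy_from_bias(state_or_hills, edges=None,
                          params: WTMetadParams | None = None):
    """Free-energy surface ``F(s) = -(T+dT)/dT V(s, t_end)``, minimum at 0.

    Accepts a :class:`BiasState` with an attached grid (the in-run bias is
    used directly) or a list of hills plus grid edges and parameters (the
    bias is replayed by summation in deposition order).  Returns
    ``(edges, F)`` with F in kJ/mol.
    """
    from .analysis import SurfaceGrid
    if isinstance(state_or_hills, BiasState):
        state = state_or_hills
        if state.grid_bias is None:
            raise MetadError("BiasState has no attached grid")
        if state.n_hills == 0:
            raise MetadError("no hills deposited")
        v = state.grid_bias.copy()
        edges = state.grid_edges
        params = state.params
    else:
        hills = list(state_or_hills)
        if not hills:
            raise MetadError("no hills deposited")
        if edges is None or params is None:
            raise MetadError("replaying hills needs grid edges and parameters")
        v = accumulate_hills_on_grid(hills, edges)
    gamma = params.bias_factor
    f = -(gamma / (gamma - 1.0)) * v
    f -= f.min()
    return SurfaceGrid(edges=[np.asarray(e) for e in edges],
                       values=np.ma.masked_invalid(f), units="kJ/mol")


def bias_offset_c_of_t(hills: list[Hill], edges, params: WTMetadParams):
    """Recompute the bias offset series c(t) from a hills record.

    The bias is accumulated hill by hill on the grid and after each
    deposition ``c = (1/beta) ln [ int exp(beta gamma/(gamma-1) V) /
    int exp(beta/(gamma-1) V) ]`` is evaluated (the grid volume element
    cancels).  Returns ``(times, c)`` arrays of length ``len(hills)``.
    """
    state = BiasState(params, grid_edges=[np.asarray(e) for e in edges])
    for h in hills:
        state.add_hill(h)
    return np.asarray(state.c_times), np.asarray(state.c_of_t)


def reweight_frames(state: BiasState, times, cv_values,
                    hills: list[Hill] | None = None):
    """Per-frame weights ``w ~ exp(+beta [V(s_t, t) - c(t)])``.

    ``times`` and ``cv_values`` are the COLVAR record; the hills deposited
    up to each frame's time determine the instantaneous bias, and ``c(t)``
    is interpolated as a step function over the deposition series (0 before
    the first hill).  Weights are returned normalized to mean 1.
    """
    times = np.asarray(times, dtype=float)
    cvs = np.atleast_2d(np.asarray(cv_values, dtype=float))
    if cvs.shape[0] != times.size:
        cvs = cvs.T
    if cvs.shape[0] != times.size:
        raise MetadError("CV series does not align with the time series")
    hills = state.hills if hills is None else hills
    if np.any(np.diff(times) < 0):
        raise MetadError("frame times must be sorted")
    beta = 1.0 / (KB * state.params.temperature)
    hill_times = np.asarray([h.time for h in hills])
    c_times = np.asarray(state.c_times)
    c_vals = np.asarray(state.c_of_t)
    scratch = BiasState(state.params)
    log_w = np.empty(times.size)
    k = 0
    for i, (t, s) in enumerate(zip(times, cvs)):
        while k < len(hills) and hill_times[k] <= t:
            scratch.add_hill(hills[k])
            k += 1
        v = scratch.hills_value(s)
        j = np.searchsorted(c_times, t, side="right") - 1
        c = c_vals[j] if j >= 0 else 0.0
        log_w[i] = beta * (v - c)
    log_w -= log_w.max()
    w = np.exp(log_w)
    return w / w.mean()


# ---------------------------------------------------------------------------
# toy dynamics

class DoubleWell:
    """U(x) = a (x^2 - 1)^2 (kJ/mol), the standard bistable test potential."""

    def __init__(self, a: float = 5.0) -> None:
        self.a = a

    def energy(self, x) -> float:
        x = np.atleast_1d(x)
        return float(np.sum(self.a * (x ** 2 - 1.0) ** 2))

    def force(self, x):
        x = np.atleast_1d(x)
        return -4.0 * self.a * x * (x ** 2 - 1.0)


class Harmonic:
    """U(x) = 1/2 k x^2 per dimension (kJ/mol)."""

    def __init__(self, k: float = 1.0) -> None:
        self.k = k

    def energy(self, x) -> float:
        x = np.atleast_1d(x)
        return float(0.5 * self.k * np.sum(x ** 2))

    def force(self, x):
        return -self.k * np.atleast_1d(x)


def langevin_propagate(potential, bias: BiasState | None, x0, dt: float,
                       friction: float, temperature: float, n_steps: int,
                       seed: int | None = None, mass: float = 1.0,
                       bound: float = 100.0, record_stride: int = 1):
    """BAOAB Langevin dynamics on an analytic potential, optionally biased.

    Positions in A, time in ps, energies in kJ/mol, mass in amu.  The bias
    (if given) is evaluated with its current hills and walls and is static
    during the call.  Returns ``(times, positions, bias_values)`` sampled
    every ``record_stride`` steps.  Raises if the trajectory leaves
    ``|x| > bound`` (divergence guard) or if ``dt * friction >= 0.1``
    (documented stability check).
    """
    if dt * friction >= 0.1:
        raise MetadError("dt * friction must stay below 0.1 for stability")
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    ndim = x.size
    rng = np.random.default_rng(seed)
    kt = KB * temperature
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(kt / mass * (1.0 - c1 * c1))
    v = rng.normal(0.0, math.sqrt(kt / mass), ndim) if temperature > 0 else np.zeros(ndim)

    def total_force(pos):
        f = np.atleast_1d(potential.force(pos)).astype(float)
        if bias is not None:
            _, fb = bias_value_and_force(bias, pos)
            f = f + fb
        return f

    f = total_force(x)
    times, xs, vbias = [], [], []
    for step in range(n_steps):
        v += 0.5 * dt * f / mass
        x += 0.5 * dt * v
        if temperature > 0:
            v = c1 * v + c2 * rng.normal(size=ndim)
        else:
            v = c1 * v
        x += 0.5 * dt * v
        f = total_force(x)
        v += 0.5 * dt * f / mass
        if np.any(np.abs(x) > bound):
            raise MetadError(f"trajectory diverged at step {step}: |x| > {bound}")
        if (step + 1) % record_stride == 0:
            times.append((step + 1) * dt)
            xs.append(x.copy())
            vbias.append(0.0 if bias is None else bias.hills_value(x))
    return np.asarray(times), np.asarray(xs), np.asarray(vbias)


@dataclass
class MetadRun:
    """Everything produced by one well-tempered metadynamics run."""

    state: BiasState
    colvar_times: np.ndarray
    colvar_values: np.ndarray       # (n_frames, ndim)
    colvar_bias: np.ndarray         # hills bias at the frame, kJ/mol
    colvar_c: np.ndarray            # c(t) at the frame, kJ/mol


def run_well_tempered_metadynamics(potential, params: WTMetadParams,
                                   walls: list[WallSpec] | None,
                                   x0, n_steps: int, dt: float,
                                   friction: float, seed: int | None = None,
                                   grid_edges=None, colvar_stride: int = 10,
                                   mass: float = 1.0,
                                   bound: float = 100.0) -> MetadRun:
    """Drive a toy Langevin system with well-tempered metadynamics.

    The CVs are the system coordinates themselves (1-4 dimensions).  Hills
    are deposited every ``params.pace`` ps with heights following the
    well-tempered rescaling; walls act throughout.  The COLVAR record
    stores, every ``colvar_stride`` steps, the time, CV values, the
    instantaneous hills bias and the current offset c(t).  When a grid is
    supplied the grid bias and c(t) are maintained per deposition, and the
    emitted hills replay to a bit-identical grid bias.
    """
    ndim = np.atleast_1d(np.asarray(x0, dtype=float)).size
    if not 1 <= ndim <= 4:
        raise MetadError("the engine supports 1 to 4 CVs")
    if len(params.widths) != ndim:
        raise MetadError("need one hill width per CV")
    if dt * friction >= 0.1:
        raise MetadError("dt * friction must stay below 0.1 for stability")
    pace_steps = max(int(round(params.pace / dt)), 1)
    if grid_edges is None:
        grid_edges = [np.linspace(-2.5, 2.5, 201)] * ndim
    state = BiasState(params, walls, grid_edges=[np.asarray(e) for e in grid_edges])

    rng = np.random.default_rng(seed)
    init_rng, noise_rng = rng.spawn(2)
    kt = KB * params.temperature
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    v = init_rng.normal(0.0, math.sqrt(kt / mass), ndim)
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(kt / mass * (1.0 - c1 * c1))

    lo = np.array([e[0] for e in state.grid_edges])
    hi = np.array([e[-1] for e in state.grid_edges])

    def total_force(pos):
        f = np.atleast_1d(potential.force(pos)).astype(float)
        _, fh = state.hills_value_and_force(pos)
        _, fw = state.walls_value_and_force(pos)
        return f + fh + fw

    f = total_force(x)
    ct_, cx_, cb_, cc_ = [], [], [], []
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f / mass
        x += 0.5 * dt * v
        v = c1 * v + c2 * noise_rng.normal(size=ndim)
        x += 0.5 * dt * v
        f = total_force(x)
        v += 0.5 * dt * f / mass
        if np.any(np.abs(x) > bound):
            raise MetadError(f"trajectory diverged at step {step}")
        t = step * dt
        if step % pace_steps == 0:
            if np.any(x < lo) or np.any(x > hi):
                raise MetadError(
                    "CV excursion beyond the bias grid; move or stiffen the "
                    "walls, or widen the grid")
            h = next_hill_height(state, x)
            state.add_hill(Hill(t, x.copy(), np.asarray(params.widths), h))
            f = total_force(x)
        if step % colvar_stride == 0:
            ct_.append(t)
            cx_.append(x.copy())
            cb_.append(state.hills_value(x))
            cc_.append(state.current_c())
    return MetadRun(state, np.asarray(ct_), np.asarray(cx_),
                    np.asarray(cb_), np.asarray(cc_))
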