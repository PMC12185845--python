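"""Synthetic ground-truth generators for every pipeline stage.

Real microsecond-scale MD of a solvated odorant-binding protein is not
reproducible at desk scale, so each analysis stage is validated against
synthetic inputs with known ground truth instead:

* fluctuation-dissipation-consistent work ensembles (analytic Gaussian
  increments or time-stepped constrained Langevin pulling) with a
  planted potential and friction profile, for the dcTMD estimator;
* five-step binding scenarios emitted both as analytic observable
  traces and as explicit coordinate trajectories (dummy scaffold with
  gate residues, ligand and waters), for the state classifier;
* planted-path contact-fingerprint batches for pathway clustering;
* latent-factor contact-distance traces for the correlation analysis;
* Gaussian pose clouds for DBSCAN;
* alignments with exact column compositions for conservation;
* noisy single-site ITC isotherms.

Every generator returns its planted truth alongside the data, and a
given spec + seed is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import constants
from .conservation import AMINO_ACIDS, Alignment
from .dctmd import WorkEnsemble
from .gate_dynamics import STATES, DistanceTrace, GateParams, StateSequence
from .itc_fit import ITCTitration, simulate_isotherm
from .path_clustering import ContactFeatures
from .pose_clustering import PoseSet
from .residue_mosaic import ContactDistanceSet, ContactRule
from .traj_io import PullRecord, Topology, Trajectory

__all__ = [
    "Potential",
    "HarmonicPotential",
    "GaussianWellsPotential",
    "TablePotential",
    "FrictionProfile",
    "PullSimSpec",
    "gen_work_ensemble",
    "gen_pull_records",
    "BindingScenarioSpec",
    "BindingTraces",
    "gen_binding_traces",
    "gen_binding_trajectory",
    "gen_binding_batch",
    "gen_path_batch",
    "gen_pose_clouds",
    "gen_mosaic_traces",
    "gen_alignment",
    "gen_itc",
]


# ---------------------------------------------------------------------------
# planted potentials and friction fields
# ---------------------------------------------------------------------------

class Potential:
    """Interface: U(x) and U'(x) in kJ/mol over x in angstrom."""

    def value(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    #: narrowest feature length scale, used for the integrator dt check
    min_width: float = 1.0


@dataclass
class HarmonicPotential(Potential):
    k: float = 10.0      # kJ/mol/A^2
    x0: float = 0.0      # A

    def value(self, x):
        return 0.5 * self.k * (np.asarray(x, dtype=float) - self.x0) ** 2

    def gradient(self, x):
        return self.k * (np.asarray(x, dtype=float) - self.x0)

    @property
    def min_width(self) -> float:
        return float(np.sqrt(2.0 / self.k)) if self.k > 0 else 1.0


@dataclass
class GaussianWellsPotential(Potential):
    """Sum of Gaussian wells plus an optional linear ramp.

    ``wells`` is a list of (depth kJ/mol, centre A, width A); depths are
    positive for attractive wells.  The default plants a double-well
    landscape: a deep bound well and a shallower vestibule well whose
    minima differ by roughly the free-energy gap between the bound state
    and the pocket intermediate (~55 kJ/mol).
    """

    wells: list = field(
        default_factory=lambda: [(75.0, 2.0, 1.5), (20.0, 10.0, 1.5)]
    )
    slope: float = 0.0   # kJ/mol/A

    def value(self, x):
        x = np.asarray(x, dtype=float)
        u = self.slope * x
        for depth, centre, width in self.wells:
            u = u - depth * np.exp(-((x - centre) ** 2) / (2.0 * width**2))
        return u

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.full_like(x, self.slope, dtype=float)
        for depth, centre, width in self.wells:
            g = g + depth * (x - centre) / width**2 * np.exp(
                -((x - centre) ** 2) / (2.0 * width**2)
            )
        return g

    @property
    def min_width(self) -> float:
        return min(w for _, _, w in self.wells) if self.wells else 1.0


@dataclass
class TablePotential(Potential):
    """Tabulated potential, interpolated with a cubic spline."""

    xs: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))
    us: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0]))

    def __post_init__(self) -> None:
        from scipy.interpolate import CubicSpline

        self.xs = np.asarray(self.xs, dtype=float)
        self.us = np.asarray(self.us, dtype=float)
        self._spline = CubicSpline(self.xs, self.us)
        self._dspline = self._spline.derivative()

    def value(self, x):
        return self._spline(np.asarray(x, dtype=float))

    def gradient(self, x):
        return self._dspline(np.asarray(x, dtype=float))

    @property
    def min_width(self) -> float:
        return float(np.min(np.diff(self.xs)))


@dataclass
class FrictionProfile:
    """gamma(x) = gamma0 + Gaussian bumps, in kg mol^-1 s^-1.

    The default plants a flat baseline of 2e12 kg/mol/s (the order of
    molar Stokes friction of a small solute in water) with one
    high-friction window centred at 9 A, where the ligand sheds its
    hydration shell.
    """

    gamma0: float = 2.0e12
    bumps: list = field(default_factory=lambda: [(1.8e13, 9.0, 0.75)])

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = np.full_like(x, self.gamma0, dtype=float)
        for height, centre, width in self.bumps:
            g = g + height * np.exp(-((x - centre) ** 2) / (2.0 * width**2))
        if np.any(g < 0):
            raise ValueError("friction profile must be non-negative")
        return g


@dataclass
class PullSimSpec:
    """Constrained-pulling simulation conditions.

    Defaults mirror the unbinding protocol the analysis targets: 200
    replicas pulled at 1 m/s for 2.5 ns (25 A of travel) at 300 K.
    """

    potential: Potential = field(default_factory=GaussianWellsPotential)
    friction: FrictionProfile = field(default_factory=FrictionProfile)
    velocity: float = 1.0         # m/s
    temperature: float = 300.0    # K
    n_replicas: int = 200
    t_total: float = 2500.0       # ps
    dt: float = 0.05              # ps (langevin mode)
    grid_spacing: float = 0.1     # A
    x0: float = 0.0               # A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicas < 2:
            raise ValueError("need at least 2 replicas")
        if min(self.velocity, self.temperature, self.t_total, self.dt) <= 0:
            raise ValueError("velocity, temperature, t_total, dt must be positive")

    @property
    def length(self) -> float:
        """Total pulling distance, A."""
        return self.velocity * constants.M_PER_S_TO_A_PER_PS * self.t_total

    def grid(self) -> np.ndarray:
        return np.arange(
            self.x0, self.x0 + self.length + 0.5 * self.grid_spacing,
            self.grid_spacing,
        )

    def ground_truth(self) -> dict:
        """Planted dG(x) and gamma(x) on the output grid."""
        g = self.grid()
        u = self.potential.value(g)
        return {
            "grid": g,
            "dG": u - u[0],
            "gamma": self.friction(g),
            "gamma0": self.friction.gamma0,
        }

    def check_dt(self) -> None:
        x_step = self.velocity * constants.M_PER_S_TO_A_PER_PS * self.dt
        if x_step > 0.2 * self.potential.min_width:
            raise ValueError(
                f"dt = {self.dt} ps moves the constraint {x_step:.3g} A per "
                f"step, too coarse for the narrowest potential feature "
                f"({self.potential.min_width:.3g} A)"
            )


def _diss_increment_kj(spec: PullSimSpec, x_mid: np.ndarray, dx: float) -> np.ndarray:
    """gamma(x)*v*dx in kJ/mol for dx in angstrom."""
    gamma = spec.friction(x_mid)  # kg/mol/s == J mol^-1 s m^-2
    return gamma * spec.velocity * (dx * constants.METER_PER_ANGSTROM) * 1.0e-3


def gen_work_ensemble(
    spec: PullSimSpec, mode: str = "gaussian_analytic"
) -> tuple[WorkEnsemble, dict]:
    """Generate a replica work ensemble with planted ground truth.

    ``gaussian_analytic`` draws fluctuation-dissipation-consistent work
    increments directly on the output grid: mean dU + gamma*v*dx,
    variance 2*gamma*v*dx*kT.  ``langevin`` integrates the constrained
    coordinate x(t) = x0 + v t with an explicit random force
    (Euler-Maruyama) and accumulates W = int f_c v dt, then resamples
    onto the grid.  Both return (ensemble, ground_truth).
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    kt = constants.kT(spec.temperature)
    truth = spec.ground_truth()

    if mode == "gaussian_analytic":
        dx = np.diff(grid)
        x_mid = 0.5 * (grid[:-1] + grid[1:])
        du = np.diff(spec.potential.value(grid))
        diss = _diss_increment_kj(spec, x_mid, 1.0) * dx  # per-step kJ/mol
        mean_inc = du + diss
        var_inc = 2.0 * diss * kt
        noise = rng.standard_normal((spec.n_replicas, len(dx)))
        incs = mean_inc[None, :] + np.sqrt(var_inc)[None, :] * noise
        works = np.concatenate(
            (np.zeros((spec.n_replicas, 1)), np.cumsum(incs, axis=1)), axis=1
        )
    elif mode == "langevin":
        spec.check_dt()
        v_aps = spec.velocity * constants.M_PER_S_TO_A_PER_PS
        n_steps = int(round(spec.t_total / spec.dt))
        t = np.arange(n_steps + 1) * spec.dt
        x = spec.x0 + v_aps * t
        # deterministic part of the constraint force, kJ/mol/A
        gamma_ps = spec.friction(x) * constants.KG_MOL_S_TO_KJ_MOL_PS_A2
        f_det = spec.potential.gradient(x) + gamma_ps * v_aps
        # random force: <xi xi'> = 2 gamma kT delta(t-t'), discretised
        xi_sd = np.sqrt(2.0 * gamma_ps * kt / spec.dt)  # kJ/mol/A
        works = np.empty((spec.n_replicas, len(grid)))
        w_t = np.empty(n_steps + 1)
        for r in range(spec.n_replicas):
            xi = rng.standard_normal(n_steps + 1) * xi_sd
            f_c = f_det - xi
            w_t[0] = 0.0
            np.cumsum(
                0.5 * (f_c[1:] + f_c[:-1]) * v_aps * spec.dt, out=w_t[1:]
            )
            works[r] = np.interp(grid, x, w_t)
        works -= works[:, :1]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ens = WorkEnsemble(
        grid=grid,
        works=works,
        velocity=spec.velocity,
        temperature=spec.temperature,
    )
    return ens, truth


def gen_pull_records(
    spec: PullSimSpec, sample_every: int = 1
) -> tuple[list[PullRecord], dict]:
    """Constraint-force time series per replica, in native pull units.

    Times in ps, forces in kJ mol^-1 nm^-1, as a pull-code output file
    would contain.  ``sample_every`` thins the time axis.
    """
    spec.check_dt()
    rng = np.random.default_rng(spec.seed)
    v_aps = spec.velocity * constants.M_PER_S_TO_A_PER_PS
    n_steps = int(round(spec.t_total / spec.dt))
    t = np.arange(n_steps + 1) * spec.dt
    x = spec.x0 + v_aps * t
    kt = constants.kT(spec.temperature)
    gamma_ps = spec.friction(x) * constants.KG_MOL_S_TO_KJ_MOL_PS_A2
    f_det = spec.potential.gradient(x) + gamma_ps * v_aps
    xi_sd = np.sqrt(2.0 * gamma_ps * kt / spec.dt)
    records = []
    for _ in range(spec.n_replicas):
        xi = rng.standard_normal(n_steps + 1) * xi_sd
        f_c = (f_det - xi) * constants.ANGSTROM_PER_NM  # kJ/mol/A -> kJ/mol/nm
        records.append(
            PullRecord(
                times=t[::sample_every],
                values=f_c[::sample_every],
                velocity=spec.velocity,
                kind="force",
            )
        )
    return records, spec.ground_truth()


# ---------------------------------------------------------------------------
# five-step binding scenarios
# ---------------------------------------------------------------------------

#: default observable levels per state: (F100 distance A, gate distance A,
#: solvation fraction).  Solvation levels follow the mechanism narrative:
#: ~75% on first contact, a stable 60% in the pocket, strong dehydration on
#: entry and near-complete dehydration in the site.
STATE_LEVELS: dict[str, tuple[float, float, float]] = {
    "unbound": (18.0, 3.0, 1.0),
    "a_contact_closed": (12.0, 3.0, 0.75),
    "b_pocket_closed": (7.5, 3.0, 0.60),
    "c_entry_open": (7.5, 4.3, 0.15),
    "d_site_open": (2.5, 4.3, 0.03),
    "e_site_closed": (2.5, 3.0, 0.03),
}


@dataclass
class BindingScenarioSpec:
    """Schedule of mechanism states with observable levels and noise."""

    schedule: list = field(
        default_factory=lambda: [
            ("unbound", 20.0),
            ("a_contact_closed", 10.0),
            ("b_pocket_closed", 70.0),
            ("c_entry_open", 6.0),
            ("d_site_open", 10.0),
            ("e_site_closed", 30.0),
        ]
    )
    levels: dict = field(default_factory=lambda: dict(STATE_LEVELS))
    distance_noise: float = 0.25   # A
    gate_noise: float = 0.12       # A
    solvation_noise: float = 0.05
    frame_interval: float = 0.2    # ns
    n_waters: int = 40
    bulk_shell: int = 20           # waters in the full hydration shell
    seed: int = 0

    def __post_init__(self) -> None:
        params = GateParams()
        for state, duration in self.schedule:
            if state not in STATES:
                raise ValueError(f"unknown state {state!r} in schedule")
            if duration <= 0:
                raise ValueError("schedule durations must be positive")
            d, g, _ = self.levels[state]
            self._check_level(state, d, g, params)
        if self.bulk_shell > self.n_waters:
            raise ValueError("bulk_shell cannot exceed n_waters")

    @staticmethod
    def _check_level(state: str, d: float, g: float, p: GateParams) -> None:
        gate_closed = g < p.closed_cutoff
        ok = {
            "unbound": d >= p.pocket_cutoff + p.contact_cutoff,
            "a_contact_closed": p.pocket_cutoff <= d < p.pocket_cutoff + p.contact_cutoff,
            "b_pocket_closed": p.bound_cutoff <= d < p.pocket_cutoff and gate_closed,
            "c_entry_open": p.bound_cutoff <= d < p.pocket_cutoff and not gate_closed,
            "d_site_open": d < p.bound_cutoff and not gate_closed,
            "e_site_closed": d < p.bound_cutoff and gate_closed,
        }[state]
        if not ok:
            raise ValueError(
                f"levels for state {state} (d={d}, gate={g}) violate the "
                "gate-parameter ordering"
            )


@dataclass
class BindingTraces:
    """Analytic observable traces realising a scenario schedule."""

    times: np.ndarray           # ns
    distance: np.ndarray        # F100 distance, A
    gate: np.ndarray            # gate distance, A
    solvation: np.ndarray       # fraction
    states: StateSequence       # planted labels


def gen_binding_traces(spec: BindingScenarioSpec) -> BindingTraces:
    """Observable traces (distance/gate/solvation) plus planted labels."""
    rng = np.random.default_rng(spec.seed)
    frames_per_state = [
        max(1, int(round(dur / spec.frame_interval))) for _, dur in spec.schedule
    ]
    n = sum(frames_per_state)
    times = np.arange(n) * spec.frame_interval
    d = np.empty(n)
    g = np.empty(n)
    s = np.empty(n)
    labels = np.empty(n, dtype=object)
    i = 0
    for (state, _), nf in zip(spec.schedule, frames_per_state):
        d0, g0, s0 = spec.levels[state]
        sl = slice(i, i + nf)
        d[sl] = d0 + spec.distance_noise * rng.standard_normal(nf)
        g[sl] = g0 + spec.gate_noise * rng.standard_normal(nf)
        s[sl] = s0 + spec.solvation_noise * rng.standard_normal(nf)
        labels[sl] = state
        i += nf
    np.clip(d, 0.0, None, out=d)
    np.clip(g, 0.0, None, out=g)
    np.clip(s, 0.0, None, out=s)
    return BindingTraces(
        times=times,
        distance=d,
        gate=g,
        solvation=s,
        states=StateSequence(times=times, states=labels.astype(str)),
    )


def _scaffold_topology(n_waters: int) -> Topology:
    """Dummy scaffold: anchor residues, gate residues, F100, ligand, waters.

    The scaffold is sparse on purpose so contact and solvation counts at
    the default cutoffs are unambiguous.
    """
    names, resnames, resseqs, chains, elements = [], [], [], [], []

    def add(name, resname, resseq, element):
        names.append(name)
        resnames.append(resname)
        resseqs.append(resseq)
        chains.append("A")
        elements.append(element)

    # four glycine anchors (superposition frame)
    for i in range(4):
        add("CA", "GLY", i + 1, "C")
    # S34: backbone only; the carbonyl O is the gate acceptor
    for nm, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
        add(nm, "SER", 34, el)
    # Y82: anchor CA plus the hydroxyl donor
    add("CA", "TYR", 82, "C")
    add("OH", "TYR", 82, "O")
    # F100 side chain (the cavity cradle)
    for nm in ("CB", "CG", "CD1", "CD2"):
        add(nm, "PHE", 100, "C")
    # ligand: three heavy atoms
    for nm in ("C1", "C2", "O1"):
        add(nm, "LIG", 201, nm[0])
    # waters: oxygen only
    for i in range(n_waters):
        add("O", "HOH", 300 + i, "O")

    from .traj_io import ELEMENT_MASSES

    resname_arr = np.array(resnames)
    is_water = resname_arr == "HOH"
    is_ligand = resname_arr == "LIG"
    return Topology(
        atom_name=np.array(names),
        residue_name=resname_arr,
        residue_seq=np.array(resseqs, dtype=int),
        chain_id=np.array(chains),
        mass=np.array([ELEMENT_MASSES[e] for e in elements]),
        element=np.array(elements),
        is_water=is_water,
        is_ligand=is_ligand,
    )


def gen_binding_trajectory(
    spec: BindingScenarioSpec,
) -> tuple[Trajectory, StateSequence, BindingTraces]:
    """Explicit-coordinate realisation of a binding scenario.

    Builds a rigid dummy protein (gate donor/acceptor, F100 side chain,
    anchors), a three-atom ligand approaching along +x, and waters whose
    in-shell count realises the scheduled solvation fraction.  Returns
    the trajectory, the planted state labels and the analytic traces the
    geometry was built from.
    """
    traces = gen_binding_traces(spec)
    top = _scaffold_topology(spec.n_waters)
    n_frames = len(traces.times)
    coords = np.zeros((n_frames, top.n_atoms, 3))

    anchors = np.array(
        [[-20.0, 0.0, 0.0], [-20.0, 8.0, 0.0], [-24.0, 0.0, 6.0], [-16.0, 0.0, -6.0]]
    )
    # S34 backbone around its O; the O itself is the gate acceptor origin
    s34_o = np.array([-8.0, 6.0, 0.0])
    s34_frame = np.array(
        [s34_o + [-2.4, 0.0, 0.0], s34_o + [-1.2, 0.9, 0.0], s34_o + [0.0, 1.2, 0.0]]
    )
    y82_ca = s34_o + np.array([0.0, -1.5, 6.0])
    # F100 side-chain atoms centred on the origin (cavity cradle)
    f100 = np.array(
        [[0.0, 0.75, 0.0], [0.0, -0.75, 0.0], [0.65, 0.0, 0.75], [-0.65, 0.0, -0.75]]
    )
    # ligand heavy atoms relative to the ligand COM (masses C, C, O)
    lig_local = np.array([[1.0, 0.0, 0.0], [-1.0, 0.4, 0.0], [0.0, -0.4, 0.8]])
    from .traj_io import ELEMENT_MASSES

    lig_masses = np.array(
        [ELEMENT_MASSES["C"], ELEMENT_MASSES["C"], ELEMENT_MASSES["O"]]
    )
    lig_local = lig_local - (
        (lig_local * lig_masses[:, None]).sum(axis=0) / lig_masses.sum()
    )
    f100_com = f100.mean(axis=0)  # equal carbon masses

    i_anchor = slice(0, 4)
    i_s34 = slice(4, 7)
    i_s34_o = 7
    i_y82_ca = 8
    i_y82_oh = 9
    i_f100 = slice(10, 14)
    i_lig = slice(14, 17)
    i_wat = slice(17, 17 + spec.n_waters)

    # bulk water park: far corner, grid spacing 3 A
    park = np.array([60.0, 60.0, 60.0])
    grid_idx = np.arange(spec.n_waters)
    park_sites = park + 3.0 * np.stack(
        [grid_idx % 5, (grid_idx // 5) % 5, grid_idx // 25], axis=1
    )

    rng = np.random.default_rng(spec.seed + 1)
    # fixed shell directions (unit vectors) to place in-shell waters
    dirs = rng.standard_normal((spec.n_waters, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    for f in range(n_frames):
        coords[f, i_anchor] = anchors
        coords[f, i_s34] = s34_frame
        coords[f, i_s34_o] = s34_o
        coords[f, i_y82_ca] = y82_ca
        # gate distance realised along +z from the S34 carbonyl O
        coords[f, i_y82_oh] = s34_o + np.array([0.0, 0.0, traces.gate[f]])
        coords[f, i_f100] = f100
        lig_com = f100_com + np.array([traces.distance[f], 0.0, 0.0])
        coords[f, i_lig] = lig_com + lig_local
        # waters: first k in the hydration shell, rest parked in bulk
        k = int(np.clip(round(traces.solvation[f] * spec.bulk_shell), 0,
                        spec.n_waters))
        wat = park_sites.copy()
        if k:
            wat[:k] = coords[f, i_lig][0] + 2.9 * dirs[:k]
        coords[f, i_wat] = wat

    box = np.tile([200.0, 200.0, 200.0], (n_frames, 1))
    traj = Trajectory(
        topology=top, coordinates=coords, times=traces.times, box=box
    )
    return traj, traces.states, traces


def gen_binding_batch(
    n_trajectories: int = 15,
    n_binding: int = 10,
    seed: int = 0,
    frame_interval: float = 0.2,
) -> tuple[list[DistanceTrace], int]:
    """Batch of F100-distance traces with a planted number of entries.

    ``n_binding`` trajectories follow the full binding schedule and end
    bound (sustained entries); the rest approach the vestibule but never
    cross the bound cutoff.  Returns the traces and the planted count of
    sustained binding events.
    """
    if n_binding > n_trajectories:
        raise ValueError("n_binding cannot exceed n_trajectories")
    traces = []
    for i in range(n_trajectories):
        if i < n_binding:
            schedule = [
                ("unbound", 15.0),
                ("a_contact_closed", 10.0),
                ("b_pocket_closed", 25.0),
                ("c_entry_open", 5.0),
                ("d_site_open", 10.0),
                ("e_site_closed", 25.0),
            ]
        else:
            schedule = [
                ("unbound", 40.0),
                ("a_contact_closed", 20.0),
                ("b_pocket_closed", 30.0),
            ]
        spec = BindingScenarioSpec(
            schedule=schedule, seed=seed + 1000 * i,
            frame_interval=frame_interval,
        )
        t = gen_binding_traces(spec)
        traces.append(
            DistanceTrace(times=t.times, values=t.distance, definition="com_f100")
        )
    return traces, n_binding


# ---------------------------------------------------------------------------
# planted path batches, pose clouds, correlation systems
# ---------------------------------------------------------------------------

def gen_path_batch(
    n_per_path: tuple = (130, 70),
    fingerprints: list | None = None,
    n_frames: int = 30,
    noise_sd: float = 0.3,
    cap: float = 10.0,
    seed: int = 0,
) -> tuple[list[ContactFeatures], np.ndarray]:
    """Contact-fingerprint batch with planted path labels.

    Each path touches its own residue set: fingerprint residues sit at
    contact distances (~3-4.5 A) with per-frame noise, all other
    residues at the far-field cap.  Returns the batch (on the union
    feature set) and the planted path label per trajectory.
    """
    if fingerprints is None:
        fingerprints = [[40, 41, 56, 57, 82], [20, 21, 100, 101, 120]]
    if len(fingerprints) != len(n_per_path):
        raise ValueError("need one fingerprint per path")
    union = sorted({r for fp in fingerprints for r in fp})
    rng = np.random.default_rng(seed)
    batch: list[ContactFeatures] = []
    labels = []
    idx = 0
    for path, (count, fp) in enumerate(zip(n_per_path, fingerprints)):
        fp_cols = [union.index(r) for r in fp]
        for _ in range(count):
            mat = np.full((n_frames, len(union)), cap)
            base = 3.5 + 0.3 * rng.standard_normal(len(fp_cols))
            drift = np.linspace(0.0, 1.0, n_frames)[:, None]
            mat[:, fp_cols] = (
                base[None, :]
                + drift
                + noise_sd * rng.standard_normal((n_frames, len(fp_cols)))
            )
            np.clip(mat, 0.0, cap, out=mat)
            batch.append(
                ContactFeatures(
                    trajectory_id=f"traj{idx:03d}",
                    matrix=mat,
                    feature_index=list(union),
                )
            )
            labels.append(path)
            idx += 1
    return batch, np.asarray(labels, dtype=int)


def gen_pose_clouds(
    centres: np.ndarray | list,
    n_per_cloud: int | list = 100,
    sigma: float = 0.5,
    n_atoms: int = 4,
    seed: int = 0,
) -> tuple[PoseSet, np.ndarray]:
    """Gaussian clouds of rigid ligand poses around given COM centres.

    Every pose is the same rigid ligand translated to a noisy copy of
    its cloud centre, so the mass-weighted RMSD between two poses equals
    the distance of their translations.  Returns (poses, cloud labels).
    """
    centres = np.atleast_2d(np.asarray(centres, dtype=float))
    if np.isscalar(n_per_cloud) or isinstance(n_per_cloud, int):
        n_per_cloud = [int(n_per_cloud)] * len(centres)
    rng = np.random.default_rng(seed)
    local = rng.standard_normal((n_atoms, 3))
    local -= local.mean(axis=0)
    masses = np.full(n_atoms, 12.011)
    coords, labels = [], []
    for c, (centre, count) in enumerate(zip(centres, n_per_cloud)):
        offsets = centre + sigma * rng.standard_normal((count, 3))
        for off in offsets:
            coords.append(local + off)
            labels.append(c)
    coords = np.asarray(coords)
    poses = PoseSet(
        frames=np.arange(len(coords)), ligand_coords=coords, masses=masses
    )
    return poses, np.asarray(labels, dtype=int)


def gen_mosaic_traces(
    communities: list | None = None,
    n_independent: int = 6,
    n_frames: int = 2000,
    loading: float = 1.0,
    noise_sd: float = 0.5,
    base_distance: float = 3.5,
    seed: int = 0,
) -> tuple[ContactDistanceSet, dict[int, list]]:
    """Contact-distance traces with planted correlated communities.

    Each community is a list of residue pairs driven by one shared
    latent factor (loading ``loading``, residual noise ``noise_sd``);
    ``n_independent`` additional pairs fluctuate independently.  Returns
    the trace set and {community id: pairs} ground truth.
    """
    if communities is None:
        communities = [[(34, 82), (34, 112), (82, 112)]]
    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, int]] = []
    cols: list[np.ndarray] = []
    truth: dict[int, list] = {}
    for c, group in enumerate(communities):
        factor = rng.standard_normal(n_frames)
        truth[c] = list(group)
        for pair in group:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            trace = (
                base_distance
                + sign * loading * factor
                + noise_sd * rng.standard_normal(n_frames)
            )
            pairs.append(tuple(pair))
            cols.append(np.clip(trace, 0.0, None))
    for i in range(n_independent):
        pair = (400 + 3 * i, 402 + 3 * i)
        trace = base_distance + noise_sd * rng.standard_normal(n_frames)
        pairs.append(pair)
        cols.append(np.clip(trace, 0.0, None))
        truth.setdefault(-1, []).append(pair)
    rule = ContactRule(cutoff=base_distance + 1.0, min_contact_fraction=0.01)
    return (
        ContactDistanceSet(pairs=pairs, traces=np.column_stack(cols), rule=rule),
        truth,
    )


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

#: family sizes of the lipocalin alignment the conservation figures use
DEFAULT_FAMILY_SIZES = {"OBP": 105, "VEG": 29, "SAL": 46, "LCN9": 21, "MUP": 47}


def _exact_column(
    n: int, freqs: dict[str, float], filler: str, rng: np.random.Generator
) -> list[str]:
    """Deal residues so realised non-gap frequencies are exact.

    Frequencies are interpreted over the non-gap denominator.  The
    largest multiple of the frequencies' common denominator that fits in
    ``n`` becomes the non-gap count; remaining rows get gaps.  Leftover
    non-gap rows are filled with ``filler``.
    """
    fracs = {
        r: Fraction(f).limit_denominator(10000) for r, f in freqs.items() if f > 0
    }
    if sum(fracs.values()) > 1:
        raise ValueError("column frequencies exceed 1")
    denom = 1
    for fr in fracs.values():
        denom = denom * fr.denominator // np.gcd(denom, fr.denominator)
    k = n // denom
    if k == 0:
        raise ValueError(
            f"cannot realise exact frequencies with denominator {denom} "
            f"in {n} sequences"
        )
    nongap = k * denom
    counts = {r: int(fr * nongap) for r, fr in fracs.items()}
    rest = nongap - sum(counts.values())
    if rest:
        counts[filler] = counts.get(filler, 0) + rest
    column = [r for r, c in counts.items() for _ in range(c)]
    column += ["-"] * (n - nongap)
    rng.shuffle(column)
    return column


def gen_alignment(
    n_per_family: dict[str, int] | None = None,
    length: int = 12,
    column_spec: dict[int, dict[str, float]] | None = None,
    exact: bool = True,
    filler: str = "A",
    consensus: str = "L",
    seed: int = 0,
) -> Alignment:
    """Synthetic lipocalin-family alignment with controlled columns.

    ``column_spec`` maps column index to residue frequencies; in exact
    mode the realised non-gap frequencies match the spec exactly (gap
    rows are added as needed), otherwise residues are drawn at random.
    Unspecified columns hold the consensus residue.  Family labels are
    assigned in blocks following ``n_per_family`` (default: the 248
    lipocalins split 105 OBP / 29 VEG / 46 SAL / 21 LCN9 / 47 MUP).
    """
    if n_per_family is None:
        n_per_family = dict(DEFAULT_FAMILY_SIZES)
    column_spec = column_spec or {}
    n = sum(n_per_family.values())
    if n == 0:
        raise ValueError("need at least one sequence")
    rng = np.random.default_rng(seed)

    columns: list[list[str]] = []
    for col in range(length):
        if col in column_spec:
            freqs = column_spec[col]
            if exact:
                columns.append(_exact_column(n, freqs, filler, rng))
            else:
                residues = list(freqs) + [filler]
                p = np.array(list(freqs.values()) + [0.0])
                p[-1] = max(0.0, 1.0 - p[:-1].sum())
                columns.append(
                    list(rng.choice(residues, size=n, p=p / p.sum()))
                )
        else:
            columns.append([consensus] * n)

    sequences: dict[str, str] = {}
    family_labels: dict[str, str] = {}
    i = 0
    for fam, count in n_per_family.items():
        for j in range(count):
            sid = f"{fam}_{j:03d}"
            sequences[sid] = "".join(columns[c][i] for c in range(length))
            family_labels[sid] = fam
            i += 1
    return Alignment(sequences=sequences, family_labels=family_labels)


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

def gen_itc(
    n: float = 1.0,
    Kd: float = 1.0e-6,
    dH: float = -5.0,
    noise_sd: float = 0.0,
    titr: ITCTitration | None = None,
    n_injections: int = 25,
    seed: int = 0,
) -> tuple[ITCTitration, dict]:
    """Noisy single-site isotherm under the default titration conditions.

    ``noise_sd`` is the absolute Gaussian noise on each injection heat
    (ucal).  Returns the titration and the planted (n, Kd, dH).
    """
    if titr is None:
        titr = ITCTitration(heats=np.zeros(n_injections))
    heats = simulate_isotherm(n, Kd, dH, titr)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + noise_sd * rng.standard_normal(len(heats))
    out = ITCTitration(
        heats=heats,
        injection_volumes=titr.injection_volumes,
        cell_volume=titr.cell_volume,
        cell_conc=titr.cell_conc,
        syringe_conc=titr.syringe_conc,
        temperature=titr.temperature,
    )
    return out, {"n": n, "Kd": Kd, "dH": dH}
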