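"""Binding observables of the gated lipocalin calyx.

The ligand's approach to the binding cavity is monitored through three
per-frame observables:

* the distance between the ligand centre of mass and the centre of mass
  of the F100 side chain, which forms the cradle of the cavity (the
  ligand counts as *bound* below 5 A);
* the Y82(OH)-S34(backbone O) hydrogen-bond distance, the "gate", which
  is *closed* below 3.4 A;
* the ligand solvation fraction, the number of water oxygens within a
  shell of the ligand heavy atoms normalised to the bulk-water value.

These three series jointly define a five-step binding sequence:
contact-closed (a), pocket-closed (b), entry-open (c), binding
site-open (d) and binding site-closed (e).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from typing import Sequence

import numpy as np
from scipy import ndimage

from .traj_io import Trajectory

__all__ = [
    "GateParams",
    "DistanceTrace",
    "SolvationTrace",
    "StateSequence",
    "BindingEvent",
    "STATES",
    "superpose_frames",
    "com_distance_trace",
    "gate_distance_trace",
    "classify_gate",
    "solvation_trace",
    "detect_binding_events",
    "assign_states",
]

logger = logging.getLogger(__name__)

#: state labels of the five-step mechanism, in mechanistic order
STATES = (
    "unbound",
    "a_contact_closed",
    "b_pocket_closed",
    "c_entry_open",
    "d_site_open",
    "e_site_closed",
)
_STATE_TO_CODE = {s: i for i, s in enumerate(STATES)}


@dataclass(frozen=True)
class GateParams:
    """Geometric thresholds of the binding-state classification (angstrom).

    ``closed_cutoff`` is the gate hydrogen-bond threshold, ``bound_cutoff``
    the ligand-in-cavity threshold on the F100 distance, ``pocket_cutoff``
    the outer edge of the vestibule (taken from the free-energy minimum of
    the unbinding profile), and ``contact_cutoff`` the width of the
    first-contact band beyond it.
    """

    closed_cutoff: float = 3.4
    bound_cutoff: float = 5.0
    pocket_cutoff: float = 10.0
    contact_cutoff: float = 4.5
    solvation_radius: float = 3.5
    min_dwell_frames: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.closed_cutoff < self.bound_cutoff < self.pocket_cutoff):
            raise ValueError(
                "require 0 < closed_cutoff < bound_cutoff < pocket_cutoff"
            )
        if self.contact_cutoff <= 0 or self.solvation_radius <= 0:
            raise ValueError("cutoffs must be positive")
        if self.min_dwell_frames < 1:
            raise ValueError("min_dwell_frames must be >= 1")


@dataclass
class DistanceTrace:
    """A per-frame distance observable (angstrom)."""

    times: np.ndarray
    values: np.ndarray
    definition: str = "custom"  # com_f100 | gate_y82_s34 | custom

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("distances must be finite and non-negative")


@dataclass
class SolvationTrace:
    """Normalised ligand-solvation fraction per frame."""

    times: np.ndarray
    fraction: np.ndarray
    bulk_reference: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if len(self.times) != len(self.fraction):
            raise ValueError("times and fraction differ in length")
        if self.bulk_reference <= 0:
            raise ValueError("bulk_reference must be positive")
        if np.any(self.fraction < 0):
            raise ValueError("fractions must be non-negative")


@dataclass
class StateSequence:
    """Per-frame label of the five-step binding mechanism."""

    times: np.ndarray
    states: np.ndarray  # array of str labels from STATES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states)
        if len(self.times) != len(self.states):
            raise ValueError("times and states differ in length")
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")


@dataclass(frozen=True)
class BindingEvent:
    """One ligand entry into the cavity."""

    entry_time: float          # ns
    replica_id: str = ""
    ligand_id: str = ""
    sustained: bool = False


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, ref: np.ndarray, weights: np.ndarray):
    """Optimal (weighted least-squares) rotation + translation mobile -> ref."""
    w = weights[:, None] / weights.sum()
    mc = (mobile * w).sum(axis=0)
    rc = (ref * w).sum(axis=0)
    a = mobile - mc
    b = ref - rc
    h = (a * w).T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    dmat = np.diag([1.0, 1.0, d])
    rot = vt.T @ dmat @ u.T
    return rot, mc, rc


def superpose_frames(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: Sequence[int] | np.ndarray | None = None,
) -> Trajectory:
    """Least-squares superpose every frame onto a reference frame.

    The optimal rotation (Kabsch) is computed on the mass-weighted
    ``selection`` atoms and applied to all atoms of the frame, so ligand
    positions become comparable across frames.
    """
    if selection is None:
        selection = np.flatnonzero(traj.topology.is_protein & traj.topology.is_heavy)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("superposition selection is empty")
    ref = traj.coordinates[reference_frame][selection]
    # degenerate-geometry guard: need 3+ non-collinear points
    if selection.size < 3 or np.linalg.matrix_rank(ref - ref.mean(axis=0)) < 2:
        raise ValueError(
            "superposition needs at least 3 non-collinear selection atoms"
        )
    weights = traj.topology.mass[selection]
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        rot, mc, rc = _kabsch(traj.coordinates[f][selection], ref, weights)
        out[f] = (traj.coordinates[f] - mc) @ rot.T + rc
    return Trajectory(
        topology=traj.topology, coordinates=out, times=traj.times, box=traj.box
    )


def _minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        delta = delta - box * np.round(delta / box)
    return delta


def _com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def com_distance_trace(
    traj: Trajectory,
    group_a: Sequence[int] | np.ndarray,
    group_b: Sequence[int] | np.ndarray,
    definition: str = "custom",
) -> DistanceTrace:
    """Per-frame distance between the mass-weighted centroids of two groups.

    Uses the minimum-image convention under the per-frame box when a box
    is present, plain Euclidean distance otherwise.
    """
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("both atom groups must be non-empty")
    ma = traj.topology.mass[ga]
    mb = traj.topology.mass[gb]
    if traj.box is None:
        logger.warning("no box information; using plain Euclidean distances")
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        ca = _com(traj.coordinates[f][ga], ma)
        cb = _com(traj.coordinates[f][gb], mb)
        d = _minimum_image(ca - cb, None if traj.box is None else traj.box[f])
        vals[f] = np.linalg.norm(d)
    return DistanceTrace(times=traj.times, values=vals, definition=definition)


def gate_distance_trace(
    traj: Trajectory,
    tyr_residue: int = 82,
    ser_residue: int = 34,
) -> DistanceTrace:
    """Y82(OH)-S34(backbone carbonyl O) distance per frame (angstrom)."""
    top = traj.topology
    oh = top.select(residue_seq=tyr_residue, atom_names=["OH"])
    o = top.select(residue_seq=ser_residue, atom_names=["O"])
    if oh.size != 1 or o.size != 1:
        candidates_oh = np.char.strip(
            top.atom_name[top.residue_seq == tyr_residue].astype(str)
        )
        candidates_o = np.char.strip(
            top.atom_name[top.residue_seq == ser_residue].astype(str)
        )
        raise ValueError(
            f"cannot resolve gate atoms: residue {tyr_residue} needs one OH "
            f"(found atoms {sorted(set(candidates_oh))}), residue "
            f"{ser_residue} needs one O (found {sorted(set(candidates_o))})"
        )
    trace = com_distance_trace(traj, oh, o, definition="gate_y82_s34")
    return trace


def classify_gate(trace: DistanceTrace, params: GateParams = GateParams()) -> np.ndarray:
    """Boolean per-frame series: gate closed iff distance < closed_cutoff.

    The inequality is strict, so a distance exactly at the cutoff counts
    as open.
    """
    if trace.definition != "gate_y82_s34":
        raise ValueError(
            f"classify_gate expects a gate_y82_s34 trace, got {trace.definition!r}"
        )
    return trace.values < params.closed_cutoff


def solvation_trace(
    traj: Trajectory,
    ligand: Sequence[int] | np.ndarray | None = None,
    params: GateParams = GateParams(),
    bulk_reference: float | str = "auto",
) -> SolvationTrace:
    """Normalised ligand solvation per frame.

    Counts water oxygens within ``params.solvation_radius`` of any ligand
    heavy atom, divided by ``bulk_reference`` (the mean count for the
    fully solvated ligand).  ``bulk_reference="auto"`` estimates the
    reference from frames where the ligand COM is more than
    ``pocket_cutoff + 5`` A away from every protein atom.
    """
    top = traj.topology
    if ligand is None:
        ligand = top.select(ligand=True, heavy_only=True)
    ligand = np.asarray(ligand, dtype=int)
    ligand = ligand[top.is_heavy[ligand]]
    if ligand.size == 0:
        raise ValueError("ligand heavy-atom selection is empty")
    wat_o = np.flatnonzero(top.is_water & (top.element == "O"))
    if wat_o.size == 0:
        raise ValueError("no water oxygens in topology")

    counts = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        lig = traj.coordinates[f][ligand]
        wat = traj.coordinates[f][wat_o]
        box = None if traj.box is None else traj.box[f]
        delta = _minimum_image(wat[:, None, :] - lig[None, :, :], box)
        dmin = np.sqrt((delta**2).sum(axis=2)).min(axis=1)
        counts[f] = int(np.sum(dmin < params.solvation_radius))

    if bulk_reference == "auto":
        prot = np.flatnonzero(top.is_protein)
        lig_m = top.mass[ligand]
        far = np.zeros(traj.n_frames, dtype=bool)
        threshold = params.pocket_cutoff + 5.0
        for f in range(traj.n_frames):
            com = _com(traj.coordinates[f][ligand], lig_m)
            box = None if traj.box is None else traj.box[f]
            delta = _minimum_image(traj.coordinates[f][prot] - com, box)
            far[f] = np.sqrt((delta**2).sum(axis=1)).min() > threshold
        if not far.any():
            raise ValueError(
                "auto bulk reference: no frames with the ligand in bulk "
                f"(> {threshold:.1f} A from protein); pass an explicit "
                "bulk_reference"
            )
        ref = float(counts[far].mean())
        if ref <= 0:
            raise ValueError(
                "auto bulk reference is zero; pass an explicit bulk_reference"
            )
    else:
        ref = float(bulk_reference)
        if ref <= 0:
            raise ValueError("bulk_reference must be positive")
    return SolvationTrace(times=traj.times, fraction=counts / ref, bulk_reference=ref)


# ---------------------------------------------------------------------------
# events and states
# ---------------------------------------------------------------------------

def detect_binding_events(
    dist: DistanceTrace,
    params: GateParams = GateParams(),
    replica_id: str = "",
    ligand_id: str = "",
) -> list[BindingEvent]:
    """Detect ligand entries into the cavity from the F100 distance trace.

    An event starts at the first frame of every run of at least
    ``min_dwell_frames`` consecutive frames below ``bound_cutoff``.  The
    event is flagged *sustained* when the run reaches the end of the
    trajectory or lasts at least ten dwell windows.
    """
    if dist.definition != "com_f100":
        raise ValueError(
            f"detect_binding_events expects a com_f100 trace, got "
            f"{dist.definition!r}"
        )
    below = dist.values < params.bound_cutoff
    events: list[BindingEvent] = []
    n = len(below)
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            run = j - i
            if run >= params.min_dwell_frames:
                sustained = (j == n) or (run >= 10 * params.min_dwell_frames)
                events.append(
                    BindingEvent(
                        entry_time=float(dist.times[i]),
                        replica_id=replica_id,
                        ligand_id=ligand_id,
                        sustained=sustained,
                    )
                )
            i = j
        else:
            i += 1
    return events


def assign_states(
    dist: DistanceTrace,
    gate_closed: np.ndarray,
    solv: SolvationTrace | None = None,
    params: GateParams = GateParams(),
) -> StateSequence:
    """Assign each frame to one of the five mechanism steps (or unbound).

    The raw per-frame rule combines the F100 distance band with the gate
    state; a median filter of width ``min_dwell_frames`` (on the ordinal
    state code) suppresses single-frame flicker.  The solvation trace is
    accepted for interface completeness and length validation; the state
    boundaries themselves are purely geometric.
    """
    d = dist.values
    n = len(d)
    gate_closed = np.asarray(gate_closed, dtype=bool)
    if len(gate_closed) != n:
        raise ValueError("distance trace and gate series differ in length")
    if solv is not None and len(solv.fraction) != n:
        raise ValueError("distance trace and solvation trace differ in length")

    codes = np.empty(n, dtype=int)
    in_site = d < params.bound_cutoff
    in_pocket = (~in_site) & (d < params.pocket_cutoff)
    in_contact = (~in_site) & (~in_pocket) & (
        d < params.pocket_cutoff + params.contact_cutoff
    )
    codes[:] = _STATE_TO_CODE["unbound"]
    codes[in_contact] = _STATE_TO_CODE["a_contact_closed"]
    codes[in_pocket & gate_closed] = _STATE_TO_CODE["b_pocket_closed"]
    codes[in_pocket & ~gate_closed] = _STATE_TO_CODE["c_entry_open"]
    codes[in_site & ~gate_closed] = _STATE_TO_CODE["d_site_open"]
    codes[in_site & gate_closed] = _STATE_TO_CODE["e_site_closed"]

    if params.min_dwell_frames > 1 and n > params.min_dwell_frames:
        codes = ndimage.median_filter(
            codes, size=params.min_dwell_frames, mode="nearest"
        )
    labels = np.array(STATES, dtype=object)[codes]
    return StateSequence(times=dist.times, states=labels.astype(str))
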