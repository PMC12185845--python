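"""Transient-pocket identification by DBSCAN over ligand poses.

Ligand poses (in the superposed protein frame) are clustered with DBSCAN
under a mass-weighted RMSD metric, with the defaults used for transient
pockets: eps = 5 A and min_samples = 50 (a cluster must persist for
~10 ns at a 0.2 ns frame interval).

DBSCAN is implemented directly on the precomputed pose-distance matrix
so the border-point tie-break is fully deterministic: a border point in
reach of several clusters is attached to its lowest-indexed core
neighbour.  Standard library implementations leave this choice to scan
order, which would make cluster membership depend on data ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PoseSet",
    "ClusterAssignment",
    "mass_weighted_rmsd",
    "pairwise_rmsd_matrix",
    "dbscan_poses",
    "dbscan_precomputed",
    "pocket_residue_report",
]

# Kyte-Doolittle hydropathy index per residue
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}


@dataclass
class PoseSet:
    """Ligand heavy-atom coordinates per frame, in a common protein frame."""

    frames: np.ndarray          # (P,) frame indices
    ligand_coords: np.ndarray   # (P, A, 3) angstrom
    masses: np.ndarray          # (A,) Da

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.ligand_coords = np.asarray(self.ligand_coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        p, a, three = self.ligand_coords.shape
        if three != 3 or len(self.frames) != p or len(self.masses) != a:
            raise ValueError("inconsistent PoseSet shapes")
        if not np.all(np.isfinite(self.ligand_coords)):
            raise ValueError("pose coordinates must be finite")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_poses(self) -> int:
        return self.ligand_coords.shape[0]


@dataclass
class ClusterAssignment:
    """DBSCAN result: labels with -1 for noise, cluster ids contiguous from 0."""

    labels: np.ndarray
    n_clusters: int
    eps: float
    min_samples: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and self.labels.min() < -1:
            raise ValueError("labels must be >= -1")
        ids = sorted(set(self.labels[self.labels >= 0]))
        if ids != list(range(len(ids))):
            raise ValueError("cluster ids must be contiguous from 0")
        if self.n_clusters != len(ids):
            raise ValueError("n_clusters disagrees with labels")


def mass_weighted_rmsd(a: np.ndarray, b: np.ndarray, masses: np.ndarray) -> float:
    """sqrt( sum_i m_i ||a_i - b_i||^2 / sum_i m_i ), no refitting.

    Both poses must already live in a common reference frame.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"pose shapes differ: {a.shape} vs {b.shape}")
    if len(masses) != a.shape[0]:
        raise ValueError("mass array does not match atom count")
    sq = ((a - b) ** 2).sum(axis=1)
    return float(np.sqrt((masses * sq).sum() / masses.sum()))


def pairwise_rmsd_matrix(poses: PoseSet) -> np.ndarray:
    """Full symmetric matrix of pairwise mass-weighted RMSDs."""
    x = poses.ligand_coords
    w = poses.masses / poses.masses.sum()
    # ||a-b||_w^2 = sum_atoms w * |a-b|^2, vectorised over pose pairs
    p = poses.n_poses
    out = np.zeros((p, p))
    for i in range(p):
        diff = x[i + 1:] - x[i]
        sq = (diff**2).sum(axis=2) @ w
        out[i, i + 1:] = out[i + 1:, i] = np.sqrt(sq)
    return out


def dbscan_precomputed(
    dist: np.ndarray, eps: float, min_samples: int
) -> ClusterAssignment:
    """DBSCAN on a precomputed distance matrix with deterministic semantics.

    Core point: at least ``min_samples`` neighbours within ``eps``
    (including itself).  Clusters are the connected components of core
    points under eps-reachability; border points join the lowest-indexed
    core neighbour's cluster; everything else is noise (-1).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    within = dist <= eps
    n_neighbors = within.sum(axis=1)  # includes self (diagonal is 0)
    core = n_neighbors >= min_samples

    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for seed in range(n):
        if not core[seed] or labels[seed] != -1:
            continue
        # BFS over eps-connected core points
        stack = [seed]
        labels[seed] = cluster
        while stack:
            p = stack.pop()
            for q in np.flatnonzero(within[p] & core):
                if labels[q] == -1:
                    labels[q] = cluster
                    stack.append(q)
        cluster += 1
    # border points: lowest-indexed core neighbour wins
    for p in range(n):
        if labels[p] != -1 or core[p]:
            continue
        core_nbrs = np.flatnonzero(within[p] & core)
        if core_nbrs.size:
            labels[p] = labels[core_nbrs[0]]
    return ClusterAssignment(
        labels=labels, n_clusters=cluster, eps=eps, min_samples=min_samples
    )


def dbscan_poses(
    poses: PoseSet, eps: float = 5.0, min_samples: int = 50
) -> ClusterAssignment:
    """Cluster ligand poses with DBSCAN under mass-weighted RMSD."""
    if poses.n_poses < 1:
        raise ValueError("need at least one pose")
    dist = pairwise_rmsd_matrix(poses)
    return dbscan_precomputed(dist, eps=eps, min_samples=min_samples)


def pocket_residue_report(
    poses: PoseSet,
    assignment: ClusterAssignment,
    traj,
    contact_cutoff: float = 4.5,
) -> list[dict]:
    """Describe each pose cluster by its contacting protein residues.

    For every cluster, protein residues with any heavy atom within
    ``contact_cutoff`` of the cluster centroid (mean ligand-atom
    position over member poses) are listed with a Kyte-Doolittle
    hydropathy tag, supporting the hydrophilic/hydrophobic pocket
    distinction near the gate.
    """
    top = traj.topology
    prot_heavy = np.flatnonzero(top.is_protein & top.is_heavy)
    ref_coords = traj.coordinates[0]
    reports = []
    for c in range(assignment.n_clusters):
        members = assignment.labels == c
        centroid = poses.ligand_coords[members].mean(axis=(0, 1))
        d = np.linalg.norm(ref_coords[prot_heavy] - centroid, axis=1)
        near = prot_heavy[d < contact_cutoff]
        residues = sorted(
            {(int(top.residue_seq[i]), str(top.residue_name[i])) for i in near}
        )
        entries = []
        for seq, name in residues:
            kd = KYTE_DOOLITTLE.get(name.upper())
            tag = None if kd is None else ("hydrophobic" if kd > 0 else "hydrophilic")
            entries.append(
                {"residue_seq": seq, "residue_name": name,
                 "kyte_doolittle": kd, "character": tag}
            )
        reports.append(
            {"cluster": c, "n_poses": int(members.sum()), "residues": entries}
        )
    return reports
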