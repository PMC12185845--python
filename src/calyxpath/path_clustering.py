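"""Unbinding-path separation by contact PCA + Leiden/CPM clustering.

Each pulled trajectory is fingerprinted by its protein-ligand contact
distances, all trajectories are projected into a common principal
component space (first four components), pairwise trajectory
similarities s_ij are computed, and communities (pathways) are found by
Leiden optimisation of the constant Potts model (CPM) at a resolution
gamma = median(s_ij).

The CPM objective over a similarity matrix s is

    Q = sum_c [ e_c - gamma * n_c (n_c - 1) / 2 ],

with e_c the sum of intra-community off-diagonal similarities (each
unordered pair counted once) and n_c the community size.  Free-energy
profiles are then estimated on the work curves of the largest community
only, so that a single pathway's energetics is not averaged with
alternative routes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .dctmd import WorkEnsemble
from .traj_io import Trajectory

__all__ = [
    "ContactFeatures",
    "SimilarityMatrix",
    "CommunityPartition",
    "contact_features",
    "contact_features_batch",
    "pca_project",
    "trajectory_similarity",
    "cpm_quality",
    "leiden_cpm",
    "largest_cluster_works",
]

logger = logging.getLogger(__name__)


@dataclass
class ContactFeatures:
    """Per-frame minimal residue-ligand heavy-atom distances (angstrom)."""

    trajectory_id: str
    matrix: np.ndarray          # (frames, features)
    feature_index: list[int]    # residue_seq per feature column
    cutoff: float = 4.5

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.feature_index):
            raise ValueError("matrix width does not match feature index")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class SimilarityMatrix:
    """Symmetric trajectory-pairwise similarity in [0, 1], unit diagonal."""

    ids: list[str]
    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        n = len(self.ids)
        if self.s.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(self.s, self.s.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.s), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if self.s.min() < -1e-12 or self.s.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")

    def median_offdiag(self) -> float:
        iu = np.triu_indices(len(self.ids), k=1)
        return float(np.median(self.s[iu]))


@dataclass
class CommunityPartition:
    """Leiden/CPM community assignment over trajectories (or features)."""

    ids: list[str]
    labels: np.ndarray
    gamma: float
    quality: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.ids):
            raise ValueError("labels length mismatch")
        found = sorted(set(self.labels))
        if found != list(range(len(found))):
            raise ValueError("community labels must be contiguous from 0")

    @property
    def n_communities(self) -> int:
        return len(set(self.labels))

    def community_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)


# ---------------------------------------------------------------------------
# featurization and projection
# ---------------------------------------------------------------------------

def _min_residue_ligand_distances(
    traj: Trajectory, ligand: np.ndarray
) -> tuple[np.ndarray, list[int]]:
    """(frames, residues) matrix of minimal heavy-atom distances."""
    top = traj.topology
    residues = top.protein_residues()
    groups = [
        top.select(residue_seq=seq, heavy_only=True)
        for _, seq in residues
    ]
    groups = [
        g[top.is_protein[g]] for g in groups
    ]
    mat = np.empty((traj.n_frames, len(groups)))
    lig_coords = traj.coordinates[:, ligand, :]
    for j, g in enumerate(groups):
        res_coords = traj.coordinates[:, g, :]
        # (F, |g|, |lig|)
        d = np.linalg.norm(
            res_coords[:, :, None, :] - lig_coords[:, None, :, :], axis=3
        )
        mat[:, j] = d.min(axis=(1, 2))
    return mat, [seq for _, seq in residues]


def contact_features(
    traj: Trajectory,
    ligand: Sequence[int] | np.ndarray | None = None,
    cutoff: float = 4.5,
    cap: float = 10.0,
    trajectory_id: str = "traj",
) -> ContactFeatures:
    """Protein-ligand contact fingerprint of a single trajectory.

    Features are protein residues whose minimal heavy-atom distance to
    the ligand falls below ``cutoff`` in at least one frame; entries are
    per-frame minimal distances capped at ``cap`` so far-field frames do
    not dominate the PCA.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = traj.topology
    if ligand is None:
        ligand = top.select(ligand=True, heavy_only=True)
    ligand = np.asarray(ligand, dtype=int)
    if ligand.size == 0:
        raise ValueError("ligand heavy-atom selection is empty")
    mat, residues = _min_residue_ligand_distances(traj, ligand)
    touched = (mat < cutoff).any(axis=0)
    if not touched.any():
        raise ValueError("ligand never contacts the protein below the cutoff")
    return ContactFeatures(
        trajectory_id=trajectory_id,
        matrix=np.minimum(mat[:, touched], cap),
        feature_index=[r for r, t in zip(residues, touched) if t],
        cutoff=cutoff,
    )


def contact_features_batch(
    features: list[ContactFeatures], cap: float = 10.0
) -> list[ContactFeatures]:
    """Re-index a batch of fingerprints onto the union feature set.

    Missing residues are filled with the cap distance (no contact).
    """
    union = sorted({r for f in features for r in f.feature_index})
    out = []
    for f in features:
        col = {r: j for j, r in enumerate(f.feature_index)}
        mat = np.full((f.matrix.shape[0], len(union)), cap)
        for j, r in enumerate(union):
            if r in col:
                mat[:, j] = np.minimum(f.matrix[:, col[r]], cap)
        out.append(
            ContactFeatures(
                trajectory_id=f.trajectory_id,
                matrix=mat,
                feature_index=list(union),
                cutoff=f.cutoff,
            )
        )
    return out


def pca_project(
    batch: list[ContactFeatures], n_components: int = 4
) -> tuple[list[np.ndarray], np.ndarray]:
    """Fit PCA on all frames of all trajectories; project each trajectory.

    Data are mean-centred but not variance-scaled (all features share
    angstrom units).  Returns per-trajectory projections and the
    explained-variance ratios.
    """
    if len(batch) < 2:
        raise ValueError("need at least two trajectories")
    index0 = batch[0].feature_index
    if any(f.feature_index != index0 for f in batch):
        raise ValueError(
            "feature indices differ across trajectories; run "
            "contact_features_batch first"
        )
    stacked = np.vstack([f.matrix for f in batch])
    max_rank = min(stacked.shape)
    if n_components > max_rank:
        logger.warning(
            "reducing n_components from %d to %d (rank limit)",
            n_components, max_rank,
        )
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(stacked)
    projections = [pca.transform(f.matrix) for f in batch]
    return projections, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def trajectory_similarity(
    projections: list[np.ndarray],
    ids: list[str] | None = None,
    radius_quantile: float = 0.5,
) -> SimilarityMatrix:
    """Pairwise trajectory similarity in PC space.

    d_ij is the mean, over frames of trajectory i, of the Euclidean
    distance to the nearest frame of trajectory j; the symmetrised
    distance D_ij = max(d_ij, d_ji) is mapped to a similarity
    s_ij = exp(-D_ij / sigma) with sigma the ``radius_quantile`` quantile
    of the off-diagonal D.
    """
    from scipy.spatial.distance import cdist

    n = len(projections)
    if n < 2:
        raise ValueError("need at least two trajectories")
    if any(p.shape[0] == 0 for p in projections):
        raise ValueError("every trajectory needs at least one frame")
    if ids is None:
        ids = [str(i) for i in range(n)]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = cdist(projections[i], projections[j])
            d[i, j] = dist.min(axis=1).mean()
            d[j, i] = dist.min(axis=0).mean()
    big = np.maximum(d, d.T)
    iu = np.triu_indices(n, k=1)
    sigma = float(np.quantile(big[iu], radius_quantile))
    if sigma <= 0:
        # all trajectories identical up to the quantile; similarity is 1
        s = np.ones((n, n))
    else:
        s = np.exp(-big / sigma)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(ids=list(ids), s=s)


# ---------------------------------------------------------------------------
# Leiden / CPM
# ---------------------------------------------------------------------------

def cpm_quality(s: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Constant Potts model objective for a partition of a similarity matrix."""
    labels = np.asarray(labels)
    q = 0.0
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        n_c = len(members)
        sub = s[np.ix_(members, members)]
        e_c = (sub.sum() - np.trace(sub)) / 2.0
        q += e_c - gamma * n_c * (n_c - 1) / 2.0
    return float(q)


def leiden_cpm(
    sim: SimilarityMatrix,
    gamma: float | str = "median",
    seed: int = 0,
    n_restarts: int = 50,
    n_iterations: int = -1,
) -> CommunityPartition:
    """Leiden community detection under the constant Potts model.

    ``gamma="median"`` resolves the resolution parameter to the median
    off-diagonal similarity.  The optimisation is restarted
    ``n_restarts`` times from seeds derived deterministically from
    ``seed`` and the best-quality partition is kept, which makes the
    result reproducible and, on small problems, reliably optimal.
    """
    import igraph as ig
    import leidenalg

    if gamma == "median":
        gamma = sim.median_offdiag()
    gamma = float(gamma)
    if gamma < 0:
        raise ValueError("resolution gamma must be non-negative")

    n = len(sim.ids)
    iu = np.triu_indices(n, k=1)
    weights = sim.s[iu]
    edges = list(zip(iu[0].tolist(), iu[1].tolist()))
    # drop zero-weight edges; they carry no quality contribution
    keep = weights > 0
    g = ig.Graph(n=n, edges=[e for e, k in zip(edges, keep) if k])
    w = weights[keep].tolist()

    best_labels = None
    best_q = -np.inf
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    for s_i in sub_seeds:
        part = leidenalg.find_partition(
            g,
            leidenalg.CPMVertexPartition,
            weights=w,
            resolution_parameter=gamma,
            seed=int(s_i),
            n_iterations=n_iterations,
        )
        labels = np.asarray(part.membership)
        q = cpm_quality(sim.s, labels, gamma)
        if q > best_q + 1e-12:
            best_q = q
            best_labels = labels

    # relabel communities by first appearance for determinism
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(best_labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return CommunityPartition(
        ids=list(sim.ids), labels=out, gamma=gamma, quality=best_q
    )


def largest_cluster_works(
    partition: CommunityPartition, ens: WorkEnsemble
) -> WorkEnsemble:
    """Sub-ensemble of the largest community (ties -> lowest community id)."""
    sizes = partition.community_sizes()
    winner = int(np.argmax(sizes))  # argmax returns the first maximum
    if (sizes == sizes[winner]).sum() > 1:
        logger.info(
            "community-size tie (%d trajectories); keeping community %d",
            sizes[winner], winner,
        )
    ids = [
        i for i, lab in zip(partition.ids, partition.labels) if lab == winner
    ]
    keep = [i for i in ids if i in set(ens.replica_ids)]
    if not keep:
        raise ValueError("no overlap between partition ids and ensemble replicas")
    return ens.subset(keep)
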