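"""Correlation analysis of internal protein dynamics (MoSAIC-style).

Collectively moving residue groups are found from the correlation
structure of residue-pair contact distances:

1. candidate features are non-adjacent residue pairs whose minimal
   heavy-atom distance stays below a 4.5 A cutoff in a minimum fraction
   of frames;
2. the Pearson correlation between all retained distance traces is
   computed;
3. the |rho| matrix is clustered with the same Leiden/CPM engine used
   for pathway separation, at resolution gamma = 0.2.

Absolute correlation is used as the similarity so that anti-correlated
but mechanically coupled pairs cluster together.  A residue-level
summary lists, per community, the union of residues its pairs touch —
this is the view in which the gate, its adjacent helix and T112 appear
as one co-moving community.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
from itertools import combinations

import numpy as np

from .path_clustering import CommunityPartition, SimilarityMatrix, leiden_cpm
from .traj_io import Trajectory

__all__ = [
    "ContactRule",
    "ContactDistanceSet",
    "CorrelationMatrix",
    "contact_distance_traces",
    "correlation_matrix",
    "cluster_correlations",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactRule:
    """Inclusion rule for residue-pair contact features."""

    cutoff: float = 4.5               # A
    min_contact_fraction: float = 0.3
    min_sequence_separation: int = 2  # exclude |i-j| < 2 (covalent neighbours)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.min_contact_fraction <= 1:
            raise ValueError("min_contact_fraction must lie in (0, 1]")


@dataclass
class ContactDistanceSet:
    """Retained residue pairs and their per-frame minimal distances."""

    pairs: list[tuple[int, int]]   # author residue numbering
    traces: np.ndarray             # (frames, n_pairs) angstrom
    rule: ContactRule

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape[1] != len(self.pairs):
            raise ValueError("traces width does not match pair count")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces must be finite")


@dataclass
class CorrelationMatrix:
    """Pearson correlation between contact-distance traces."""

    pairs: list[tuple[int, int]]
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = len(self.pairs)
        if self.rho.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.rho, self.rho.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(self.rho) > 1 + 1e-10):
            raise ValueError("|rho| must not exceed 1")


def contact_distance_traces(
    traj: Trajectory, rule: ContactRule = ContactRule()
) -> ContactDistanceSet:
    """Minimal heavy-atom distance traces of persistently contacting pairs.

    Candidate pairs are protein residue pairs at sequence separation
    >= 2; a pair is kept when its distance is below ``rule.cutoff`` in
    at least ``rule.min_contact_fraction`` of the frames.
    """
    top = traj.topology
    residues = top.protein_residues()
    if len(residues) < 2:
        raise ValueError("need at least two protein residues")
    groups = {
        seq: top.select(residue_seq=seq, heavy_only=True)
        for _, seq in residues
    }
    seqs = [seq for _, seq in residues]
    kept_pairs: list[tuple[int, int]] = []
    kept_traces: list[np.ndarray] = []
    for a, b in combinations(seqs, 2):
        if abs(a - b) < rule.min_sequence_separation:
            continue
        ca = traj.coordinates[:, groups[a], :]
        cb = traj.coordinates[:, groups[b], :]
        d = np.linalg.norm(ca[:, :, None, :] - cb[:, None, :, :], axis=3)
        trace = d.min(axis=(1, 2))
        if np.mean(trace < rule.cutoff) >= rule.min_contact_fraction:
            kept_pairs.append((a, b))
            kept_traces.append(trace)
    if not kept_pairs:
        raise ValueError(
            "no residue pair satisfies the contact rule; consider lowering "
            "min_contact_fraction"
        )
    return ContactDistanceSet(
        pairs=kept_pairs, traces=np.column_stack(kept_traces), rule=rule
    )


def correlation_matrix(cds: ContactDistanceSet) -> CorrelationMatrix:
    """Pearson correlation between all retained distance traces.

    Constant traces carry no correlation information and are dropped
    with a warning.
    """
    if cds.traces.shape[0] < 2:
        raise ValueError("need at least two frames")
    variances = cds.traces.var(axis=0)
    keep = variances > 0
    if not keep.all():
        dropped = [p for p, k in zip(cds.pairs, keep) if not k]
        logger.warning("dropping %d constant traces: %s", len(dropped), dropped)
    if keep.sum() < 2:
        raise ValueError("fewer than two non-constant traces")
    pairs = [p for p, k in zip(cds.pairs, keep) if k]
    rho = np.corrcoef(cds.traces[:, keep], rowvar=False)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(pairs=pairs, rho=rho)


def cluster_correlations(
    corr: CorrelationMatrix,
    gamma: float = 0.2,
    seed: int = 0,
) -> tuple[CommunityPartition, dict[int, list[int]]]:
    """Leiden/CPM clustering of the |rho| matrix at resolution gamma.

    Returns the pair-level partition and a residue-level summary mapping
    each community id to the sorted union of residues its pairs touch.
    """
    ids = [f"{a}-{b}" for a, b in corr.pairs]
    s = np.abs(corr.rho).copy()
    np.fill_diagonal(s, 1.0)
    sim = SimilarityMatrix(ids=ids, s=s)
    partition = leiden_cpm(sim, gamma=gamma, seed=seed)
    summary: dict[int, list[int]] = {}
    for (a, b), lab in zip(corr.pairs, partition.labels):
        summary.setdefault(int(lab), set()).update((a, b))  # type: ignore[union-attr]
    return partition, {k: sorted(v) for k, v in sorted(summary.items())}
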