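"""Dissipation-corrected targeted MD (dcTMD) post-processing.

In a constant-velocity constraint-pulling experiment the work done on
the system along the pulling coordinate x contains a reversible and a
dissipative part.  Assuming Gaussian work fluctuations (second-order
cumulant expansion of the Jarzynski average) over an ensemble of
replicas,

    W_diss(x) = (beta/2) * Var[W(x)],
    dG(x)     = <W(x)> - W_diss(x),

and, within Langevin dynamics along x, the dissipated work grows with
the local friction:  Gamma(x) = (1/v) * dW_diss/dx.

The estimator therefore needs only the work curves of the replica
ensemble; the derivative is taken after Gaussian smoothing of W_diss
because the pointwise variance of a finite ensemble is noisy.

The cumulant truncation is only valid for near-Gaussian work
distributions; :func:`normality_diagnostic` flags grid regions where
the skewness leaves the trustworthy regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from . import constants
from .traj_io import PullRecord

__all__ = [
    "WorkEnsemble",
    "FreeEnergyProfile",
    "NormalityDiagnostic",
    "work_from_force",
    "build_ensemble",
    "estimate_profile",
    "normality_diagnostic",
    "jarzynski_profile",
]


@dataclass
class WorkEnsemble:
    """Replica work curves W(x) on a common position grid.

    ``grid`` in angstrom (strictly increasing, starts at the constraint
    origin), ``works`` in kJ/mol with W(grid[0]) = 0 for every replica.
    """

    grid: np.ndarray            # (G,) A
    works: np.ndarray           # (R, G) kJ/mol
    velocity: float             # m/s
    temperature: float          # K
    replica_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.works = np.atleast_2d(np.asarray(self.works, dtype=float))
        if self.works.shape[1] != len(self.grid):
            raise ValueError("works and grid disagree on length")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if not np.allclose(self.works[:, 0], 0.0, atol=1e-9):
            raise ValueError("every work curve must start at zero")
        if self.velocity <= 0:
            raise ValueError("pulling velocity must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.replica_ids is None:
            self.replica_ids = [str(i) for i in range(self.n_replicas)]
        elif len(self.replica_ids) != self.n_replicas:
            raise ValueError("replica_ids length mismatch")

    @property
    def n_replicas(self) -> int:
        return self.works.shape[0]

    def subset(self, ids: list[str]) -> "WorkEnsemble":
        index = {r: i for i, r in enumerate(self.replica_ids)}
        missing = [r for r in ids if r not in index]
        if missing:
            raise KeyError(f"replica ids not in ensemble: {missing[:5]}")
        rows = [index[r] for r in ids]
        return WorkEnsemble(
            grid=self.grid,
            works=self.works[rows],
            velocity=self.velocity,
            temperature=self.temperature,
            replica_ids=list(ids),
        )


@dataclass
class FreeEnergyProfile:
    """dcTMD output fields along the pulling coordinate.

    ``friction`` is in kg mol^-1 s^-1; ``friction_kj`` is the same field
    in kJ mol^-1 s m^-2 (divide by 1000).  The identity
    dG = w_mean - w_diss holds pointwise by construction.
    """

    grid: np.ndarray            # A
    dG: np.ndarray              # kJ/mol, dG[0] = 0
    w_mean: np.ndarray          # kJ/mol
    w_diss: np.ndarray          # kJ/mol (smoothed)
    friction: np.ndarray        # kg mol^-1 s^-1
    smoothing_sigma: float      # A

    @property
    def friction_kj(self) -> np.ndarray:
        """Friction in kJ mol^-1 s m^-2."""
        return self.friction / constants.KJ_MOL_S_M2_TO_KG_MOL_S


@dataclass
class NormalityDiagnostic:
    """Per-grid-point Gaussianity check of the work distribution."""

    grid: np.ndarray
    skewness: np.ndarray
    excess_kurtosis: np.ndarray
    skew_ci_low: np.ndarray
    skew_ci_high: np.ndarray
    flagged: np.ndarray         # bool: |skew| beyond threshold
    threshold: float


def work_from_force(
    record: PullRecord,
    grid: np.ndarray | None = None,
    grid_spacing: float = 0.1,
    x0: float = 0.0,
    rtol_uniform: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a constraint-force record to a work curve W(x).

    The constrained coordinate moves as x(t) = x0 + v*t, so
    W(x) = integral of f_c dx, evaluated with the trapezoidal rule and
    linearly resampled onto a uniform grid (angstrom).  Returns
    ``(grid, work)`` with work in kJ/mol.

    The record's native units (ps, kJ mol^-1 nm^-1) are converted here.
    """
    if record.kind != "force":
        raise ValueError("work_from_force requires a force record")
    t = record.times  # ps
    if len(t) < 2:
        raise ValueError("need at least two samples")
    dts = np.diff(t)
    if np.max(np.abs(dts - dts[0])) > rtol_uniform * dts[0]:
        raise ValueError(
            "non-uniform time sampling in pull record; refusing to resample "
            "forces implicitly"
        )
    v_aps = record.velocity * constants.M_PER_S_TO_A_PER_PS
    x = x0 + v_aps * (t - t[0])                       # A
    force_kj_per_a = record.values * constants.NM_PER_ANGSTROM  # kJ/mol/A
    w = np.concatenate(
        ([0.0], np.cumsum(0.5 * (force_kj_per_a[1:] + force_kj_per_a[:-1]) * np.diff(x)))
    )
    if grid is None:
        grid = np.arange(x[0], x[-1] + 0.5 * grid_spacing, grid_spacing)
    grid = np.asarray(grid, dtype=float)
    w_grid = np.interp(grid, x, w)
    w_grid = w_grid - w_grid[0]
    return grid, w_grid


def build_ensemble(
    records: list[PullRecord],
    temperature: float,
    grid_spacing: float = 0.1,
    replica_ids: list[str] | None = None,
) -> WorkEnsemble:
    """Integrate many force records onto a shared grid."""
    if not records:
        raise ValueError("no pull records given")
    v = records[0].velocity
    if any(r.velocity != v for r in records):
        raise ValueError("all records must share the pulling velocity")
    grid, w0 = work_from_force(records[0], grid_spacing=grid_spacing)
    works = np.empty((len(records), len(grid)))
    works[0] = w0
    for i, rec in enumerate(records[1:], start=1):
        _, works[i] = work_from_force(rec, grid=grid)
    return WorkEnsemble(
        grid=grid, works=works, velocity=v, temperature=temperature,
        replica_ids=replica_ids,
    )


def estimate_profile(
    ens: WorkEnsemble, smoothing_sigma: float = 0.5
) -> FreeEnergyProfile:
    """Second-order cumulant dcTMD estimate of dG(x) and Gamma(x).

    ``smoothing_sigma`` (angstrom) is the width of the Gaussian kernel
    applied to W_diss before the central-difference derivative that
    yields the friction.
    """
    if ens.n_replicas < 2:
        raise ValueError("need at least 2 replicas for variance estimates")
    beta = 1.0 / constants.kT(ens.temperature)
    w_mean = ens.works.mean(axis=0)
    w_var = ens.works.var(axis=0, ddof=1)
    w_diss_raw = 0.5 * beta * w_var

    dx = float(np.mean(np.diff(ens.grid)))
    if smoothing_sigma > 0:
        w_diss = ndimage.gaussian_filter1d(
            w_diss_raw, sigma=smoothing_sigma / dx, mode="nearest"
        )
    else:
        w_diss = w_diss_raw

    dG = w_mean - w_diss
    dG = dG - dG[0]
    # friction: Gamma = (1/v) dW_diss/dx ; convert kJ/mol/A -> kJ mol^-1 s m^-2
    dwdx = np.gradient(w_diss, ens.grid)  # kJ/mol/A
    gamma_kj = dwdx * constants.ANGSTROM_PER_METER / ens.velocity
    friction = gamma_kj * constants.KJ_MOL_S_M2_TO_KG_MOL_S
    return FreeEnergyProfile(
        grid=ens.grid.copy(),
        dG=dG,
        w_mean=w_mean - ens.works.mean(axis=0)[0],
        w_diss=w_diss - w_diss[0],
        friction=friction,
        smoothing_sigma=smoothing_sigma,
    )


def jarzynski_profile(ens: WorkEnsemble) -> np.ndarray:
    """Direct exponential-average (Jarzynski) free-energy estimate.

    Provided as an independent cross-check of the cumulant estimator;
    its sampling error is much larger for strongly dissipative pulls.
    """
    beta = 1.0 / constants.kT(ens.temperature)
    # log-sum-exp for numerical stability
    a = -beta * ens.works
    amax = a.max(axis=0)
    lse = amax + np.log(np.exp(a - amax).mean(axis=0))
    dg = -lse / beta
    return dg - dg[0]


def normality_diagnostic(
    ens: WorkEnsemble,
    skew_threshold: float = 1.0,
    n_boot: int = 200,
    seed: int = 0,
) -> NormalityDiagnostic:
    """Per-x skewness/kurtosis of the work distribution with bootstrap CIs.

    Grid points where |skewness| exceeds ``skew_threshold`` are flagged:
    the second-cumulant free-energy estimate is unreliable there.
    """
    if ens.n_replicas < 8:
        raise ValueError("need at least 8 replicas for a normality diagnostic")
    w = ens.works
    # columns with zero variance (e.g. the origin) have undefined moments;
    # they are treated as Gaussian
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.nan_to_num(stats.skew(w, axis=0, bias=False))
        kurt = np.nan_to_num(stats.kurtosis(w, axis=0, bias=False))
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, w.shape[1]))
    for b in range(n_boot):
        sample = w[rng.integers(0, ens.n_replicas, ens.n_replicas)]
        with np.errstate(invalid="ignore", divide="ignore"):
            boots[b] = np.nan_to_num(stats.skew(sample, axis=0, bias=False))
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return NormalityDiagnostic(
        grid=ens.grid.copy(),
        skewness=skew,
        excess_kurtosis=kurt,
        skew_ci_low=lo,
        skew_ci_high=hi,
        flagged=np.abs(skew) > skew_threshold,
        threshold=skew_threshold,
    )
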