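"""Single-site ITC isotherm simulation and fitting.

An isothermal titration calorimetry experiment injects ligand aliquots
into a protein cell and records the heat of each injection.  For a
single set of identical sites with stoichiometry n, dissociation
constant Kd and molar enthalpy dH, the bound-ligand concentration after
injection i follows the mass-action quadratic

    B = ( n*M + X + Kd - sqrt((n*M + X + Kd)^2 - 4*n*M*X) ) / 2,

with M and X the current (dilution-corrected) total protein and ligand
concentrations in the cell.  The perfusion-displacement convention of
volumetric instruments is used: each injection of volume dV displaces
cell liquid, diluting existing contents by (1 - dV/V0).

The derived thermodynamic quantities are dG = RT ln Kd and
TdS = dH - dG (kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .constants import CAL_TO_J, R_KJ_MOL_K

__all__ = ["ITCTitration", "BindingFit", "simulate_isotherm", "fit_single_site",
           "read_itc_csv", "write_itc_csv"]

#: gas constant, kcal mol^-1 K^-1
R_KCAL = R_KJ_MOL_K / CAL_TO_J


@dataclass
class ITCTitration:
    """One titration: cell/syringe concentrations and injection heats.

    Defaults mirror a typical VP-ITC odorant-binding experiment: 25 uM
    protein in a 1.4 mL cell titrated with 25 x 10 uL injections of a
    250 uM ligand solution at 25 C.
    """

    heats: np.ndarray                      # ucal per injection
    injection_volumes: np.ndarray | None = None  # L per injection
    cell_volume: float = 1.4e-3            # L
    cell_conc: float = 25e-6               # M protein
    syringe_conc: float = 250e-6           # M ligand
    temperature: float = 298.15            # K

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.injection_volumes is None:
            self.injection_volumes = np.full(len(self.heats), 10e-6)
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if len(self.injection_volumes) != len(self.heats):
            raise ValueError("injection_volumes and heats differ in length")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("injection volumes must be positive")
        if min(self.cell_volume, self.cell_conc, self.syringe_conc) <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if not np.all(np.isfinite(self.heats)):
            raise ValueError("heats must be finite")

    @property
    def n_injections(self) -> int:
        return len(self.heats)


@dataclass
class BindingFit:
    """Fitted single-site parameters with derived thermodynamics."""

    n: float                 # stoichiometry
    Kd: float                # M
    dH: float                # kcal/mol
    temperature: float       # K
    residual_norm: float
    std_errors: dict = field(default_factory=dict)
    no_binding: bool = False
    c_value: float = float("nan")
    c_warning: str | None = None

    @property
    def dG(self) -> float:
        """RT ln Kd, kcal/mol (negative for sub-molar Kd)."""
        return R_KCAL * self.temperature * np.log(self.Kd)

    @property
    def TdS(self) -> float:
        return self.dH - self.dG

    @property
    def Ka(self) -> float:
        return 1.0 / self.Kd


def _cell_totals(titr: ITCTitration) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total protein and ligand concentration after each injection.

    Returns (M_t, X_t, dilution factors), each shape (n_injections,).
    """
    v0 = titr.cell_volume
    n_inj = titr.n_injections
    m = np.empty(n_inj)
    x = np.empty(n_inj)
    f = 1.0 - titr.injection_volumes / v0
    m_cur = titr.cell_conc
    x_cur = 0.0
    for i in range(n_inj):
        m_cur = m_cur * f[i]
        x_cur = x_cur * f[i] + titr.syringe_conc * titr.injection_volumes[i] / v0
        m[i] = m_cur
        x[i] = x_cur
    return m, x, f


def _bound_concentration(n: float, kd: float, m: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Bound-ligand concentration from the single-site quadratic."""
    b_tot = n * m + x + kd
    disc = b_tot**2 - 4.0 * n * m * x
    if np.any(disc < -1e-30):
        raise AssertionError("negative discriminant in single-site quadratic")
    return 0.5 * (b_tot - np.sqrt(np.maximum(disc, 0.0)))


def simulate_isotherm(
    n: float, Kd: float, dH: float, titr: ITCTitration
) -> np.ndarray:
    """Per-injection heats (ucal) of the single-site model.

    ``dH`` is in kcal/mol.  The heat of injection i is the enthalpy of
    newly formed complex, accounting for the complex carried out of the
    cell by displacement:  q_i = dH * V0 * (B_i - B_{i-1} * (1 - dV/V0)).
    """
    if n <= 0 or Kd <= 0:
        raise ValueError("n and Kd must be positive")
    m, x, f = _cell_totals(titr)
    b = _bound_concentration(n, Kd, m, x)
    b_prev = np.concatenate(([0.0], b[:-1]))
    delta_moles = titr.cell_volume * (b - b_prev * f)
    return dH * delta_moles * 1.0e9  # kcal -> ucal


def _auto_guess(titr: ITCTitration) -> tuple[float, float, float]:
    """Initial (n, Kd, dH) from isotherm shape.

    dH from the first-injection heat per mole injected; n from the molar
    ratio at the steepest heat change (inflection); Kd from the cell
    protein concentration (c ~ 10 starting regime).
    """
    m, x, _ = _cell_totals(titr)
    ratio = x / m
    moles_per_inj = titr.syringe_conc * titr.injection_volumes
    dh = titr.heats[0] / (moles_per_inj[0] * 1.0e9)
    if not np.isfinite(dh) or dh == 0:
        dh = -1.0
    if titr.n_injections >= 3:
        slopes = np.abs(np.diff(titr.heats))
        n_guess = float(np.clip(ratio[np.argmax(slopes)], 0.2, 5.0))
    else:
        n_guess = 1.0
    kd_guess = titr.cell_conc / 10.0
    return n_guess, kd_guess, float(dh)


def fit_single_site(
    titr: ITCTitration,
    initial_guess: tuple[float, float, float] | None = None,
    noise_floor: float | None = None,
) -> BindingFit:
    """Nonlinear least-squares fit of the single-site model.

    Parameters are optimised in (n, log10 Kd, dH) space.  Standard
    errors come from the Jacobian at the optimum.  When the fitted
    enthalpy signal is smaller than three times the residual noise, the
    titration is flagged as showing no detectable binding (the fitted Kd
    is then meaningless).  A c-value outside [1, 1000] raises a warning
    string on the fit (shape too shallow or too steep to constrain Kd).
    """
    if titr.n_injections < 5:
        raise ValueError("need at least 5 injections to fit")
    if initial_guess is None:
        initial_guess = _auto_guess(titr)
    n0, kd0, dh0 = initial_guess

    def residuals(theta: np.ndarray) -> np.ndarray:
        n, log_kd, dh = theta
        return simulate_isotherm(n, 10.0**log_kd, dh, titr) - titr.heats

    result = least_squares(
        residuals,
        x0=[n0, np.log10(kd0), dh0],
        bounds=([1e-3, -12.0, -1e4], [1e2, 0.0, 1e4]),
        method="trf",
        max_nfev=5000,
    )
    if not result.success:
        raise RuntimeError(
            f"single-site fit did not converge: {result.message}; "
            f"last iterate n={result.x[0]:.3g}, "
            f"Kd={10**result.x[1]:.3g}, dH={result.x[2]:.3g}"
        )
    n_fit, log_kd_fit, dh_fit = result.x
    kd_fit = 10.0**log_kd_fit

    dof = max(titr.n_injections - 3, 1)
    res_var = 2.0 * result.cost / dof
    jtj = result.jac.T @ result.jac
    try:
        cov = np.linalg.inv(jtj) * res_var
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        std_errors = {
            "n": float(se[0]),
            "Kd": float(se[1] * kd_fit * np.log(10.0)),  # delta method
            "dH": float(se[2]),
        }
    except np.linalg.LinAlgError:
        std_errors = {}

    noise = float(np.sqrt(res_var)) if noise_floor is None else noise_floor
    # signal scale: heat per mole of a full first injection
    signal = abs(dh_fit) * titr.syringe_conc * titr.injection_volumes[0] * 1.0e9
    no_binding = signal < 3.0 * noise

    c = n_fit * titr.cell_conc / kd_fit
    if c < 1.0:
        c_warning = f"c = {c:.3g} < 1: isotherm too shallow for a reliable Kd"
    elif c > 1000.0:
        c_warning = f"c = {c:.3g} > 1000: isotherm too steep for a reliable Kd"
    else:
        c_warning = None
    return BindingFit(
        n=float(n_fit),
        Kd=float(kd_fit),
        dH=float(dh_fit),
        temperature=titr.temperature,
        residual_norm=float(np.sqrt(2.0 * result.cost)),
        std_errors=std_errors,
        no_binding=bool(no_binding),
        c_value=float(c),
        c_warning=c_warning,
    )


def read_itc_csv(
    path: str | Path,
    cell_conc: float = 25e-6,
    syringe_conc: float = 250e-6,
    cell_volume: float = 1.4e-3,
    temperature: float = 298.15,
) -> ITCTitration:
    """Read an injection table CSV (injection_index, volume_uL, heat_ucal)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"volume_uL", "heat_ucal"}
    if not required.issubset(df.columns):
        raise ValueError(f"ITC CSV must contain columns {sorted(required)}")
    return ITCTitration(
        heats=df["heat_ucal"].to_numpy(dtype=float),
        injection_volumes=df["volume_uL"].to_numpy(dtype=float) * 1e-6,
        cell_volume=cell_volume,
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        temperature=temperature,
    )


def write_itc_csv(titr: ITCTitration, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "injection_index": np.arange(1, titr.n_injections + 1),
            "volume_uL": titr.injection_volumes * 1e6,
            "heat_ucal": titr.heats,
        }
    ).to_csv(path, index=False)
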