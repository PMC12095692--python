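"""Membrane permeability from PMF profiles, with PAMPA calibration.

The effective permeability of a solute crossing a bilayer is computed with
the inhomogeneous solubility-diffusion model: the membrane resistance is
the integral of the local partition/diffusion resistance along the
membrane normal z,

    1 / P_eff = integral_{z1}^{z2} exp(dG(z) / k_B T) / D(z) dz

with dG(z) the potential of mean force referenced to the water phase
(kcal/mol), D(z) the local diffusivity (cm^2/s, constant by default), and
z in cm.  Computed log10(P_eff/P_0) values (P_0 = 1 cm/s) are mapped onto
the PAMPA scale by an ordinary-least-squares calibration against reference
compounds, and the calibrated permeability is classified into the
high / medium / low-to-medium / low bands used for the lead compounds.

A constant-D approximation biases the raw resistance integral; the
calibration regression absorbs that bias, which is why calibrated values
are the reported ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PMFProfile",
    "CalibrationModel",
    "PermeabilityResult",
    "LEAD_COMPOUND_CALIBRATION",
    "KB_KCAL_PER_MOL_K",
    "peff_from_pmf",
    "fit_calibration",
    "apply_calibration",
    "classify_permeability",
]

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_PER_MOL_K = 0.0019872041
CM_PER_ANGSTROM = 1e-8

#: Published (log10 P_eff/PMF, log10 P_eff/PAMPA) pairs for the NHR2 lead
#: compounds (M23 and M27 also in their protonated _H forms).  These printed
#: values double as the shipped default calibration set.
LEAD_COMPOUND_CALIBRATION: dict[str, tuple[float, float]] = {
    "M23": (0.56, -5.16),
    "M23_H": (-4.22, -6.45),
    "M27": (0.75, -5.10),
    "M27_H": (-2.95, -6.10),
    "M10": (0.83, -5.08),
}

#: Permeability class boundaries in cm/s.
HIGH_THRESHOLD = 4.7e-6
LOW_TO_MEDIUM_RANGE = (7e-7, 2.1e-6)


@dataclass
class PMFProfile:
    """Potential of mean force along the membrane normal.

    ``z`` in Angstrom (strictly increasing, spanning the bilayer), ``dG``
    in kcal/mol referenced to the water phase (the profile must return to
    ~0 at both ends), ``temperature`` in K.
    """

    z: np.ndarray
    dG: np.ndarray
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.dG = np.asarray(self.dG, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.dG.shape:
            raise ValueError("z and dG must be 1-D arrays of equal length")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")
        if not np.all(np.isfinite(self.dG)):
            raise ValueError("non-finite free energies")
        if max(abs(self.dG[0]), abs(self.dG[-1])) > 0.5:
            raise ValueError(
                "profile is not referenced to the water phase: "
                "dG at the ends must be ~0 kcal/mol"
            )
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @classmethod
    def from_csv(cls, path, temperature: float = 300.0) -> "PMFProfile":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["z_angstrom"].to_numpy(), df["dG_kcal_mol"].to_numpy(),
                   temperature=temperature)

    def membrane_bounds(self, threshold: float = 0.1) -> tuple[float, float]:
        """Default integration bounds: z-range where |dG| exceeds threshold."""
        mask = np.abs(self.dG) > threshold
        if not np.any(mask):
            raise ValueError(
                "no membrane region detected (|dG| never exceeds "
                f"{threshold} kcal/mol); pass bounds explicitly"
            )
        idx = np.flatnonzero(mask)
        return float(self.z[idx[0]]), float(self.z[idx[-1]])


@dataclass
class CalibrationModel:
    """OLS map from computed log10(P_eff/P_0) to the PAMPA scale."""

    slope: float
    intercept: float
    n_ref: int
    residual_sd: float
    p0: float = 1.0  # cm/s

    def predict(self, log_peff_pmf: float | np.ndarray) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(log_peff_pmf)


@dataclass
class PermeabilityResult:
    log_peff_pmf: float
    log_peff_pampa: float
    peff: float          # cm/s
    permeability_class: str
    se_log_pampa: float | None = None


def peff_from_pmf(profile: PMFProfile,
                  diffusivity: float | np.ndarray = 1e-5,
                  bounds: tuple[float, float] | None = None) -> float:
    """log10(P_eff / 1 cm/s) from the solubility-diffusion resistance integral.

    ``diffusivity`` is either a constant (cm^2/s) or a per-grid-point
    profile aligned with ``profile.z``.  ``bounds`` defaults to the z-range
    where |dG| > 0.1 kcal/mol.  Trapezoidal quadrature; z is converted from
    Angstrom to cm inside the integral.
    """
    D = np.asarray(diffusivity, dtype=float)
    if np.any(D <= 0):
        raise ValueError("diffusivity must be positive")
    if D.ndim not in (0, 1):
        raise ValueError("diffusivity must be a scalar or a 1-D profile")
    if D.ndim == 1 and D.shape != profile.z.shape:
        raise ValueError("diffusivity profile must align with the PMF grid")
    if bounds is None:
        bounds = profile.membrane_bounds()
    z_lo, z_hi = (float(b) for b in bounds)
    if z_lo >= z_hi:
        raise ValueError("bounds must satisfy z_lo < z_hi")
    if z_lo < profile.z[0] - 1e-9 or z_hi > profile.z[-1] + 1e-9:
        raise ValueError("PMF profile is narrower than the requested bounds")
    mask = (profile.z >= z_lo - 1e-12) & (profile.z <= z_hi + 1e-12)
    z_cm = profile.z[mask] * CM_PER_ANGSTROM
    kt = KB_KCAL_PER_MOL_K * profile.temperature
    integrand = np.exp(profile.dG[mask] / kt)
    integrand = integrand / (D if D.ndim == 0 else D[mask])
    resistance = float(np.trapezoid(integrand, z_cm))  # s/cm
    return float(np.log10(1.0 / resistance))


def fit_calibration(pairs: Sequence[tuple[float, float]]) -> CalibrationModel:
    """OLS of log10(P_eff/PAMPA) on log10(P_eff/PMF) over reference pairs."""
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 calibration pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) < 1e-12:
        raise ValueError("calibration x values are degenerate (all equal)")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    ddof = max(len(pairs) - 2, 1)
    return CalibrationModel(slope=float(res.slope), intercept=float(res.intercept),
                            n_ref=len(pairs),
                            residual_sd=float(np.sqrt(np.sum(resid ** 2) / ddof)))


def apply_calibration(model: CalibrationModel, log_peff_pmf: float,
                      se_log_pmf: float | None = None) -> PermeabilityResult:
    """Map a computed log-permeability to the PAMPA scale and classify it.

    An optional input uncertainty on log10(P_eff/PMF) is propagated through
    the linear map (|slope| * se).
    """
    log_pampa = float(model.predict(log_peff_pmf))
    peff = model.p0 * 10.0 ** log_pampa
    se = None if se_log_pmf is None else abs(model.slope) * float(se_log_pmf)
    return PermeabilityResult(
        log_peff_pmf=float(log_peff_pmf),
        log_peff_pampa=log_pampa,
        peff=float(peff),
        permeability_class=classify_permeability(peff),
        se_log_pampa=se,
    )


def classify_permeability(peff: float) -> str:
    """Band a permeability (cm/s): high / medium_high_gap / low_to_medium / low."""
    if peff <= 0:
        raise ValueError("peff must be positive")
    lo, hi = LOW_TO_MEDIUM_RANGE
    if peff > HIGH_THRESHOLD:
        return "high"
    if peff > hi:
        return "medium_high_gap"
    if peff >= lo:
        return "low_to_medium"
    return "low"
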