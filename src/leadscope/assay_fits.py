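"""Curve fitting for the biophysical readouts of the inhibitor workflow.

One fitter per assay:

- ``fit_ic50``        : four-parameter logistic (4PL) dose-response on
                        log10 concentration -> IC50 with standard error.
- ``fit_mst_kd``      : exact quadratic 1:1 binding isotherm for microscale
                        thermophoresis titrations at known labeled-target
                        concentration -> apparent K_D.
- ``compute_tm``      : nanoDSF melting temperature from the F350/F330
                        fluorescence ratio, first-derivative extremum.
- ``delta_tm``        : signed thermal shift between two melts.
- ``std_epitope_map`` : per-proton saturation-transfer-difference effects,
                        normalized to a reference proton.
- ``fit_pka``         : Henderson-Hasselbalch fit of chemical shift vs pH.

All nonlinear fits use least squares (``scipy.optimize.curve_fit``) with
data-driven initialization; standard errors come from the Jacobian-based
covariance at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

__all__ = [
    "TitrationSeries",
    "DoseResponseFit",
    "BindingFit",
    "ThermalFit",
    "STDRecord",
    "PkaFit",
    "FitError",
    "NoTransitionError",
    "normalize_to_vehicle",
    "fit_ic50",
    "classify_activity",
    "bound_fraction",
    "fit_mst_kd",
    "compute_tm",
    "delta_tm",
    "std_epitope_map",
    "fit_pka",
    "protonated_fraction",
]

LN10 = np.log(10.0)


class FitError(RuntimeError):
    """A nonlinear fit failed to converge or the data carry no signal."""


class NoTransitionError(FitError):
    """A melting curve shows no detectable unfolding transition."""


@dataclass
class TitrationSeries:
    """Common container for titration-style data.

    ``x`` is the abscissa (concentration in uM, temperature in C, or pH)
    and ``y`` a ``(n_points, n_replicates)`` response matrix.  Rows are
    sorted by ``x`` on construction.
    """

    x: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim == 1:
            self.y = self.y[:, None]
        if self.x.ndim != 1 or self.y.shape[0] != self.x.shape[0]:
            raise ValueError("x and y row counts differ")
        if self.y.shape[1] < 1:
            raise ValueError("need at least one replicate")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite values in titration data")
        order = np.argsort(self.x)
        self.x, self.y = self.x[order], self.y[order]
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x values must be distinct")

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "TitrationSeries":
        """Read columns ``x, y_rep1..y_repN`` from a CSV file."""
        df = pd.read_csv(path)
        ycols = [c for c in df.columns if c != df.columns[0]]
        return cls(df.iloc[:, 0].to_numpy(), df[ycols].to_numpy(),
                   meta=meta or {})

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicates flattened to paired (x, y) observations."""
        reps = self.y.shape[1]
        return np.repeat(self.x, reps), self.y.ravel()


def normalize_to_vehicle(x: Sequence[float], raw: np.ndarray,
                         vehicle: Sequence[float],
                         meta: dict | None = None) -> TitrationSeries:
    """Divide raw responses by the vehicle-control mean (vehicle maps to 1)."""
    vehicle_mean = float(np.mean(vehicle))
    if vehicle_mean <= 0:
        raise ValueError("vehicle control mean must be positive")
    meta = dict(meta or {})
    meta.setdefault("normalization", "vehicle")
    meta["vehicle_mean"] = vehicle_mean
    return TitrationSeries(np.asarray(x, float),
                           np.asarray(raw, float) / vehicle_mean, meta)


# ---------------------------------------------------------------------------
# dose-response (4PL)
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    ic50: float           # uM
    hill: float
    top: float
    bottom: float
    se_ic50: float        # uM
    extrapolated: bool
    rss: float


def four_pl(x: np.ndarray, log_ic50: float, hill: float,
            top: float, bottom: float) -> np.ndarray:
    """4PL response: bottom + (top-bottom) / (1 + (x/ic50)^hill)."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.log10(x) - log_ic50)))


def fit_ic50(series: TitrationSeries) -> DoseResponseFit:
    """Fit a sigmoid dose-response curve; concentrations in uM, x > 0.

    Raises :class:`FitError` when the data show no dose dependence or the
    fit does not converge.  IC50s outside the tested concentration range
    are flagged ``extrapolated``.
    """
    if len(series.x) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    if np.any(series.x <= 0):
        raise ValueError("concentrations must be positive")
    x, y = series.flat()
    if np.ptp(y) < 1e-9 * max(1.0, abs(np.mean(y))):
        raise FitError("no dose dependence in the response")
    top0, bottom0 = float(np.max(series.y.mean(axis=1))), float(np.min(series.y.mean(axis=1)))
    mid = 0.5 * (top0 + bottom0)
    log_ic50_0 = float(np.log10(series.x[np.argmin(np.abs(series.y.mean(axis=1) - mid))]))
    p0 = [log_ic50_0, 1.0, top0, bottom0]
    try:
        popt, pcov = curve_fit(four_pl, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"dose-response fit did not converge: {exc}") from exc
    log_ic50, hill, top, bottom = popt
    if hill < 0:  # equivalent curve with hill > 0 and top/bottom swapped
        hill, top, bottom = -hill, bottom, top
        log_ic50 = log_ic50  # unchanged under reparameterization
    ic50 = 10.0 ** log_ic50
    se_log = float(np.sqrt(np.abs(pcov[0, 0])))
    rss = float(np.sum((four_pl(x, *popt) - y) ** 2))
    return DoseResponseFit(
        ic50=float(ic50), hill=float(abs(hill)),
        top=float(max(top, bottom)), bottom=float(min(top, bottom)),
        se_ic50=float(LN10 * ic50 * se_log),
        extrapolated=not (series.x[0] <= ic50 <= series.x[-1]),
        rss=rss,
    )


def classify_activity(fit: DoseResponseFit, cutoff: float = 1000.0) -> str:
    """Label a compound inactive when IC50 > cutoff uM or extrapolated."""
    return "inactive" if (fit.ic50 > cutoff or fit.extrapolated) else "active"


# ---------------------------------------------------------------------------
# MST 1:1 binding
# ---------------------------------------------------------------------------

@dataclass
class BindingFit:
    kd_app: float        # uM
    f_free: float
    f_bound: float
    se_kd: float         # uM
    target_conc: float   # nM
    flagged: bool
    rss: float


def bound_fraction(ligand_um: np.ndarray, kd_um: float,
                   target_um: float) -> np.ndarray:
    """Exact 1:1 bound fraction of the target from the quadratic isotherm.

    fb = ((L + T + K) - sqrt((L + T + K)^2 - 4 L T)) / (2 T)
    """
    L = np.asarray(ligand_um, dtype=float)
    s = L + target_um + kd_um
    disc = np.clip(s * s - 4.0 * L * target_um, 0.0, None)
    return (s - np.sqrt(disc)) / (2.0 * target_um)


def fit_mst_kd(series: TitrationSeries, target_conc_nM: float = 100.0) -> BindingFit:
    """Fit Fnorm vs total ligand (uM) to the exact 1:1 isotherm.

    The labeled-target concentration is a known constant (nM).  The fitted
    K_D is apparent; a fit hitting its bounds or not converging is flagged.
    """
    if target_conc_nM <= 0:
        raise ValueError("target concentration must be positive")
    target_um = target_conc_nM * 1e-3
    x, y = series.flat()

    def model(L, log_kd, f_free, f_bound):
        return f_free + (f_bound - f_free) * bound_fraction(L, 10.0 ** log_kd, target_um)

    f_free0 = float(series.y[0].mean())
    f_bound0 = float(series.y[-1].mean())
    log_kd0 = float(np.log10(np.median(series.x)))
    lo, hi = np.log10(series.x[0]) - 4, np.log10(series.x[-1]) + 4
    flagged = False
    try:
        popt, pcov = curve_fit(model, x, y, p0=[log_kd0, f_free0, f_bound0],
                               bounds=([lo, -np.inf, -np.inf], [hi, np.inf, np.inf]),
                               maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"binding fit did not converge: {exc}") from exc
    log_kd, f_free, f_bound = popt
    if log_kd - lo < 1e-6 or hi - log_kd < 1e-6:
        flagged = True
    kd = 10.0 ** log_kd
    se_log = float(np.sqrt(np.abs(pcov[0, 0])))
    rss = float(np.sum((model(x, *popt) - y) ** 2))
    return BindingFit(kd_app=float(kd), f_free=float(f_free),
                      f_bound=float(f_bound), se_kd=float(LN10 * kd * se_log),
                      target_conc=float(target_conc_nM), flagged=flagged,
                      rss=rss)


# ---------------------------------------------------------------------------
# nanoDSF melting temperature
# ---------------------------------------------------------------------------

@dataclass
class ThermalFit:
    tm: float                       # C
    ratio_curve: pd.DataFrame       # columns: temperature, ratio
    derivative_curve: pd.DataFrame  # columns: temperature, dratio_dT


def _transition_midpoint(T: np.ndarray, ratio: np.ndarray, deriv: np.ndarray,
                         k: int, step: float) -> float:
    """Sub-grid location of the first-derivative extremum near index ``k``.

    Locates the inflection of the two-state transition by fitting
    ``baseline + slope*T + A / (1 + exp(-(T - Tm)/w))`` to the ratio curve
    (the derivative extremum of that model is exactly Tm); this uses the
    full transition amplitude rather than the noise-amplified pointwise
    derivative.  Falls back to parabolic interpolation of the derivative
    peak when the model fit fails, wanders outside the scan, or finds no
    significant amplitude.
    """
    # fallback: 3-point parabola through the empirical derivative extremum
    y0, y1, y2 = deriv[k - 1], deriv[k], deriv[k + 1]
    denom = y0 - 2 * y1 + y2
    parabolic = float(T[k]) if abs(denom) < 1e-300 else \
        float(T[k] + np.clip(0.5 * (y0 - y2) / denom, -1, 1) * step)

    sign = 1.0 if deriv[k] >= 0 else -1.0
    amp0 = sign * max(np.ptp(ratio) * 0.5, 1e-9)
    base0 = float(ratio[0])
    width0 = max(step, 0.25 / max(abs(deriv[k]) / abs(amp0), 1e-9) / 4.0)

    def model(t, base, slope, amp, tm, w):
        return base + slope * (t - T[0]) + amp / (1.0 + np.exp(-(t - tm) / w))

    try:
        popt, _ = curve_fit(model, T, ratio,
                            p0=[base0, 0.0, amp0, T[k], width0], maxfev=10000)
    except RuntimeError:
        return parabolic
    base, slope, amp, tm, w = popt
    resid = ratio - model(T, *popt)
    significant = abs(amp) > max(5.0 * float(np.std(resid)), 1e-9)
    if T[0] <= tm <= T[-1] and significant and abs(w) < (T[-1] - T[0]):
        return float(tm)
    return parabolic


def compute_tm(temperature: Sequence[float], f330: Sequence[float],
               f350: Sequence[float], window: int = 11,
               polyorder: int = 3) -> ThermalFit:
    """Melting temperature from the F350/F330 ratio, derivative method.

    The ratio is smoothed with a Savitzky-Golay filter (default window 11
    points, order 3), differentiated, and Tm taken as the location of the
    absolute derivative extremum, refined by parabolic interpolation.  The
    transition may raise or lower the ratio; the sign is auto-detected.
    Invariant to rescaling both channels by a common factor.
    """
    T = np.asarray(temperature, dtype=float)
    f330 = np.asarray(f330, dtype=float)
    f350 = np.asarray(f350, dtype=float)
    if len(T) < 50:
        raise ValueError("need at least 50 temperature points")
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperature ramp must be strictly monotone")
    if np.any(f330 <= 0):
        raise ValueError("F330 must be positive")
    ratio = f350 / f330
    step = float(np.median(np.diff(T)))
    smooth = savgol_filter(ratio, window, polyorder)
    deriv = savgol_filter(ratio, window, polyorder, deriv=1, delta=step)
    # exclude filter-edge artifacts from the extremum search
    half = window // 2
    interior = slice(half, len(T) - half)
    mag = np.abs(deriv[interior])
    if np.ptp(smooth) < 1e-4 * max(1.0, abs(np.median(smooth))):
        raise NoTransitionError("no transition detected: flat melting curve")
    k = int(np.argmax(mag)) + half
    if k <= half or k >= len(T) - half - 1:
        raise NoTransitionError("no transition detected inside the scanned range")
    tm = _transition_midpoint(T, ratio, deriv, k, step)
    return ThermalFit(
        tm=tm,
        ratio_curve=pd.DataFrame({"temperature": T, "ratio": ratio}),
        derivative_curve=pd.DataFrame({"temperature": T, "dratio_dT": deriv}),
    )


def delta_tm(apo: ThermalFit, complex_fit: ThermalFit) -> float:
    """Signed thermal shift: Tm(complex) - Tm(apo), in C."""
    return float(complex_fit.tm - apo.tm)


# ---------------------------------------------------------------------------
# STD epitope mapping
# ---------------------------------------------------------------------------

@dataclass
class STDRecord:
    label: str
    i_sat: float
    i_0: float
    effect: float        # I_sat / I_0 (or 1 - I_sat/I_0, by convention)
    relative_pct: float  # % relative to the reference proton


def std_epitope_map(records: Sequence[tuple[str, float, float]],
                    reference: str = "max",
                    convention: str = "ratio") -> list[STDRecord]:
    """Per-proton STD effects normalized to a reference proton.

    ``convention="ratio"`` defines the effect literally as I_sat/I_0;
    ``convention="difference"`` uses the saturation-transfer magnitude
    (I_0 - I_sat)/I_0 common elsewhere in the literature.  With
    ``reference="max"`` the largest effect is set to 100%; a named
    reference may yield relative values above 100%.
    """
    if convention not in ("ratio", "difference"):
        raise ValueError("convention must be 'ratio' or 'difference'")
    effects: dict[str, float] = {}
    for label, i_sat, i_0 in records:
        if i_0 <= 0:
            raise ValueError(f"proton {label!r}: off-resonance intensity must be positive")
        eff = i_sat / i_0
        effects[label] = eff if convention == "ratio" else 1.0 - eff
    if reference == "max":
        ref_effect = max(effects.values())
    else:
        if reference not in effects:
            raise KeyError(f"reference proton {reference!r} not in records")
        ref_effect = effects[reference]
    if ref_effect == 0:
        raise ValueError("reference effect is zero; cannot normalize")
    return [
        STDRecord(label=label, i_sat=float(i_sat), i_0=float(i_0),
                  effect=float(effects[label]),
                  relative_pct=float(100.0 * effects[label] / ref_effect))
        for label, i_sat, i_0 in records
    ]


# ---------------------------------------------------------------------------
# Henderson-Hasselbalch pKa
# ---------------------------------------------------------------------------

@dataclass
class PkaFit:
    pka: float
    delta_acid: float   # ppm, acidic-limit chemical shift
    delta_base: float   # ppm, basic-limit chemical shift
    se_pka: float
    rss: float


def henderson_hasselbalch(ph: np.ndarray, pka: float,
                          delta_acid: float, delta_base: float) -> np.ndarray:
    """delta(pH) = delta_base + (delta_acid - delta_base) / (1 + 10^(pH - pKa))."""
    return delta_base + (delta_acid - delta_base) / (1.0 + 10.0 ** (np.asarray(ph) - pka))


def fit_pka(series: TitrationSeries) -> PkaFit:
    """Fit chemical shift vs pH to the Henderson-Hasselbalch equation.

    The pH range must bracket the transition (>= 8 points).  Monotone-flat
    data raise :class:`FitError` ("no titration transition").  The estimate
    is invariant to swapping the acid/base limit initialization.
    """
    if len(series.x) < 8:
        raise ValueError("need at least 8 pH points")
    x, y = series.flat()
    if np.ptp(y) < 1e-6:
        raise FitError("no titration transition: chemical shift is flat")
    d_acid0 = float(series.y[0].mean())
    d_base0 = float(series.y[-1].mean())
    mid = 0.5 * (d_acid0 + d_base0)
    pka0 = float(series.x[np.argmin(np.abs(series.y.mean(axis=1) - mid))])
    try:
        popt, pcov = curve_fit(henderson_hasselbalch, x, y,
                               p0=[pka0, d_acid0, d_base0], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"pKa fit did not converge: {exc}") from exc
    pka, d_acid, d_base = (float(v) for v in popt)
    if not (series.x[0] <= pka <= series.x[-1]):
        raise FitError("fitted pKa falls outside the titrated pH range")
    rss = float(np.sum((henderson_hasselbalch(x, *popt) - y) ** 2))
    return PkaFit(pka=pka, delta_acid=d_acid, delta_base=d_base,
                  se_pka=float(np.sqrt(np.abs(pcov[0, 0]))), rss=rss)


def protonated_fraction(pka: float, ph: float) -> float:
    """Fraction protonated at a given pH: 1 / (1 + 10^(pH - pKa))."""
    return float(1.0 / (1.0 + 10.0 ** (ph - pka)))
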