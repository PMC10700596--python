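"""Assay and pharmacokinetic arithmetic.

Covers the quantitative post-screen characterization of hits: four-parameter
logistic (4PL) dose-response fitting, the Cheng-Prusoff IC50-to-Ki
conversion, ligand efficiency, Schild regression for competitive
antagonism, and noncompartmental PK analysis (AUC, Cmax, T1/2, oral
bioavailability) with explicit lower-limit-of-quantification (LLOQ)
handling: censored concentrations count as zero in the AUC and are
discarded from the terminal half-life regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

#: gas constant, kcal/(mol·K)
R_KCAL = 1.987e-3


class FitError(RuntimeError):
    """Raised when a curve fit cannot be performed or does not converge."""


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponse:
    """Concentration-response table; responses in % of control."""

    concentrations: np.ndarray    # molar
    responses: np.ndarray        # %
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if len(self.concentrations) != len(self.responses):
            raise ValueError("concentrations and responses differ in length")


def four_pl(
    x: np.ndarray,
    log_xc50: float,
    hill: float,
    top: float,
    bottom: float,
    model: Literal["inhibition", "stimulation"] = "inhibition",
) -> np.ndarray:
    """4PL curve.  For inhibition the response falls from ``top`` to
    ``bottom`` with increasing concentration; at ``x = XC50`` the response
    is the midpoint ``(top + bottom) / 2`` in both conventions."""
    lx = np.log10(np.asarray(x, dtype=float))
    sign = 1.0 if model == "inhibition" else -1.0
    expo = np.clip(sign * (lx - log_xc50) * hill, -300.0, 300.0)
    return bottom + (top - bottom) / (1.0 + 10.0**expo)


@dataclass
class DoseResponseResults:
    """Fitted 4PL parameters and diagnostics."""

    xc50: float                 # molar (IC50 or EC50 depending on model)
    hill: float
    top: float
    bottom: float
    model: str
    residual_sd: float
    converged: bool
    n_points: int
    cov: np.ndarray | None = None

    @property
    def log10_xc50(self) -> float:
        return math.log10(self.xc50)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return four_pl(x, self.log10_xc50, self.hill, self.top, self.bottom, self.model)

    def summary(self) -> str:
        name = "IC50" if self.model == "inhibition" else "EC50"
        lines = [
            "4PL dose-response fit",
            "=" * 34,
            f"model            {self.model}",
            f"{name:<10} (M)    {self.xc50:.4g}",
            f"log10 {name}      {self.log10_xc50:.4f}",
            f"Hill slope       {self.hill:.3f}",
            f"top (%)          {self.top:.2f}",
            f"bottom (%)       {self.bottom:.2f}",
            f"residual SD (%)  {self.residual_sd:.3f}",
            f"n points         {self.n_points}",
            f"converged        {self.converged}",
        ]
        return "\n".join(lines)


class DoseResponseModel:
    """4PL dose-response model with a statsmodels-like fit interface.

    Parameters
    ----------
    data : DoseResponse
        Concentration-response observations (>= 4 distinct concentrations).
    model : {"inhibition", "stimulation"}
        Direction of the response.
    """

    def __init__(self, data: DoseResponse, model: str = "inhibition") -> None:
        if model not in ("inhibition", "stimulation"):
            raise ValueError(f"unknown model {model!r}")
        if len(np.unique(data.concentrations)) < 4:
            raise ValueError("need at least 4 distinct concentrations")
        self.data = data
        self.model = model

    def fit(self, flat_tol: float = 1e-9) -> DoseResponseResults:
        """Least-squares 4PL fit with multi-start initialization.

        Five starting log-XC50 values spanning the observed concentration
        range guard against local minima; the best (lowest SSE) converged
        start wins.  A flat response (range below ``flat_tol``) is not
        fittable and raises :class:`FitError`.
        """
        x = self.data.concentrations
        y = self.data.responses
        if np.ptp(y) < flat_tol:
            raise FitError("response is flat; no dose dependence to fit")

        sign = 1.0 if self.model == "inhibition" else -1.0

        def f(xx, log_xc50, hill, top, bottom):
            return four_pl(xx, log_xc50, hill, top, bottom, self.model)

        lo, hi = math.log10(x.min()), math.log10(x.max())
        starts = np.linspace(lo, hi, 5)
        top0 = float(y.max())
        bot0 = float(y.min())
        best = None
        for s in starts:
            try:
                popt, pcov = optimize.curve_fit(
                    f,
                    x,
                    y,
                    p0=[s, 1.0, top0, bot0],
                    maxfev=10000,
                )
            except (RuntimeError, optimize.OptimizeWarning):
                continue
            sse = float(np.sum((f(x, *popt) - y) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt, pcov)
        if best is None:
            raise FitError("4PL fit failed to converge from every start")
        sse, popt, pcov = best
        log_xc50, hill, top, bottom = popt
        if top < bottom:  # canonical orientation: top is the high plateau
            top, bottom = bottom, top
            hill = -hill
        dof = max(len(x) - 4, 1)
        return DoseResponseResults(
            xc50=10.0**log_xc50,
            hill=float(hill),
            top=float(top),
            bottom=float(bottom),
            model=self.model,
            residual_sd=math.sqrt(sse / dof),
            converged=True,
            n_points=len(x),
            cov=pcov,
        )


def fit_dose_response(
    data: DoseResponse, model: str = "inhibition"
) -> DoseResponseResults:
    """Functional wrapper around :class:`DoseResponseModel`."""
    return DoseResponseModel(data, model=model).fit()


# ---------------------------------------------------------------------------
# Potency arithmetic
# ---------------------------------------------------------------------------

def cheng_prusoff(ic50: float, s: float, km: float) -> float:
    """Ki = IC50 / (S/Km + 1): functional IC50 corrected for agonist
    occupancy, with S the agonist concentration used in the assay and Km
    its EC50."""
    if ic50 <= 0 or s < 0 or km <= 0:
        raise ValueError("ic50 and km must be positive; s non-negative")
    return ic50 / (s / km + 1.0)


def ligand_efficiency(
    ki: float, heavy_atoms: int, temperature: float = 298.0
) -> float:
    """Binding free energy per heavy atom: LE = −R·T·ln(Ki) / N_heavy,
    in kcal/mol per heavy atom (Ki in molar)."""
    if ki <= 0:
        raise ValueError("ki must be positive")
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    return -R_KCAL * temperature * math.log(ki) / heavy_atoms


# ---------------------------------------------------------------------------
# Schild analysis
# ---------------------------------------------------------------------------

@dataclass
class SchildResult:
    pa2: float
    slope: float
    kb: float | None            # molar; reported only when slope is unit-like
    slope_ok: bool
    n_used: int
    intercept: float

    def summary(self) -> str:
        lines = [
            "Schild regression",
            "=" * 30,
            f"slope        {self.slope:.3f}" + ("" if self.slope_ok else "  [not unit slope]"),
            f"pA2          {self.pa2:.3f}",
            f"K_B (M)      {self.kb:.4g}" if self.kb is not None else "K_B          not reported (slope outside [0.8, 1.2])",
            f"n points     {self.n_used}",
        ]
        return "\n".join(lines)


def schild_analysis(
    dose_ratios: Sequence[tuple[float, float]],
    slope_window: tuple[float, float] = (0.8, 1.2),
) -> SchildResult:
    """Regression of log10(DR − 1) on log10[B] over antagonist
    concentrations B and agonist dose-ratios DR.

    A unit slope indicates simple competitive antagonism; the x-intercept
    is −pA2 and K_B = 10^(−pA2).  Points with DR <= 1 carry no antagonism
    information and are excluded with a warning; K_B is reported only when
    the slope falls within ``slope_window``.
    """
    usable = []
    for b, dr in dose_ratios:
        if dr <= 1.0:
            warnings.warn(f"dose ratio {dr} at [B]={b} <= 1; point excluded")
            continue
        if b <= 0:
            raise ValueError("antagonist concentrations must be positive")
        usable.append((math.log10(b), math.log10(dr - 1.0)))
    if len(usable) < 3:
        raise ValueError("need at least 3 usable (DR > 1) points")
    xs = np.array([u[0] for u in usable])
    ys = np.array([u[1] for u in usable])
    res = stats.linregress(xs, ys)
    slope = float(res.slope)
    intercept = float(res.intercept)
    x_intercept = -intercept / slope
    pa2 = -x_intercept
    slope_ok = slope_window[0] <= slope <= slope_window[1]
    return SchildResult(
        pa2=pa2,
        slope=slope,
        kb=10.0 ** (-pa2) if slope_ok else None,
        slope_ok=slope_ok,
        n_used=len(usable),
        intercept=intercept,
    )


# ---------------------------------------------------------------------------
# Noncompartmental PK
# ---------------------------------------------------------------------------

@dataclass
class PKProfile:
    """Concentration-time profile with below-LLOQ censoring.

    ``concentrations[i]`` is meaningful only where ``censored[i]`` is
    False; censored samples carry no numeric concentration.
    """

    timepoints: np.ndarray       # min
    concentrations: np.ndarray   # ng/ml
    censored: np.ndarray         # bool
    lloq: float                  # ng/ml
    dose: float                  # mg/kg
    route: Literal["iv", "oral", "ip"] = "iv"

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not (
            len(self.timepoints) == len(self.concentrations) == len(self.censored)
        ):
            raise ValueError("profile arrays differ in length")


@dataclass
class PKSummary:
    auc: float                   # ng·min/ml over the observed span
    cmax: float                  # ng/ml
    tmax: float                  # min
    t_half: float | None         # min; absent without a terminal phase
    points_used_for_t_half: int

    def summary(self) -> str:
        lines = [
            "Noncompartmental PK summary",
            "=" * 32,
            f"AUC (ng*min/ml)  {self.auc:,.0f}",
            f"Cmax (ng/ml)     {self.cmax:,.1f}",
            f"Tmax (min)       {self.tmax:.0f}",
            (
                f"T1/2 (min)       {self.t_half:.1f}  ({self.points_used_for_t_half} points)"
                if self.t_half is not None
                else "T1/2             not estimable"
            ),
        ]
        return "\n".join(lines)


def nca(profile: PKProfile) -> PKSummary:
    """Noncompartmental analysis with the two LLOQ rules.

    Censored concentrations are set to zero for the linear-trapezoid AUC
    (no extrapolation beyond the last timepoint); they are discarded from
    the terminal log-linear T1/2 regression, which uses the longest
    terminal run of >= 3 strictly declining quantifiable points.
    """
    quant = ~profile.censored
    if quant.sum() < 2:
        raise ValueError("need at least 2 quantifiable timepoints")
    conc_auc = np.where(profile.censored, 0.0, profile.concentrations)
    auc = float(np.trapezoid(conc_auc, profile.timepoints))

    qt = profile.timepoints[quant]
    qc = profile.concentrations[quant]
    imax = int(np.argmax(qc))
    cmax, tmax = float(qc[imax]), float(qt[imax])

    # longest strictly-declining suffix of the quantifiable series
    run = 1
    for i in range(len(qc) - 1, 0, -1):
        if qc[i - 1] > qc[i]:
            run += 1
        else:
            break
    t_half = None
    n_used = 0
    if run >= 3:
        tt, cc = qt[-run:], qc[-run:]
        res = stats.linregress(tt, np.log(cc))
        k = -float(res.slope)
        if k > 0:
            t_half = math.log(2.0) / k
            n_used = run
    return PKSummary(auc=auc, cmax=cmax, tmax=tmax, t_half=t_half,
                     points_used_for_t_half=n_used)


def oral_bioavailability(
    auc_ref: float, dose_ref: float, auc_test: float, dose_test: float
) -> float:
    """F (%) = 100 · (AUC_test/dose_test) / (AUC_ref/dose_ref), with the
    reference arm given intravenously."""
    if dose_ref <= 0 or dose_test <= 0:
        raise ValueError("doses must be positive")
    if auc_ref <= 0 or auc_test < 0:
        raise ValueError("AUCs must be positive (reference) / non-negative (test)")
    return 100.0 * (auc_test / dose_test) / (auc_ref / dose_ref)
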