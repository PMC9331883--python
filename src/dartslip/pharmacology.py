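"""Supporting pharmacology: % growth / GI50, PAMPA permeability, enzyme kinetics,
and docking-energy-to-affinity conversion.

These are the quantitative companions of the target-deconvolution pipeline:

* ``percent_growth`` / ``fit_gi50`` — growth-inhibition dose-response with the
  standard %-growth normalisation and a four-parameter logistic (4PL) fit; the
  GI50 is read off where the fitted curve crosses 50% growth.
* ``pampa_pe`` — effective permeability from a two-compartment single-time-point
  parallel artificial membrane permeability assay (PAMPA), reported as -log Pe
  with the usual permeability classification thresholds.
* ``activity_delta_abs`` — blank-corrected absorbance increment and initial rate
  for a coupled NADPH-producing glycogenolysis assay read at 340 nm.
* ``kd_from_dg`` — equilibrium dissociation constant from a docking free energy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

log = logging.getLogger(__name__)

#: gas constant, kcal / (mol K)
R_KCAL = 1.9872e-3


class DegenerateControlError(ValueError):
    pass


@dataclass(frozen=True)
class DoseResponsePoint:
    """One viability reading: treated signal T at time t, baseline T0, control C."""

    concentration: float  # µM
    T: float
    T0: float
    C: float


@dataclass(frozen=True)
class GI50Result:
    gi50: float  # µM; nan when fit_ok is False
    hill: float
    top: float
    bottom: float
    fit_ok: bool
    ci: tuple[float, float]  # µM


@dataclass(frozen=True)
class PampaRecord:
    """Geometry and concentrations for one PAMPA well."""

    donor_conc_0: float  # µM
    acceptor_conc_t: float  # µM
    V_donor: float  # µL
    V_acceptor: float  # µL
    area: float  # cm²
    time: float  # hours
    donor_conc_t: float = float("nan")  # optional; not used by the acceptor-side form


@dataclass
class ActivityKinetics:
    time: np.ndarray  # minutes
    od340: np.ndarray
    blank_od340: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od340 = np.asarray(self.od340, dtype=float)
        self.blank_od340 = np.asarray(self.blank_od340, dtype=float)
        if not (self.time.shape == self.od340.shape == self.blank_od340.shape):
            raise ValueError("time, sample and blank vectors differ in length")


# ---------------------------------------------------------------------------
# growth inhibition


def percent_growth(point: DoseResponsePoint) -> float:
    """% growth = 100 * (T - T0) / (C - T0).

    May be negative (net cell loss below the time-zero baseline) or exceed 100.
    """
    if point.C == point.T0:
        raise DegenerateControlError("control signal equals time-zero signal; % growth undefined")
    return 100.0 * (point.T - point.T0) / (point.C - point.T0)


def four_pl(conc: np.ndarray, top: float, bottom: float, mid: float, hill: float) -> np.ndarray:
    """Four-parameter logistic in concentration; decreasing for hill > 0.

    ``mid`` is the inflection concentration (response midway between top and
    bottom), not necessarily the GI50 when top/bottom differ from 100/0.
    """
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / mid) ** hill)


def _crossing_50(top: float, bottom: float, mid: float, hill: float) -> float:
    """Concentration where the fitted 4PL equals 50% growth; nan if none."""
    if not (min(top, bottom) < 50.0 < max(top, bottom)):
        return float("nan")
    return mid * ((top - 50.0) / (50.0 - bottom)) ** (1.0 / hill)


def fit_gi50(
    points: list[tuple[float, float]],
    n_boot: int = 500,
    seed: int | None = None,
) -> GI50Result:
    """Fit a 4PL to (concentration µM, % growth) points and read off the GI50.

    The GI50 is the concentration at which the fitted curve crosses 50% growth;
    ``fit_ok`` is False when the curve does not cross 50% within the tested
    concentration range. Confidence interval by parametric bootstrap
    (``n_boot`` refits on data resampled from the fitted curve plus the
    residual standard deviation; 2.5/97.5 percentiles). Set ``n_boot=0`` to
    skip the bootstrap.
    """
    conc = np.asarray([p[0] for p in points], dtype=float)
    resp = np.asarray([p[1] for p in points], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive (log-scale fit)")
    if len(np.unique(conc)) < 4:
        raise ValueError("need >= 4 distinct concentrations")

    def fit_once(y: np.ndarray) -> tuple[float, float, float, float]:
        p0 = (float(np.max(y)), float(np.min(y)), float(np.exp(np.mean(np.log(conc)))), 1.0)
        popt, _ = curve_fit(
            four_pl, conc, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12, 0.05], [np.inf, np.inf, 1e12, 20.0]),
            maxfev=20000,
        )
        return tuple(popt)  # type: ignore[return-value]

    try:
        top, bottom, mid, hill = fit_once(resp)
    except RuntimeError:
        return GI50Result(float("nan"), float("nan"), float("nan"), float("nan"),
                          False, (float("nan"), float("nan")))
    # GI50 is an inhibition readout: the fitted curve must fall with dose
    # (top asymptote above bottom, positive slope parameter) and cross 50%
    # inside the tested range.
    decreasing = (top - bottom) * hill > 0
    gi50 = _crossing_50(top, bottom, mid, hill)
    in_range = decreasing and math.isfinite(gi50) and conc.min() <= gi50 <= conc.max()
    if not in_range:
        return GI50Result(float("nan"), hill, top, bottom, False, (float("nan"), float("nan")))

    ci = (float("nan"), float("nan"))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        fitted = four_pl(conc, top, bottom, mid, hill)
        sigma = float(np.std(resp - fitted, ddof=min(4, len(resp) - 1)))
        draws = []
        for _ in range(n_boot):
            y = fitted + rng.normal(0.0, sigma, size=len(conc))
            try:
                t, b, m, h = fit_once(y)
            except RuntimeError:
                continue
            g = _crossing_50(t, b, m, h)
            if math.isfinite(g):
                draws.append(g)
        if draws:
            ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    return GI50Result(float(gi50), float(hill), float(top), float(bottom), True, ci)


def gi50_interpolated(points: list[tuple[float, float]]) -> float:
    """Fallback GI50: log-linear interpolation between the doses bracketing 50%."""
    pts = sorted(points)
    for (c0, y0), (c1, y1) in zip(pts, pts[1:]):
        if (y0 - 50.0) * (y1 - 50.0) <= 0 and y0 != y1:
            f = (y0 - 50.0) / (y0 - y1)
            return float(10 ** (np.log10(c0) + f * (np.log10(c1) - np.log10(c0))))
    return float("nan")


# ---------------------------------------------------------------------------
# PAMPA


def pampa_pe(rec: PampaRecord) -> tuple[float, float]:
    """Effective permeability Pe (cm/s) and -log10 Pe from a single-time-point well.

    Two-compartment model without donor-depletion sampling::

        C_eq = C_D(0) * V_D / (V_D + V_A)
        Pe   = -ln(1 - C_A(t)/C_eq) * V_D*V_A / ((V_D + V_A) * A * t_seconds)

    Acceptor concentration at or above equilibrium is an error (the log form
    diverges); zero acceptor concentration gives Pe = 0 and -log Pe = +inf.
    """
    if rec.time <= 0:
        raise ValueError("incubation time must be positive")
    if min(rec.donor_conc_0, rec.acceptor_conc_t) < 0:
        raise ValueError("concentrations must be non-negative")
    c_eq = rec.donor_conc_0 * rec.V_donor / (rec.V_donor + rec.V_acceptor)
    if rec.acceptor_conc_t >= c_eq:
        raise ValueError(
            f"acceptor concentration {rec.acceptor_conc_t} at/above equilibrium {c_eq:.4g}"
        )
    if rec.acceptor_conc_t == 0:
        return 0.0, float("inf")
    t_sec = rec.time * 3600.0
    pe = (
        -math.log(1.0 - rec.acceptor_conc_t / c_eq)
        * rec.V_donor * rec.V_acceptor
        / ((rec.V_donor + rec.V_acceptor) * rec.area * t_sec)
    )
    return pe, -math.log10(pe)


def pampa_label(neg_log_pe: float) -> str:
    """Classify permeability: < 6 permeable, 6-6.5 intermediate, > 6.5 impermeable."""
    if neg_log_pe < 6.0:
        return "permeable"
    if neg_log_pe <= 6.5:
        return "intermediate"
    return "impermeable"


# ---------------------------------------------------------------------------
# coupled activity assay


def activity_delta_abs(
    kin: ActivityKinetics, t_read: float, rate_window: float = 30.0
) -> tuple[float, float]:
    """Blank-corrected absorbance increment at ``t_read`` minutes, plus initial rate.

    Delta Abs = [OD(t) - OD(0)] - [blank(t) - blank(0)], with linear
    interpolation between sampled times. The initial rate is the least-squares
    slope (AU/min) of the blank-corrected trace over the first
    ``rate_window`` minutes.
    """
    t = kin.time
    if not (t[0] <= t_read <= t[-1]):
        raise ValueError(f"t_read {t_read} outside sampled range [{t[0]}, {t[-1]}]")
    corrected = (kin.od340 - kin.od340[0]) - (kin.blank_od340 - kin.blank_od340[0])
    delta = float(np.interp(t_read, t, corrected))
    mask = t <= t[0] + rate_window
    if mask.sum() >= 2:
        slope = float(np.polyfit(t[mask], corrected[mask], 1)[0])
    else:
        slope = float("nan")
    return delta, slope


# ---------------------------------------------------------------------------
# docking energetics


def kd_from_dg(dg: float, temperature: float = 298.0) -> float:
    """Equilibrium dissociation constant (molar) from a binding free energy.

    Kd = exp(dG / (R T)) with R = 1.9872e-3 kcal/(mol K); dG in kcal/mol
    (negative for favourable binding), reference state 1 M.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return math.exp(dg / (R_KCAL * temperature))


def dg_from_kd(kd: float, temperature: float = 298.0) -> float:
    """Inverse of :func:`kd_from_dg`: dG = R T ln Kd, kcal/mol."""
    if kd <= 0:
        raise ValueError("Kd must be positive (molar)")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return R_KCAL * temperature * math.log(kd)
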