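"""Stern–Volmer analysis of corrected fluorescence titrations.

Collisional (dynamic) and complex-forming (static) quenching both obey the
Stern–Volmer law at low quencher concentration,

    F₀/F = 1 + K_SV·[Q]

with F₀ and F the window-integrated, inner-filter-corrected intensities
before and after quencher addition. The slope K_SV (written ``K_q`` here,
units M⁻¹) divided by the unquenched fluorophore lifetime τ₀ (10⁻⁸ s for
tryptophan) gives the bimolecular quenching constant k_q; values above the
diffusion-controlled limit ~2×10¹⁰ M⁻¹s⁻¹ indicate a ground-state complex
rather than purely collisional quenching.

The mechanism is classified from the temperature dependence of K_q: static
quenching weakens on heating (the complex dissociates), dynamic quenching
strengthens (faster diffusion), and a flat trend is read as a combination
of both. At extreme quencher concentrations the plot curves upward as
closely spaced fluorophore–quencher pairs act as dark complexes, so fits
are truncated to the first ``n_points`` (default 7) samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from albind.errors import ClassificationError, DataError, FitError, InvariantError
from albind.spectra import (
    CorrectionSettings,
    TitrationSeries,
    inner_filter_correct,
    integrate_window,
)

#: Unquenched fluorescence lifetime of tryptophan, seconds.
TRP_LIFETIME_S = 1e-8

#: Maximum diffusion-controlled (scattering collision) quenching constant,
#: M⁻¹ s⁻¹; larger k_q implies static, complex-forming quenching.
DIFFUSION_LIMIT = 2.0e10

CurvatureFlag = Literal["linear", "upward", "downward"]
MechanismLabel = Literal["static", "dynamic", "static_dynamic_combination"]


@dataclass(frozen=True)
class QuenchingCurve:
    """F₀/F ratios against quencher concentration at one temperature."""

    concentrations: np.ndarray
    ratios: np.ndarray
    temperature: float
    n_points_used: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        ratios = np.asarray(self.ratios, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "ratios", ratios)
        if conc.shape != ratios.shape or conc.ndim != 1:
            raise InvariantError("concentrations and ratios must match 1-d shapes")
        if conc.size < 2:
            raise InvariantError("quenching curve needs at least 2 points")
        if conc[0] != 0.0 or ratios[0] != 1.0:
            raise InvariantError("first point must be [Q]=0 with ratio exactly 1")
        if not np.all(np.diff(conc) > 0):
            raise InvariantError("concentrations must be strictly increasing")

    def __len__(self) -> int:
        return int(self.concentrations.size)


@dataclass(frozen=True)
class QuenchingResult:
    """Stern–Volmer fit: K_q (M⁻¹), k_q = K_q/τ₀ (M⁻¹s⁻¹), diagnostics.

    ``k_q`` is derived from ``K_q`` and ``tau_0`` in the constructor so the
    identity k_q = K_q/τ₀ holds exactly for every instance.
    """

    K_q: float
    intercept: float
    pearson_r: float
    tau_0: float = TRP_LIFETIME_S
    K_q_stderr: float = float("nan")
    curvature_flag: CurvatureFlag = "linear"
    k_q: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.tau_0 > 0:
            raise InvariantError("tau_0 must be positive")
        if np.isfinite(self.pearson_r) and abs(self.pearson_r) > 1 + 1e-12:
            raise InvariantError("|pearson_r| must be <= 1")
        object.__setattr__(self, "k_q", self.K_q / self.tau_0)


@dataclass(frozen=True)
class MechanismCall:
    """Quenching-mechanism classification from a temperature series."""

    label: MechanismLabel
    diffusion_limit_exceeded: bool
    relative_trend: float  # fractional K_q change per kelvin


def build_quenching_curve(
    series: TitrationSeries, corrections: CorrectionSettings | None = None
) -> QuenchingCurve:
    """Form F₀/F from window-integrated, corrected intensities.

    Each point's emission spectrum is integrated over the series' window;
    the inner-filter correction is applied per point (using the point's own
    A_ex/A_em) when enabled. Background subtraction, which needs the buffer
    spectrum, is the manifest loader's job and must happen before the series
    is assembled.
    """
    if corrections is None:
        corrections = CorrectionSettings()
    intensities = []
    for point in series.points:
        f = integrate_window(
            point.spectrum, series.window_center, series.window_width
        )
        if corrections.apply_inner_filter:
            f = inner_filter_correct(f, point.a_ex, point.a_em)
        if f <= 0:
            raise DataError(
                f"non-positive corrected intensity at "
                f"titrant_total={point.titrant_total!r}"
            )
        intensities.append(f)
    f0 = intensities[0]
    ratios = f0 / np.asarray(intensities)
    ratios[0] = 1.0  # exact by construction
    return QuenchingCurve(
        concentrations=series.titrant_totals,
        ratios=ratios,
        temperature=series.temperature,
        n_points_used=len(series),
    )


def _curvature_flag(curve: QuenchingCurve, rel_tol: float = 0.01) -> CurvatureFlag:
    """Sign of a quadratic term fitted to the full curve.

    Flagged linear when the quadratic contribution at the highest
    concentration is below ``rel_tol`` of the total span of the curve —
    a deterministic smallness rule rather than a significance test.
    """
    if len(curve) < 3:
        return "linear"
    coeffs = np.polynomial.polynomial.polyfit(
        curve.concentrations, curve.ratios, deg=2
    )
    quad_at_max = coeffs[2] * curve.concentrations[-1] ** 2
    span = max(np.ptp(curve.ratios), 1e-12)
    if abs(quad_at_max) < rel_tol * span:
        return "linear"
    return "upward" if coeffs[2] > 0 else "downward"


def stern_volmer_fit(curve: QuenchingCurve, n_points: int = 7) -> QuenchingResult:
    """Ordinary least squares of F₀/F on [Q] over the first ``n_points``.

    The intercept is fitted freely (not pinned at 1): a free intercept far
    from 1 exposes correction errors. ``pearson_r`` is computed on the
    fitted subset; the curvature flag is judged on the full curve so the
    dark-complex upward bend at extreme concentrations is still reported
    when the fit itself is truncated below it.
    """
    n_points = min(n_points, len(curve))
    if n_points < 3:
        raise FitError("Stern-Volmer fit needs at least 3 points")
    q = curve.concentrations[:n_points]
    r = curve.ratios[:n_points]
    design = np.column_stack([np.ones_like(q), q])
    (intercept, slope), residuals, *_ = np.linalg.lstsq(design, r, rcond=None)
    dof = n_points - 2
    if dof > 0 and np.ptp(q) > 0:
        resid = r - design @ np.array([intercept, slope])
        sigma2 = float(resid @ resid) / dof
        sxx = float(np.sum((q - q.mean()) ** 2))
        stderr = float(np.sqrt(sigma2 / sxx))
    else:
        stderr = float("nan")
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    if ss_tot == 0.0:
        pearson = 1.0  # constant data: the zero-slope line is a perfect fit
    else:
        # r² = 1 − SS_res/SS_tot with the fitted line; on collinear input
        # SS_res underflows relative to SS_tot and r is exactly ±1
        ss_res = float(np.sum((r - design @ np.array([intercept, slope])) ** 2))
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
        pearson = float(np.copysign(np.sqrt(r2), slope if slope != 0 else 1.0))
    return QuenchingResult(
        K_q=float(slope),
        intercept=float(intercept),
        pearson_r=pearson,
        K_q_stderr=stderr,
        curvature_flag=_curvature_flag(curve),
    )


def bimolecular_constant(K_q: float, tau_0: float = TRP_LIFETIME_S) -> float:
    """k_q = K_q / τ₀ in M⁻¹ s⁻¹."""
    if not tau_0 > 0:
        raise DataError("tau_0 must be positive")
    return K_q / tau_0


def classify_mechanism(
    results_by_temperature: Sequence[tuple[float, QuenchingResult]],
    tolerance: float = 0.05,
) -> MechanismCall:
    """Classify the quenching mechanism from K_q across temperatures.

    A linear trend of K_q against T is fitted; the relative change across
    the full temperature span below ``tolerance`` is read as a combination
    of static and dynamic quenching (K_q effectively constant), a
    significant decrease as static, a significant increase as dynamic.
    Classification is invariant to the ordering of the input list.

    ``diffusion_limit_exceeded`` reports whether k_q at the highest
    temperature exceeds the diffusion-controlled collisional limit.
    """
    if len(results_by_temperature) < 2:
        raise ClassificationError("need results at >= 2 temperatures")
    pairs = sorted(results_by_temperature, key=lambda tr: tr[0])
    temps = np.array([t for t, _ in pairs])
    if np.unique(temps).size < 2:
        raise ClassificationError("need >= 2 distinct temperatures")
    kqs = np.array([res.K_q for _, res in pairs])
    slope = np.polynomial.polynomial.polyfit(temps, kqs, deg=1)[1]
    mean_kq = float(np.mean(np.abs(kqs)))
    if mean_kq == 0.0:
        raise ClassificationError("all K_q are zero; mechanism undefined")
    rel_per_kelvin = float(slope / mean_kq)
    span = float(temps[-1] - temps[0])
    rel_change = rel_per_kelvin * span
    if abs(rel_change) <= tolerance:
        label: MechanismLabel = "static_dynamic_combination"
    elif rel_change < 0:
        label = "static"
    else:
        label = "dynamic"
    k_q_hottest = pairs[-1][1].k_q
    return MechanismCall(
        label=label,
        diffusion_limit_exceeded=bool(k_q_hottest > DIFFUSION_LIMIT),
        relative_trend=rel_per_kelvin,
    )
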