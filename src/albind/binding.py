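"""Equilibrium 1:1 binding with ligand depletion: K_D, ΔG, comparisons.

At the micromolar protein concentrations of a tryptophan-fluorescence
titration the bound ligand is not a negligible fraction of the total, so
the free-ligand concentration must come from the exact mass balance of the
1:1 equilibrium P + L ⇌ PL with dissociation constant K_D:

    L_free = ½[(L_t − P_t − K_D) + √((L_t − P_t − K_D)² + 4·K_D·L_t)]

The fluorescence signal model is a two-state fluorophore: F/F₀ is affine
in the fractional occupancy of the single binding site,

    F/F₀ = 1 + (r_sat − 1) · L_free/(L_free + K_D)

with ``r_sat`` the fitted plateau at saturation (r_sat < 1 for quenching,
> 1 for enhancement). K_D is then the free-ligand concentration at the
halfway point of the sigmoid on a semilog axis, and the standard Gibbs
free energy of binding follows as ΔG = −R·T·ln(c⁰/K_D) with the standard
reference concentration c⁰ = 1 mol/L.

One class of independent sites with stoichiometry 1 is assumed throughout;
no Hill exponent or Scatchard-style "number of binding sites" is fitted,
because a single titration cannot identify one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from albind.errors import DataError, FitError, InvariantError

#: Ideal gas constant, J mol⁻¹ K⁻¹.
GAS_CONSTANT = 8.314

#: Standard reference concentration c⁰, mol/L.
STANDARD_CONCENTRATION = 1.0

AffinityCall = Literal["unchanged", "enhanced", "weakened"]


@dataclass(frozen=True)
class BindingSystem:
    """A titration reduced to signal ratios: the input to ``fit_binding``.

    ``p_total`` is the fixed protein concentration (mol/L), ``l_totals``
    the total ligand concentrations and ``signal_ratios`` the matched
    F/F₀ values (corrected, window-integrated).
    """

    p_total: float
    l_totals: np.ndarray
    signal_ratios: np.ndarray
    temperature: float
    label: str = ""

    def __post_init__(self) -> None:
        lt = np.asarray(self.l_totals, dtype=float)
        sr = np.asarray(self.signal_ratios, dtype=float)
        object.__setattr__(self, "l_totals", lt)
        object.__setattr__(self, "signal_ratios", sr)
        if lt.shape != sr.shape or lt.ndim != 1:
            raise InvariantError("l_totals and signal_ratios must match 1-d shapes")
        if lt[0] != 0.0 or not np.all(np.diff(lt) > 0):
            raise InvariantError("l_totals must be strictly increasing from 0")
        if sr[0] != 1.0:
            raise InvariantError("signal_ratios[0] must be exactly 1 (the F0 point)")
        if not self.p_total > 0:
            raise InvariantError("p_total must be positive")
        if not self.temperature > 0:
            raise InvariantError("temperature must be positive (kelvin)")

    def __len__(self) -> int:
        return int(self.l_totals.size)


@dataclass(frozen=True)
class BindingFit:
    """Fitted 1:1 binding model: K_D, signal plateau, ΔG, diagnostics."""

    K_D: float
    ratio_at_saturation: float
    delta_g: float  # kJ/mol at the system temperature
    residual_norm: float
    free_ligand_at_half: float
    temperature: float
    K_D_stderr: float = float("nan")
    saturation_reached: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if not self.K_D > 0:
            raise InvariantError("K_D must be positive")


@dataclass(frozen=True)
class InteractionReport:
    """Binary-vs-ternary affinity comparison for one titrant."""

    kd_binary: float
    kd_ternary: float
    call: AffinityCall
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratio", self.kd_ternary / self.kd_binary)


def system_from_curve(curve, p_total: float, label: str = "") -> BindingSystem:
    """Build the binding-fit input from a Stern–Volmer quenching curve.

    The quenching module works with F₀/F; the binding model is written in
    F/F₀, so the ratios are inverted (the reference point stays exactly 1).
    """
    ratios = 1.0 / np.asarray(curve.ratios, dtype=float)
    ratios[0] = 1.0
    return BindingSystem(
        p_total=p_total,
        l_totals=np.asarray(curve.concentrations, dtype=float),
        signal_ratios=ratios,
        temperature=curve.temperature,
        label=label,
    )


def free_ligand(l_total, p_total, k_d):
    """Free-ligand concentration from the 1:1 mass balance (mol/L).

    Vectorized in ``l_total``. The quadratic root is evaluated in the
    cancellation-free branch so it is accurate to machine precision even
    deep in the ligand-depleted regime (L_t ≪ P_t).
    """
    l_total = np.asarray(l_total, dtype=float)
    if np.any(l_total < 0) or p_total < 0 or not k_d > 0:
        raise DataError("concentrations must be >= 0 and k_d > 0")
    b = l_total - p_total - k_d
    c = k_d * l_total
    disc = np.sqrt(b * b + 4.0 * c)
    # root = (b + disc)/2, rewritten as 2c/(disc - b) where b < 0 to avoid
    # subtractive cancellation.
    with np.errstate(invalid="ignore", divide="ignore"):
        root = np.where(b >= 0, (b + disc) / 2.0, 2.0 * c / (disc - b))
    root = np.where(c == 0.0, np.where(b >= 0, b, 0.0), root)
    return float(root) if root.ndim == 0 else root


def fraction_bound(l_total, p_total, k_d):
    """Fractional occupancy PL/P_t of the single site, in [0, 1)."""
    if not p_total > 0:
        raise DataError("fraction_bound is undefined for p_total = 0")
    lf = free_ligand(l_total, p_total, k_d)
    return lf / (lf + k_d)


def gibbs_free_energy(k_d: float, temperature: float) -> float:
    """Standard Gibbs free energy of binding, ΔG = −R·T·ln(c⁰/K_D), kJ/mol.

    ``k_d`` in mol/L; negative ΔG (K_D < 1 M) means spontaneous binding.
    """
    if not k_d > 0 or not temperature > 0:
        raise DataError("k_d and temperature must be positive")
    return (
        -GAS_CONSTANT
        * temperature
        * np.log(STANDARD_CONCENTRATION / k_d)
        / 1000.0
    )


def _signal_model(l_totals, p_total, k_d, r_sat):
    return 1.0 + (r_sat - 1.0) * fraction_bound(l_totals, p_total, k_d)


def fit_binding(system: BindingSystem) -> BindingFit:
    """Nonlinear least squares of the two-state signal model.

    Fits (K_D, r_sat) by trust-region least squares; K_D is
    log-parameterized (positivity built in) and initialized at the
    geometric midpoint of the nonzero L_total range. ``free_ligand_at_half``
    is read off the fitted curve as the interpolated L_free where the
    signal change is half its fitted span — by construction of the model it
    must equal K_D, so a mismatch flags an interpolation or convergence
    problem rather than a chemical result.

    Raises ``FitError`` when the signal carries no binding information
    (flat ratios) or the optimizer fails; sets ``saturation_reached=False``
    with a warning when the titration stops below 95% occupancy.
    """
    if len(system) < 5:
        raise FitError("binding fit needs at least 5 titration points")
    lt = system.l_totals
    ratios = system.signal_ratios
    span = float(np.max(np.abs(ratios - 1.0)))
    if span < 1e-9:
        raise FitError("flat signal: K_D is unidentifiable")
    nonzero = lt[lt > 0]
    log_kd0 = float(np.mean(np.log(nonzero)))
    r_sat0 = float(ratios[-1])
    if abs(r_sat0 - 1.0) < 1e-9:
        r_sat0 = 1.0 + 2.0 * (ratios[np.argmax(np.abs(ratios - 1.0))] - 1.0)

    def residuals(params):
        log_kd, r_sat = params
        return _signal_model(lt, system.p_total, np.exp(log_kd), r_sat) - ratios

    sol = least_squares(
        residuals,
        x0=[log_kd0, r_sat0],
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    if not sol.success:
        raise FitError(f"binding fit did not converge: {sol.message}")
    k_d = float(np.exp(sol.x[0]))
    r_sat = float(sol.x[1])
    if abs(r_sat - 1.0) < 1e-9:
        raise FitError("fitted plateau indistinguishable from 1: unidentifiable K_D")

    # standard error on K_D via the Jacobian (delta method for the log-param)
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(len(system) - 2, 1)
        sigma2 = 2.0 * sol.cost / dof
        cov = sigma2 * np.linalg.inv(jtj)
        kd_stderr = float(np.sqrt(cov[0, 0]) * k_d)
    except np.linalg.LinAlgError:
        kd_stderr = float("nan")

    lf = free_ligand(lt, system.p_total, k_d)
    occ = lf / (lf + k_d)
    saturation = bool(occ[-1] >= 0.95)
    if not saturation:
        warnings.warn(
            f"titration reaches only {occ[-1]:.0%} occupancy; "
            "K_D extrapolates beyond the sampled range"
        )
    half_signal = 1.0 + (r_sat - 1.0) / 2.0
    fitted = _signal_model(lt, system.p_total, k_d, r_sat)
    lf_half = _interp_halfway(lf, fitted, half_signal)
    return BindingFit(
        K_D=k_d,
        ratio_at_saturation=r_sat,
        delta_g=gibbs_free_energy(k_d, system.temperature),
        residual_norm=float(np.linalg.norm(sol.fun)),
        free_ligand_at_half=lf_half,
        temperature=system.temperature,
        K_D_stderr=kd_stderr,
        saturation_reached=saturation,
        label=system.label,
    )


def _interp_halfway(lf: np.ndarray, fitted: np.ndarray, half: float) -> float:
    """log-linear interpolation of L_free at the half-signal point."""
    drop = fitted - half
    sign_change = np.where(np.diff(np.sign(drop)) != 0)[0]
    if sign_change.size == 0:
        # half-signal outside the sampled curve; fall back to the model root
        return float("nan")
    i = int(sign_change[0])
    x0, x1 = lf[i], lf[i + 1]
    y0, y1 = drop[i], drop[i + 1]
    if x0 <= 0:  # first point is L=0; interpolate linearly there
        return float(x0 + (x1 - x0) * (-y0) / (y1 - y0))
    t = (-y0) / (y1 - y0)
    return float(np.exp(np.log(x0) + t * (np.log(x1) - np.log(x0))))


def compare_systems(
    binary: BindingFit, ternary: BindingFit, threshold: float = 0.10
) -> InteractionReport:
    """Compare binary and ternary K_D of the same titrant.

    ``enhanced`` means the ternary K_D is lower (tighter binding in the
    presence of the pre-bound competitor), ``weakened`` the opposite;
    within ``threshold`` relative the affinity is called unchanged.
    """
    if binary.temperature != ternary.temperature:
        raise DataError(
            f"temperature mismatch: {binary.temperature} K vs "
            f"{ternary.temperature} K"
        )
    ratio = ternary.K_D / binary.K_D
    if abs(ratio - 1.0) <= threshold:
        call: AffinityCall = "unchanged"
    elif ratio < 1.0:
        call = "enhanced"
    else:
        call = "weakened"
    return InteractionReport(kd_binary=binary.K_D, kd_ternary=ternary.K_D, call=call)
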