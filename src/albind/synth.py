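"""Synthetic-data generators: every pipeline input with known ground truth.

The study the pipeline targets deposits no raw spectra, so the package
carries a forward model of the experiments instead: tryptophan-fluorescence
titrations of 5 μM HSA with amlodipine (0–500 μM) or quercetin
(0–83.3 μM), ligand-fluorescence enhancement titrations, ternary
(competitor-preincubated) titrations, far-/near-UV CD spectra with a
prescribed α-helix content, and amide-region IR spectra as Gaussian band
sums. Each generator embeds the physics the analysis modules invert —
static (ground-state complex) quenching through site occupancy, collisional
quenching through the free-quencher concentration, the inner-filter
attenuation 10^(−(A_ex+A_em)/2), the MRE normalization — so that on
noise-free data the analysis pipeline is the identity on the generative
parameters. Noise is multiplicative Gaussian on fluorescence intensities
(shot-noise-dominated counting) and additive on CD/IR signals; every
generator is bitwise-deterministic under a fixed seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from albind.binding import free_ligand
from albind.cd import (
    CDConditions,
    mre_at_helix_percent,
    theta_from_mre,
)
from albind.errors import GenerationError, InvariantError
from albind.ftir import AmideBand
from albind.spectra import Spectrum, SpectrumKind, TitrationPoint, TitrationSeries

#: Amlodipine concentration series of the binary titration design, mol/L.
AML_SERIES_M = tuple(
    c * 1e-6
    for c in (0.0, 3.9, 7.8, 15.6, 31.25, 62.5, 125.0, 250.0, 333.3, 500.0)
)

#: Quercetin concentration series of the binary titration design, mol/L.
Q_SERIES_M = tuple(
    c * 1e-6
    for c in (0.0, 1.95, 3.9, 7.8, 10.4, 15.6, 20.8, 31.25, 41.6, 62.5, 83.3)
)

#: Measurement temperatures of the titration design, kelvin.
TEMPERATURES_K = (298.15, 303.15, 310.15)

#: HSA concentration in the quenching titrations, mol/L.
HSA_TOTAL_M = 5e-6

#: Trp excitation wavelength (nm) and emission maximum of free HSA (nm).
EXCITATION_NM = 295.0
EMISSION_MAX_NM = 347.0


@dataclass(frozen=True)
class TitrationScenario:
    """Ground truth for one simulated fluorescence titration.

    ``ratio_at_saturation`` is the F/F₀ plateau of the static (occupancy-
    linked) signal change; ``dynamic_kq`` adds a collisional Stern–Volmer
    component acting through the free-titrant concentration;
    ``dark_complex_volume`` (per mol/L) adds a sphere-of-action term
    exp(V·[Q]) that bends the Stern–Volmer plot upward at extreme quencher
    concentrations; ``absorbance_per_molar`` are the titrant's effective
    extinction terms (per mol/L, path included) at the excitation and
    emission wavelengths, from which per-point A_ex/A_em — and the embedded
    inner-filter attenuation — are derived. ``noise_sd`` is the relative SD
    of the multiplicative intensity noise.
    """

    p_total: float = HSA_TOTAL_M
    l_totals: tuple[float, ...] = Q_SERIES_M
    k_d: float = 6.48e-6
    ratio_at_saturation: float = 0.1
    dynamic_kq: float = 0.0
    dark_complex_volume: float = 0.0
    emission_center: float = EMISSION_MAX_NM
    emission_sigma: float = 25.0
    blue_shift_at_saturation: float = 0.0
    absorbance_per_molar: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.01
    seed: int = 0
    temperature: float = 310.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "l_totals", tuple(self.l_totals))
        lt = np.array(self.l_totals)
        if not self.k_d > 0:
            raise GenerationError("k_d must be positive")
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")
        if self.p_total < 0:
            raise GenerationError("p_total must be >= 0")
        if lt.size < 2 or lt[0] != 0.0 or not np.all(np.diff(lt) > 0):
            raise GenerationError("l_totals must be strictly increasing from 0")
        if self.emission_sigma <= 0:
            raise GenerationError("emission_sigma must be positive")


class TernaryMode(str, enum.Enum):
    """How the pre-bound competitor acts on the titrant."""

    COMPETITIVE = "competitive"
    COOPERATIVE = "cooperative"


def _emission_grid() -> np.ndarray:
    return np.arange(300.0, 400.0 + 0.25, 0.5)


def _titration_point(
    sc: TitrationScenario,
    l_total: float,
    occupancy: float,
    l_free: float,
    rng: np.random.Generator,
) -> TitrationPoint:
    grid = _emission_grid()
    static = 1.0 + (sc.ratio_at_saturation - 1.0) * occupancy
    dynamic = 1.0 / (1.0 + sc.dynamic_kq * l_free)
    # sphere-of-action "dark complexes": quencher molecules already inside
    # the first solvent shell at excitation quench instantly, multiplying
    # the Stern-Volmer ratio by exp(V·[Q]) and bending it upward at
    # extreme quencher concentrations.
    dark = np.exp(-sc.dark_complex_volume * l_free)
    center = sc.emission_center - sc.blue_shift_at_saturation * occupancy
    eps_ex, eps_em = sc.absorbance_per_molar
    a_ex = eps_ex * l_total
    a_em = eps_em * l_total
    attenuation = 10.0 ** (-(a_ex + a_em) / 2.0)
    amplitude = 1e6 * static * dynamic * dark * attenuation
    signal = amplitude * np.exp(
        -((grid - center) ** 2) / (2.0 * sc.emission_sigma**2)
    )
    if sc.noise_sd > 0:
        signal = signal * (1.0 + sc.noise_sd * rng.standard_normal(grid.size))
    spectrum = Spectrum(
        axis=grid,
        signal=signal,
        kind=SpectrumKind.EMISSION,
        temperature=sc.temperature,
        label=f"titrant {l_total * 1e6:.4g} uM",
    )
    return TitrationPoint(
        titrant_total=l_total, spectrum=spectrum, a_ex=a_ex, a_em=a_em
    )


def simulate_titration(sc: TitrationScenario) -> TitrationSeries:
    """Forward-simulate a binary fluorescence titration.

    Per point: the free-titrant concentration and site occupancy come from
    the same mass-balance solution the binding module uses; the emission
    band is a Gaussian whose amplitude carries the static and dynamic
    quenching factors and the embedded inner-filter attenuation, and whose
    center shifts blue with occupancy. A_ex/A_em are recorded on each point
    so the inner-filter correction is exactly invertible in the noise-free
    case.
    """
    rng = np.random.default_rng(sc.seed)
    points = []
    for l_total in sc.l_totals:
        lf = free_ligand(l_total, sc.p_total, sc.k_d)
        occ = lf / (lf + sc.k_d)
        points.append(_titration_point(sc, l_total, occ, lf, rng))
    return TitrationSeries(
        fixed_total=sc.p_total,
        points=tuple(points),
        excitation_wavelength=EXCITATION_NM,
        window_center=sc.emission_center,
        window_width=10.0,
        temperature=sc.temperature,
    )


def solve_competitive_equilibrium(
    p_total: float,
    a_total: float,
    k_a: float,
    b_total: float,
    k_b: float,
) -> tuple[float, float, float]:
    """Two-ligand, one-site equilibrium: free (P, A, B) concentrations.

    Solves P·(1 + A_t/(K_A+P) + B_t/(K_B+P)) = P_t for the free protein by
    bracketed root finding (the left side is strictly increasing in P), then
    recovers the free ligands; mass is conserved to better than 10⁻¹²
    relative.
    """
    if min(p_total, a_total, b_total) < 0 or k_a <= 0 or k_b <= 0:
        raise GenerationError("concentrations must be >= 0 and constants > 0")
    if p_total == 0:
        return 0.0, a_total, b_total

    def residual(p: float) -> float:
        return p * (1.0 + a_total / (k_a + p) + b_total / (k_b + p)) - p_total

    p_free = brentq(residual, 0.0, p_total, xtol=1e-300, rtol=8.9e-16)
    a_free = a_total * k_a / (k_a + p_free)
    b_free = b_total * k_b / (k_b + p_free)
    return float(p_free), float(a_free), float(b_free)


def simulate_ternary(
    binary_sc: TitrationScenario,
    competitor_kd: float,
    competitor_total: float,
    mode: TernaryMode | str = TernaryMode.COMPETITIVE,
    cooperative_factor: float = 1.0,
) -> TitrationSeries:
    """Forward-simulate a ternary titration (protein preincubated with a
    competitor, then titrated).

    ``competitive`` solves the coupled two-ligand one-site mass balance at
    every point, so the titrant's apparent affinity weakens as the
    competitor occupies the site. ``cooperative`` instead multiplies the
    titrant's K_D by ``cooperative_factor`` whenever the competitor is
    present — a phenomenological stand-in for allosteric assistance
    (factor < 1 strengthens binding). With ``competitor_total = 0`` both
    modes reduce bitwise to :func:`simulate_titration`.
    """
    mode = TernaryMode(mode)
    if competitor_total < 0 or competitor_kd <= 0:
        raise GenerationError("competitor_total >= 0 and competitor_kd > 0 required")
    if competitor_total == 0.0:
        return simulate_titration(binary_sc)
    if mode is TernaryMode.COOPERATIVE:
        if cooperative_factor <= 0:
            raise GenerationError("cooperative_factor must be positive")
        sc = replace(binary_sc, k_d=binary_sc.k_d * cooperative_factor)
        return simulate_titration(sc)

    rng = np.random.default_rng(binary_sc.seed)
    points = []
    for l_total in binary_sc.l_totals:
        p_free, _, b_free = solve_competitive_equilibrium(
            binary_sc.p_total,
            competitor_total,
            competitor_kd,
            l_total,
            binary_sc.k_d,
        )
        occ = (
            p_free * b_free / binary_sc.k_d / binary_sc.p_total
            if binary_sc.p_total > 0
            else 0.0
        )
        points.append(_titration_point(binary_sc, l_total, occ, b_free, rng))
    return TitrationSeries(
        fixed_total=binary_sc.p_total,
        points=tuple(points),
        excitation_wavelength=EXCITATION_NM,
        window_center=binary_sc.emission_center,
        window_width=10.0,
        temperature=binary_sc.temperature,
    )


@dataclass(frozen=True)
class CDScenario:
    """Ground truth for synthetic far-/near-UV CD spectra.

    ``near_uv_perturbation`` are the (Tyr, Trp) window band amplitudes in
    mdeg added to the flat near-UV baseline; ``noise_sd`` is additive in
    mdeg on both spectra.
    """

    helix_percent_truth: float = 59.1
    conditions: CDConditions = field(
        default_factory=lambda: CDConditions(
            protein_concentration=1e-6, path_length=0.1
        )
    )
    near_uv_perturbation: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")


def simulate_cd(sc: CDScenario) -> tuple[Spectrum, Spectrum]:
    """Generate (far-UV, near-UV) CD spectra in millidegrees.

    The far-UV spectrum is the classic α-helix template — two negative
    bands with minima at 208 and 222 nm — scaled so the MRE at 208 nm is
    exactly the closed-form inverse of the helix estimator at
    ``helix_percent_truth``, then converted to mdeg with the same MRE
    convention the analysis applies. The near-UV spectrum is a flat
    baseline plus Gaussian perturbations centered in the Tyr (281 nm) and
    Trp (295 nm) windows.
    """
    rng = np.random.default_rng(sc.seed)

    far_grid = np.arange(200.0, 260.0 + 0.25, 0.5)
    band_208 = np.exp(-((far_grid - 208.0) ** 2) / (2.0 * 5.5**2))
    band_222 = np.exp(-((far_grid - 222.0) ** 2) / (2.0 * 7.0**2))
    template = band_208 + 0.95 * band_222
    template = template / template[np.argmin(np.abs(far_grid - 208.0))]
    mre_208 = mre_at_helix_percent(sc.helix_percent_truth)
    theta_far = theta_from_mre(mre_208, sc.conditions) * template
    if sc.noise_sd > 0:
        theta_far = theta_far + sc.noise_sd * rng.standard_normal(far_grid.size)
    far_uv = Spectrum(
        axis=far_grid,
        signal=theta_far,
        kind=SpectrumKind.CD_MILLIDEGREES,
        label=f"far-UV, helix {sc.helix_percent_truth:.1f}%",
    )

    near_grid = np.arange(250.0, 340.0 + 0.25, 0.5)
    tyr_amp, trp_amp = sc.near_uv_perturbation
    theta_near = tyr_amp * np.exp(
        -((near_grid - 281.0) ** 2) / (2.0 * 2.5**2)
    ) + trp_amp * np.exp(-((near_grid - 295.0) ** 2) / (2.0 * 3.5**2))
    if sc.noise_sd > 0:
        theta_near = theta_near + sc.noise_sd * rng.standard_normal(near_grid.size)
    near_uv = Spectrum(
        axis=near_grid,
        signal=theta_near,
        kind=SpectrumKind.CD_MILLIDEGREES,
        label="near-UV",
    )
    return far_uv, near_uv


#: Free-HSA amide I component bands (center cm⁻¹, sigma cm⁻¹, amplitude),
#: in decreasing intensity order: random coil, α-helix, β-turn.
FREE_HSA_AMIDE_I = (
    AmideBand(center=1651.0, width=3.4, amplitude=1.00),
    AmideBand(center=1660.0, width=3.4, amplitude=0.72),
    AmideBand(center=1667.0, width=3.0, amplitude=0.45),
)

#: Typical amide II band of free HSA.
FREE_HSA_AMIDE_II = AmideBand(center=1548.0, width=10.0, amplitude=0.8)


def simulate_ir(
    bands: Sequence[AmideBand],
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """Sum-of-Gaussians IR spectrum on ``grid`` (default 1450–1750 cm⁻¹ at
    0.5 cm⁻¹) plus additive Gaussian noise. The input band list is the
    ground truth for recovery tests."""
    if not bands:
        raise GenerationError("band list must not be empty")
    if noise_sd < 0:
        raise GenerationError("noise_sd must be >= 0")
    if grid is None:
        grid = np.arange(1450.0, 1750.0 + 0.25, 0.5)
    grid = np.asarray(grid, dtype=float)
    signal = np.zeros_like(grid)
    for band in bands:
        signal = signal + band.profile(grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + noise_sd * rng.standard_normal(grid.size)
    return Spectrum(
        axis=grid, signal=signal, kind=SpectrumKind.IR_ABSORBANCE, label="synthetic IR"
    )
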