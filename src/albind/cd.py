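"""Circular dichroism processing: MRE, α-helix content, near-UV differences.

Far-UV CD of an α-helical protein shows two negative minima at 208 and
222 nm. The ellipticity θ (millidegrees) is first normalized to the mean
residue ellipticity

    MRE = θ / (10 · n · c · l)        [deg·cm²·dmol⁻¹]

with n the number of residues (585 for HSA), c the molar protein
concentration (mol/L) and l the cuvette path length (cm). The α-helix
fraction is then estimated from MRE at 208 nm against the standardized
end-member values MRE_α = 33,000 (pure helix) and MRE_β = 4,000 (pure
β-sheet):

    α-helix % = −(MRE₂₀₈ − MRE_β) / (MRE_α − MRE_β) × 100

The equation is applied sign-for-sign as written; note that with these
end-member magnitudes it reaches 100% at MRE₂₀₈ = −25,000 (not −33,000),
so estimates outside [0, 100] are possible for strongly helical signals
and are reported with a plausibility warning rather than clipped.

Near-UV CD (250–340 nm) reports on tertiary structure around the aromatic
residues; spectra are brought to a common baseline by subtracting the
ligand-free protein spectrum and summarized as the mean signed change in
the tyrosine (275–287 nm) and tryptophan (285–305 nm) windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from albind.errors import DataError, InvariantError, WindowRangeError
from albind.spectra import Spectrum, SpectrumKind, subtract_background

#: Standardized MRE of a protein with 100% α-helix content.
MRE_ALPHA = 33000.0
#: Standardized MRE of a protein with 100% β-sheet content.
MRE_BETA = 4000.0

#: HSA residue count.
HSA_N_RESIDUES = 585

#: Aromatic-residue windows of the near-UV CD spectrum (closed, nm).
TYR_WINDOW = (275.0, 287.0)
TRP_WINDOW = (285.0, 305.0)

#: Wavelength at which the helix estimate samples the far-UV spectrum.
HELIX_WAVELENGTH = 208.0


@dataclass(frozen=True)
class CDConditions:
    """Sample conditions entering the MRE normalization."""

    protein_concentration: float  # mol/L
    path_length: float  # cm
    n_residues: int = HSA_N_RESIDUES

    def __post_init__(self) -> None:
        if not (
            self.protein_concentration > 0
            and self.path_length > 0
            and self.n_residues > 0
        ):
            raise InvariantError("CD conditions must all be positive")


class HelixEstimate(NamedTuple):
    """MRE at 208 nm and the α-helix percentage derived from it."""

    mre_208: float
    helix_percent: float


def mre(theta: float, conditions: CDConditions) -> float:
    """Mean residue ellipticity from raw ellipticity θ in millidegrees."""
    return theta / (
        10.0
        * conditions.n_residues
        * conditions.protein_concentration
        * conditions.path_length
    )


def theta_from_mre(mre_value: float, conditions: CDConditions) -> float:
    """Raw ellipticity (mdeg) giving the stated MRE — inverse of :func:`mre`."""
    return mre_value * (
        10.0
        * conditions.n_residues
        * conditions.protein_concentration
        * conditions.path_length
    )


def helix_percent(mre_208: float) -> float:
    """α-helix percentage from MRE at 208 nm (see module docstring)."""
    value = -(mre_208 - MRE_BETA) / (MRE_ALPHA - MRE_BETA) * 100.0
    if not 0.0 <= value <= 100.0:
        warnings.warn(
            f"helix estimate {value:.1f}% outside [0, 100]; the end-member "
            "calibration saturates near MRE_208 = -25,000"
        )
    return value


def mre_at_helix_percent(percent: float) -> float:
    """MRE at 208 nm for a given α-helix percentage — exact closed-form
    inverse of :func:`helix_percent`."""
    return MRE_BETA - percent / 100.0 * (MRE_ALPHA - MRE_BETA)


def mre_at_full_helix() -> float:
    """MRE₂₀₈ at which the estimator reads exactly 100% helix."""
    return mre_at_helix_percent(100.0)


def _sample_at(s: Spectrum, wavelength: float) -> float:
    if wavelength < s.axis[0] or wavelength > s.axis[-1]:
        raise WindowRangeError(
            f"spectrum [{s.axis[0]}, {s.axis[-1]}] nm does not cover "
            f"{wavelength} nm"
        )
    return float(s.signal[np.argmin(np.abs(s.axis - wavelength))])


def helix_estimate(s: Spectrum, conditions: CDConditions) -> HelixEstimate:
    """Helix content of one far-UV spectrum (θ in mdeg, nearest grid point
    to 208 nm)."""
    if s.kind is not SpectrumKind.CD_MILLIDEGREES:
        raise DataError("helix estimation expects a cd_millidegrees spectrum")
    mre_208 = mre(_sample_at(s, HELIX_WAVELENGTH), conditions)
    return HelixEstimate(mre_208=mre_208, helix_percent=helix_percent(mre_208))


def helix_table(
    series: Sequence[tuple[float, Spectrum | Sequence[Spectrum]]],
    conditions: CDConditions,
) -> pd.DataFrame:
    """Per-molar-ratio helix table, replicate mean ± SD when triplicates
    are supplied.

    Parameters
    ----------
    series
        Ordered ``(molar_ratio, spectrum_or_replicates)`` pairs; a single
        Spectrum gives a row without SD, a sequence of replicate spectra
        gives mean ± SD (ddof=1).

    Returns
    -------
    DataFrame with columns ``molar_ratio``, ``mre_208``, ``helix_percent``,
    ``helix_sd`` (NaN for single spectra), ``n_replicates``.
    """
    rows = []
    for ratio, entry in series:
        replicates = [entry] if isinstance(entry, Spectrum) else list(entry)
        estimates = [helix_estimate(s, conditions) for s in replicates]
        helices = np.array([e.helix_percent for e in estimates])
        rows.append(
            {
                "molar_ratio": ratio,
                "mre_208": float(np.mean([e.mre_208 for e in estimates])),
                "helix_percent": float(np.mean(helices)),
                "helix_sd": float(np.std(helices, ddof=1))
                if len(helices) > 1
                else float("nan"),
                "n_replicates": len(helices),
            }
        )
    return pd.DataFrame(rows)


def near_uv_difference(sample: Spectrum, reference_hsa: Spectrum) -> Spectrum:
    """Difference near-UV spectrum: sample minus ligand-free protein.

    Both spectra must lie within 250–340 nm on identical grids.
    """
    for s, name in ((sample, "sample"), (reference_hsa, "reference")):
        if s.axis[0] < 250.0 or s.axis[-1] > 340.0:
            raise WindowRangeError(
                f"{name} spectrum [{s.axis[0]}, {s.axis[-1]}] nm outside the "
                "near-UV range 250-340 nm"
            )
    return subtract_background(sample, reference_hsa)


class NearUVReport(NamedTuple):
    """Mean signed change of a near-UV difference spectrum in the aromatic
    windows (Tyr 275–287 nm, Trp 285–305 nm; closed intervals, the 285–287
    overlap counts in both)."""

    tyr_mean: float
    trp_mean: float


def near_uv_window_report(difference: Spectrum) -> NearUVReport:
    """Summarize a near-UV difference spectrum over the Tyr/Trp windows."""

    def window_mean(lo: float, hi: float) -> float:
        mask = (difference.axis >= lo) & (difference.axis <= hi)
        if not np.any(mask):
            raise WindowRangeError(
                f"difference spectrum has no samples in [{lo}, {hi}] nm"
            )
        return float(np.mean(difference.signal[mask]))

    return NearUVReport(
        tyr_mean=window_mean(*TYR_WINDOW),
        trp_mean=window_mean(*TRP_WINDOW),
    )
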