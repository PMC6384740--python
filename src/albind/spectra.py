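"""Core spectral types, delimited-text I/O, and signal corrections.

A :class:`Spectrum` is one measured curve on a strictly increasing axis
grid (nm for optical spectra, cm⁻¹ for IR). Fluorescence titrations are
ordered collections of emission spectra (:class:`TitrationSeries`) with the
per-point absorbances needed for the multiplicative inner-filter correction

    F_cor = F_obs · 10^((A_ex + A_em) / 2)

where A_ex and A_em are the absorbances of the cuvette contents at the
excitation wavelength and at the emission-window center. Window-integrated
intensities (a 10 nm section around the emission maximum, samples summed)
are the quantity every downstream stage consumes.

No operation here resamples or interpolates: spectra with different grids
cannot be combined and raise :class:`~albind.errors.GridMismatchError`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from albind.errors import (
    DataError,
    GridMismatchError,
    InvariantError,
    SpectrumParseError,
    WindowRangeError,
)


class SpectrumKind(str, enum.Enum):
    """What physical quantity the signal column holds."""

    EMISSION = "emission"
    ABSORBANCE = "absorbance"
    CD_MILLIDEGREES = "cd_millidegrees"
    IR_ABSORBANCE = "ir_absorbance"


@dataclass(frozen=True)
class Spectrum:
    """One measured curve: axis grid, signal, kind and conditions.

    Parameters
    ----------
    axis : array-like
        Strictly increasing grid, nm (optical) or cm⁻¹ (IR), length ≥ 2.
    signal : array-like
        Signal values, same length as ``axis``.
    kind : SpectrumKind
        Physical meaning of the signal column.
    temperature : float
        Sample temperature in kelvin (> 0).
    ph : float
        Buffer pH.
    label : str
        Free-text sample description.
    """

    axis: np.ndarray
    signal: np.ndarray
    kind: SpectrumKind
    temperature: float = 298.15
    ph: float = 7.4
    label: str = ""

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "kind", SpectrumKind(self.kind))
        if axis.ndim != 1 or signal.ndim != 1:
            raise InvariantError("axis and signal must be one-dimensional")
        if axis.size < 2:
            raise InvariantError("spectrum needs at least 2 samples")
        if axis.size != signal.size:
            raise InvariantError(
                f"axis length {axis.size} != signal length {signal.size}"
            )
        if not np.all(np.isfinite(axis)) or not np.all(np.isfinite(signal)):
            raise InvariantError("axis and signal must be finite")
        if not np.all(np.diff(axis) > 0):
            raise InvariantError("axis must be strictly increasing")
        if not self.temperature > 0:
            raise InvariantError("temperature must be positive (kelvin)")

    def __len__(self) -> int:
        return int(self.axis.size)

    def with_signal(self, signal: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with a new signal, metadata retained."""
        return replace(self, signal=np.asarray(signal, dtype=float))


@dataclass(frozen=True)
class TitrationPoint:
    """One titrant addition: the emission spectrum plus its absorbances.

    ``a_ex``/``a_em`` are the absorbances of the mixture at the excitation
    wavelength and the emission-window center, used for the inner-filter
    correction. They are recorded per point because the absorbing titrant
    concentration changes at every addition.
    """

    titrant_total: float
    spectrum: Spectrum
    a_ex: float = 0.0
    a_em: float = 0.0

    def __post_init__(self) -> None:
        if self.titrant_total < 0:
            raise InvariantError("titrant_total must be >= 0")
        if self.a_ex < 0 or self.a_em < 0:
            raise InvariantError("absorbances must be >= 0")
        if self.spectrum.kind is not SpectrumKind.EMISSION:
            raise InvariantError("titration point spectrum must be emission kind")


@dataclass(frozen=True)
class TitrationSeries:
    """Ordered titration of a fixed component with increasing titrant.

    The first point must be the titrant-free reference (the F₀ source).
    ``fixed_total`` is the concentration of the non-titrated component
    (the protein in a quenching experiment). The emission window
    (``window_center`` ± ``window_width``/2) defines the integrated
    intensity used for all ratios.
    """

    fixed_total: float
    points: tuple[TitrationPoint, ...]
    excitation_wavelength: float
    window_center: float
    window_width: float = 10.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if self.fixed_total < 0:
            raise InvariantError("fixed_total must be >= 0")
        if len(self.points) < 2:
            raise InvariantError("titration series needs at least 2 points")
        totals = np.array([p.titrant_total for p in self.points])
        if totals[0] != 0.0:
            raise InvariantError("first titration point must have titrant_total = 0")
        if not np.all(np.diff(totals) > 0):
            raise InvariantError("titrant_total must be strictly increasing")
        if self.window_width < 0:
            raise InvariantError("window_width must be >= 0")
        if not self.temperature > 0:
            raise InvariantError("temperature must be positive (kelvin)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def titrant_totals(self) -> np.ndarray:
        return np.array([p.titrant_total for p in self.points])


@dataclass(frozen=True)
class CorrectionSettings:
    """Which signal corrections to apply before forming intensity ratios."""

    apply_background: bool = True
    apply_inner_filter: bool = True


# ---------------------------------------------------------------------------
# delimited-text I/O
#
# Dialect: comma-separated, '.' decimal, optional '#' comment lines, UTF-8,
# one optional non-numeric header row. Chosen for an unambiguous round-trip.


def read_spectrum(path: str | Path, kind: SpectrumKind | str, **metadata) -> Spectrum:
    """Read a two-column delimited-text spectrum.

    Parameters
    ----------
    path : path-like
        CSV file: axis,signal per row; '#' lines are comments; a single
        non-numeric header row is permitted and skipped.
    kind : SpectrumKind
        Kind to stamp on the returned spectrum.
    **metadata
        Extra ``Spectrum`` fields (temperature, ph, label).

    Raises
    ------
    SpectrumParseError
        Non-numeric cells or wrong column counts, naming the line number.
    InvariantError
        Parsed columns violate the Spectrum invariants (e.g. a duplicated
        axis value); inputs are rejected, never repaired.
    """
    path = Path(path)
    axis: list[float] = []
    signal: list[float] = []
    header_allowed = True
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = [c.strip() for c in line.split(",")]
            if len(cells) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected 2 comma-separated columns, "
                    f"got {len(cells)}"
                )
            try:
                x, y = float(cells[0]), float(cells[1])
            except ValueError:
                if header_allowed:
                    header_allowed = False
                    continue
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric cell in {cells!r}"
                ) from None
            header_allowed = False
            axis.append(x)
            signal.append(y)
    if len(axis) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    label = metadata.pop("label", path.stem)
    return Spectrum(
        axis=np.array(axis), signal=np.array(signal), kind=SpectrumKind(kind),
        label=label, **metadata,
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum in the dialect :func:`read_spectrum` reads.

    Values are written with ``repr`` so the read→write→read round trip is
    bit-identical for double precision data.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write(f"# kind: {spectrum.kind.value}\n")
        if spectrum.label:
            handle.write(f"# label: {spectrum.label}\n")
        handle.write("axis,signal\n")
        for x, y in zip(spectrum.axis, spectrum.signal):
            handle.write(f"{float(x)!r},{float(y)!r}\n")


# ---------------------------------------------------------------------------
# corrections and window operations


def subtract_background(sample: Spectrum, buffer: Spectrum) -> Spectrum:
    """Pointwise buffer-background subtraction.

    Grids and kinds must match exactly; no interpolation is attempted.
    The sample's metadata is retained.
    """
    if sample.kind is not buffer.kind:
        raise GridMismatchError(
            f"kind mismatch: {sample.kind.value} vs {buffer.kind.value}"
        )
    if sample.axis.shape != buffer.axis.shape or not np.array_equal(
        sample.axis, buffer.axis
    ):
        raise GridMismatchError("sample and buffer axis grids differ")
    return sample.with_signal(sample.signal - buffer.signal)


def inner_filter_correct(f_obs: float, a_ex: float, a_em: float) -> float:
    """Correct an observed fluorescence intensity for the inner-filter effect.

    Returns ``f_obs · 10^((a_ex + a_em)/2)``: the attenuation of excitation
    light and re-absorption of emitted light by absorbing species is undone
    multiplicatively from the absorbances at the excitation wavelength
    (``a_ex``) and the emission wavelength (``a_em``).
    """
    if a_ex < 0 or a_em < 0:
        raise DataError("absorbances must be non-negative")
    if f_obs < 0:
        raise DataError("observed intensity must be non-negative")
    return f_obs * 10.0 ** ((a_ex + a_em) / 2.0)


def integrate_window(s: Spectrum, center: float, width: float) -> float:
    """Sum the signal samples inside a closed axis window.

    The window is ``[center − width/2, center + width/2]``, inclusive on
    both endpoints; samples are summed, not trapezoid-integrated, matching
    the practice of adding up the intensities of a fixed section around the
    emission maximum to suppress noise. ``width = 0`` degenerates to the
    single sample nearest ``center``.
    """
    lo, hi = center - width / 2.0, center + width / 2.0
    if lo < s.axis[0] or hi > s.axis[-1]:
        raise WindowRangeError(
            f"window [{lo}, {hi}] outside axis range "
            f"[{s.axis[0]}, {s.axis[-1]}]"
        )
    if width == 0.0:
        return float(s.signal[np.argmin(np.abs(s.axis - center))])
    mask = (s.axis >= lo) & (s.axis <= hi)
    return float(np.sum(s.signal[mask]))


class PeakResult(NamedTuple):
    """Location of the global signal maximum; ``ambiguous`` is set when the
    maximum is attained at more than one sample (including a completely
    flat signal)."""

    position: float
    ambiguous: bool


def peak_position(s: Spectrum) -> PeakResult:
    """Axis position of the global emission maximum.

    Ties break to the smallest axis value so that a blue shift (shortening
    emission maximum upon complex formation) is reported deterministically;
    any tie is flagged ambiguous.
    """
    if s.kind is not SpectrumKind.EMISSION:
        raise InvariantError("peak_position expects an emission spectrum")
    peak = np.max(s.signal)
    hits = np.flatnonzero(s.signal == peak)
    return PeakResult(position=float(s.axis[hits[0]]), ambiguous=hits.size > 1)


class OverlapResult(NamedTuple):
    """FRET-style spectral overlap score with the common-range bounds."""

    score: float
    lower: float
    upper: float


def spectral_overlap(
    donor_emission: Spectrum, acceptor_absorbance: Spectrum
) -> OverlapResult:
    """Overlap integral between donor emission and acceptor absorption.

    The donor spectrum is normalized internally to unit area (trapezoid over
    its full range) and ``∫ F_D(λ)·A(λ) dλ`` is evaluated trapezoidally over
    the common axis range. A large score means strong resonance energy
    transfer is geometrically possible (the prerequisite for FRET between a
    Trp donor and a bound-ligand acceptor). Disjoint ranges give a zero
    score with a warning rather than an error.

    Grids must agree on the common range; no interpolation is performed.
    """
    lo = max(donor_emission.axis[0], acceptor_absorbance.axis[0])
    hi = min(donor_emission.axis[-1], acceptor_absorbance.axis[-1])
    if lo >= hi:
        warnings.warn("donor and acceptor axis ranges are disjoint; overlap = 0")
        return OverlapResult(score=0.0, lower=float(lo), upper=float(hi))
    area = np.trapezoid(donor_emission.signal, donor_emission.axis)
    if area <= 0:
        raise DataError("donor emission has non-positive total area")
    d_mask = (donor_emission.axis >= lo) & (donor_emission.axis <= hi)
    a_mask = (acceptor_absorbance.axis >= lo) & (acceptor_absorbance.axis <= hi)
    dx = donor_emission.axis[d_mask]
    ax = acceptor_absorbance.axis[a_mask]
    if dx.shape != ax.shape or not np.array_equal(dx, ax):
        raise GridMismatchError("donor and acceptor grids differ on common range")
    density = donor_emission.signal[d_mask] / area
    score = float(np.trapezoid(density * acceptor_absorbance.signal[a_mask], dx))
    return OverlapResult(score=score, lower=float(lo), upper=float(hi))
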