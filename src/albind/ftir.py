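"""FT-IR amide-band location and Gaussian amide-I decomposition.

Protein IR spectra carry the amide I band near 1650 cm⁻¹ (C=O stretching)
and the amide II band near 1545 cm⁻¹ (C–N stretch coupled with N–H
bending), both sensitive to secondary structure. The amide I envelope is
a sum of overlapping component bands whose positions index structure
types: ~1645–1652 cm⁻¹ random coil, ~1652–1662 cm⁻¹ α-helix,
~1663–1672 cm⁻¹ β-turn.

Decomposition here is a second-derivative-initialized sum-of-Gaussians
least-squares fit of the 1600–1700 cm⁻¹ region: component candidates are
the deepest minima of a lightly smoothed second derivative of the
envelope (overlapped bands that are invisible as shoulders still produce
distinct second-derivative minima), and the Gaussian centers, widths and
amplitudes are then refined jointly. Fitted bands are returned in
decreasing amplitude order and labelled through configurable wavenumber
interval rules — band assignment in this region is convention-dependent
(published assignments overlap), so the rules travel with the output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from lmfit.models import GaussianModel
from scipy.signal import argrelmin, savgol_filter

from albind.errors import DetectionError, FitError, InvariantError
from albind.spectra import Spectrum, SpectrumKind

AMIDE_I_WINDOW = (1600.0, 1700.0)
AMIDE_II_WINDOW = (1500.0, 1600.0)


class BandLabel(str, enum.Enum):
    ALPHA_HELIX = "alpha_helix"
    RANDOM_COIL = "random_coil"
    BETA_TURN = "beta_turn"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AmideBand:
    """One fitted Gaussian component of the amide I envelope.

    ``width`` is the Gaussian sigma in cm⁻¹; ``amplitude`` the peak height
    in absorbance units.
    """

    center: float
    width: float
    amplitude: float
    label: BandLabel = BandLabel.UNASSIGNED

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise InvariantError("band width must be positive")
        if not self.amplitude > 0:
            raise InvariantError("band amplitude must be positive")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Gaussian absorbance profile of this band on ``grid``."""
        return self.amplitude * np.exp(
            -((np.asarray(grid) - self.center) ** 2) / (2.0 * self.width**2)
        )


@dataclass(frozen=True)
class AssignmentRules:
    """Ordered closed wavenumber intervals mapping centers to labels.

    Intervals must not overlap; boundaries use a closed-left convention
    (a center equal to an interval's lower bound belongs to it). Full
    coverage of the amide I region is not required — unmatched centers
    stay unassigned.
    """

    intervals: tuple[tuple[float, float, BandLabel], ...] = (
        (1645.0, 1652.0, BandLabel.RANDOM_COIL),
        (1652.01, 1662.0, BandLabel.ALPHA_HELIX),
        (1663.0, 1672.0, BandLabel.BETA_TURN),
    )

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.intervals, key=lambda iv: iv[0]))
        object.__setattr__(self, "intervals", ordered)
        for (_, hi, _), (lo2, _, _) in zip(ordered, ordered[1:]):
            if lo2 <= hi:
                raise InvariantError("assignment intervals must not overlap")
        for lo, hi, _ in ordered:
            if hi < lo:
                raise InvariantError("interval upper bound below lower bound")

    def label_for(self, center: float) -> BandLabel:
        c = round(center)
        for lo, hi, label in self.intervals:
            if lo <= c <= hi:
                return label
        return BandLabel.UNASSIGNED


def _window_slice(s: Spectrum, lo: float, hi: float) -> np.ndarray:
    return (s.axis >= lo) & (s.axis <= hi)


def _local_max_in(s: Spectrum, lo: float, hi: float, name: str) -> float:
    mask = _window_slice(s, lo, hi)
    if np.count_nonzero(mask) < 3:
        raise DetectionError(f"too few samples in the {name} window [{lo}, {hi}]")
    x, y = s.axis[mask], s.signal[mask]
    i = int(np.argmax(y))
    # require an interior maximum that actually rises above its surroundings
    if i in (0, len(y) - 1) or (y[i] <= y[0] and y[i] <= y[-1]) or np.ptp(y) == 0:
        raise DetectionError(f"no local maximum inside the {name} window")
    return float(x[i])


def locate_amide_maxima(s: Spectrum) -> tuple[float, float]:
    """Locate the amide I and amide II band maxima.

    Searches 1600–1700 cm⁻¹ (amide I) and 1500–1600 cm⁻¹ (amide II) of an
    IR absorbance spectrum; a window without an interior maximum raises
    ``DetectionError``.
    """
    if s.kind is not SpectrumKind.IR_ABSORBANCE:
        raise InvariantError("locate_amide_maxima expects an ir_absorbance spectrum")
    if s.axis[0] > AMIDE_II_WINDOW[0] or s.axis[-1] < AMIDE_I_WINDOW[1]:
        raise InvariantError("spectrum must cover 1500-1700 cm⁻¹")
    amide_i = _local_max_in(s, *AMIDE_I_WINDOW, name="amide I")
    amide_ii = _local_max_in(s, *AMIDE_II_WINDOW, name="amide II")
    return amide_i, amide_ii


def _second_derivative_minima(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Candidate band centers: minima of the smoothed second derivative,
    ordered by depth (deepest first)."""
    window = min(len(y) - (1 - len(y) % 2), max(7, 2 * (len(y) // 50) + 1))
    d2 = savgol_filter(y, window_length=window, polyorder=3, deriv=2)
    idx = argrelmin(d2, order=2)[0]
    idx = idx[d2[idx] < 0]
    if idx.size == 0:
        return np.array([])
    order = np.argsort(d2[idx])
    return x[idx[order]]


def fit_amide_i_bands(
    s: Spectrum, n_bands: int, seed: int = 0
) -> list[AmideBand]:
    """Decompose the amide I region into ``n_bands`` Gaussian components.

    Initial centers are the ``n_bands`` deepest second-derivative minima;
    amplitudes start at the envelope height at each center and sigmas at
    4 cm⁻¹. The joint least-squares refinement constrains centers to the
    1600–1700 cm⁻¹ region and widths to (0, 30] cm⁻¹. Bands are returned
    sorted by decreasing amplitude; ``seed`` is recorded for provenance
    (the fit itself is deterministic) and used only to break exact
    amplitude ties reproducibly.

    Raises ``FitError`` on non-convergence and ``DetectionError`` when the
    second derivative offers fewer candidate minima than ``n_bands``.
    """
    if not 1 <= n_bands <= 6:
        raise InvariantError("n_bands must be between 1 and 6")
    if s.kind is not SpectrumKind.IR_ABSORBANCE:
        raise InvariantError("fit_amide_i_bands expects an ir_absorbance spectrum")
    mask = _window_slice(s, *AMIDE_I_WINDOW)
    if np.count_nonzero(mask) < 3 * n_bands:
        raise InvariantError("amide I region poorly sampled for this n_bands")
    x, y = s.axis[mask], s.signal[mask]

    centers = _second_derivative_minima(x, y)
    if centers.size < n_bands:
        raise DetectionError(
            f"only {centers.size} second-derivative minima for {n_bands} bands"
        )
    centers = np.sort(centers[:n_bands])

    model = None
    params = None
    for i, c0 in enumerate(centers):
        g = GaussianModel(prefix=f"g{i}_")
        p = g.make_params()
        a0 = max(float(y[np.argmin(np.abs(x - c0))]), 1e-6)
        sigma0 = 4.0
        p[f"g{i}_center"].set(value=c0, min=AMIDE_I_WINDOW[0], max=AMIDE_I_WINDOW[1])
        p[f"g{i}_sigma"].set(value=sigma0, min=1e-3, max=30.0)
        # lmfit amplitude is the area; height = amplitude/(sigma*sqrt(2π))
        p[f"g{i}_amplitude"].set(
            value=a0 * sigma0 * np.sqrt(2.0 * np.pi), min=1e-12
        )
        model = g if model is None else model + g
        params = p if params is None else params.update(p) or params
    result = model.fit(y, params, x=x, fit_kws={"xtol": 1e-15, "ftol": 1e-15})
    if not result.success:
        raise FitError(f"amide I decomposition did not converge: {result.message}")

    bands = []
    for i in range(n_bands):
        sigma = float(result.params[f"g{i}_sigma"].value)
        area = float(result.params[f"g{i}_amplitude"].value)
        height = area / (sigma * np.sqrt(2.0 * np.pi))
        bands.append(
            AmideBand(
                center=float(result.params[f"g{i}_center"].value),
                width=sigma,
                amplitude=height,
            )
        )
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(0, 1e-15, size=len(bands))  # reproducible tie-break
    order = sorted(
        range(len(bands)), key=lambda i: (-bands[i].amplitude, jitter[i])
    )
    return [bands[i] for i in order]


def assign_bands(
    bands: list[AmideBand], rules: AssignmentRules | None = None
) -> list[AmideBand]:
    """Label fitted bands by the interval containing their rounded center.

    Idempotent: relabelling an already-labelled list gives the same result.
    """
    if rules is None:
        rules = AssignmentRules()
    return [
        AmideBand(
            center=b.center,
            width=b.width,
            amplitude=b.amplitude,
            label=rules.label_for(b.center),
        )
        for b in bands
    ]
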