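"""End-to-end orchestration: manifests, run configs, reports.

A titration lives on disk as a YAML *series manifest* next to its per-point
spectrum CSVs:

.. code-block:: yaml

    fixed_total: 5.0e-06        # mol/L, non-titrated component
    temperature: 310.15         # K
    excitation_wavelength: 295.0
    window_center: 347.0        # nm
    window_width: 10.0
    buffer: buffer.csv          # optional background spectrum
    points:
      - {file: point_00.csv, titrant_total: 0.0, a_ex: 0.0, a_em: 0.0}
      - {file: point_01.csv, titrant_total: 1.95e-06, a_ex: 0.023, a_em: 0.006}

``run_binary_analysis`` composes correction → quenching → binding for one
manifest; ``run_ternary_comparison`` adds the binary-vs-ternary affinity
call. Reports are plain dicts (JSON-serializable, no timestamps) embedding
the settings and a hash of the resolved configuration, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from albind.binding import (
    BindingFit,
    compare_systems,
    fit_binding,
    system_from_curve,
)
from albind.errors import ConfigError
from albind.quenching import (
    build_quenching_curve,
    classify_mechanism,
    stern_volmer_fit,
)
from albind.spectra import (
    CorrectionSettings,
    Spectrum,
    SpectrumKind,
    TitrationPoint,
    TitrationSeries,
    peak_position,
    read_spectrum,
    subtract_background,
    write_spectrum,
)


@dataclass(frozen=True)
class RunConfig:
    """Settings for one pipeline run.

    ``manifest`` (and ``ternary_manifest`` for comparisons) point at series
    manifests; fit settings mirror the module defaults. The seed is
    recorded in every report even when no stochastic step runs.
    """

    manifest: str
    ternary_manifest: str | None = None
    apply_background: bool = True
    apply_inner_filter: bool = True
    sv_n_points: int = 7
    mechanism_tolerance: float = 0.05
    compare_threshold: float = 0.10
    seed: int = 0
    output_dir: str = "results"

    @property
    def corrections(self) -> CorrectionSettings:
        return CorrectionSettings(
            apply_background=self.apply_background,
            apply_inner_filter=self.apply_inner_filter,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "manifest" not in raw:
            raise ConfigError(f"{path}: missing required key 'manifest'")
        return cls(**raw)


# ---------------------------------------------------------------------------
# manifest I/O


_REQUIRED_SERIES_KEYS = (
    "fixed_total",
    "temperature",
    "excitation_wavelength",
    "window_center",
    "points",
)
_REQUIRED_POINT_KEYS = ("file", "titrant_total", "a_ex", "a_em")


def load_series_manifest(
    path: str | Path, corrections: CorrectionSettings | None = None
) -> TitrationSeries:
    """Load a titration series from a YAML manifest.

    Spectrum paths are resolved relative to the manifest. When a ``buffer``
    entry is present and background correction is enabled, the buffer
    spectrum is subtracted from every point at load time (grids must match
    exactly).
    """
    if corrections is None:
        corrections = CorrectionSettings()
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: manifest must be a mapping")
    for key in _REQUIRED_SERIES_KEYS:
        if key not in raw:
            raise ConfigError(f"{path}: missing manifest key '{key}'")
    base = path.parent
    buffer = None
    if corrections.apply_background and raw.get("buffer"):
        buffer = read_spectrum(base / raw["buffer"], SpectrumKind.EMISSION)
    points = []
    for i, entry in enumerate(raw["points"]):
        for key in _REQUIRED_POINT_KEYS:
            if key not in entry:
                raise ConfigError(f"{path}: point {i} missing key '{key}'")
        spectrum = read_spectrum(
            base / entry["file"],
            SpectrumKind.EMISSION,
            temperature=float(raw["temperature"]),
        )
        if buffer is not None:
            spectrum = subtract_background(spectrum, buffer)
        points.append(
            TitrationPoint(
                titrant_total=float(entry["titrant_total"]),
                spectrum=spectrum,
                a_ex=float(entry["a_ex"]),
                a_em=float(entry["a_em"]),
            )
        )
    return TitrationSeries(
        fixed_total=float(raw["fixed_total"]),
        points=tuple(points),
        excitation_wavelength=float(raw["excitation_wavelength"]),
        window_center=float(raw["window_center"]),
        window_width=float(raw.get("window_width", 10.0)),
        temperature=float(raw["temperature"]),
    )


def write_series_manifest(
    series: TitrationSeries, directory: str | Path, name: str = "series"
) -> Path:
    """Write a series as per-point CSVs plus a manifest; returns the
    manifest path. The output is consumable by :func:`load_series_manifest`
    and round-trips the signal values bit-identically."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, point in enumerate(series.points):
        filename = f"{name}_point_{i:02d}.csv"
        write_spectrum(point.spectrum, directory / filename)
        entries.append(
            {
                "file": filename,
                "titrant_total": float(point.titrant_total),
                "a_ex": float(point.a_ex),
                "a_em": float(point.a_em),
            }
        )
    manifest = {
        "fixed_total": float(series.fixed_total),
        "temperature": float(series.temperature),
        "excitation_wavelength": float(series.excitation_wavelength),
        "window_center": float(series.window_center),
        "window_width": float(series.window_width),
        "points": entries,
    }
    manifest_path = directory / f"{name}.yaml"
    with manifest_path.open("w", encoding="utf-8") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=False)
    return manifest_path


# ---------------------------------------------------------------------------
# report formatting

SIG_DIGITS = 4  # constants (K_q, k_q, K_D)
DELTA_G_DECIMALS = 3  # kJ/mol, matching conventional reporting


def _sig(x: float, digits: int = SIG_DIGITS) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{digits}g}")


def _binding_fit_report(fit: BindingFit) -> dict:
    return {
        "K_D_molar": _sig(fit.K_D),
        "K_D_uM": _sig(fit.K_D * 1e6),
        "K_D_stderr_molar": _sig(fit.K_D_stderr),
        "ratio_at_saturation": _sig(fit.ratio_at_saturation),
        "delta_g_kJ_mol": round(fit.delta_g, DELTA_G_DECIMALS),
        "free_ligand_at_half_molar": _sig(fit.free_ligand_at_half),
        "residual_norm": _sig(fit.residual_norm),
        "saturation_reached": fit.saturation_reached,
        "temperature_K": fit.temperature,
    }


def run_binary_analysis(config: RunConfig) -> dict:
    """Correct → quench → bind for one binary titration manifest.

    Returns (and writes, under ``config.output_dir``) a report with the
    Stern–Volmer table (K_q, k_q, R), the binding table (K_D, ΔG), and a
    peak-shift summary between the first and last titration points.
    """
    series = load_series_manifest(config.manifest, config.corrections)
    curve = build_quenching_curve(series, config.corrections)
    sv = stern_volmer_fit(curve, n_points=config.sv_n_points)
    system = system_from_curve(curve, p_total=series.fixed_total)
    fit = fit_binding(system)

    first_peak = peak_position(series.points[0].spectrum)
    last_peak = peak_position(series.points[-1].spectrum)
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "manifest": str(config.manifest),
        "corrections": asdict(config.corrections),
        "stern_volmer": {
            "K_q_per_molar": _sig(sv.K_q),
            "K_q_stderr_per_molar": _sig(sv.K_q_stderr),
            "k_q_per_molar_s": _sig(sv.k_q),
            "intercept": _sig(sv.intercept),
            "pearson_r": _sig(sv.pearson_r),
            "n_points": min(config.sv_n_points, len(curve)),
            "curvature_flag": sv.curvature_flag,
        },
        "binding": _binding_fit_report(fit),
        "peak_shift_nm": {
            "reference_peak": first_peak.position,
            "final_peak": last_peak.position,
            "shift": last_peak.position - first_peak.position,
            "ambiguous": first_peak.ambiguous or last_peak.ambiguous,
        },
    }
    _write_report(config, report, "binary_analysis")
    return report


def run_ternary_comparison(config: RunConfig) -> dict:
    """Binary and ternary binding fits plus the affinity-change call."""
    if config.ternary_manifest is None:
        raise ConfigError("ternary comparison needs 'ternary_manifest'")
    reports = {}
    fits = {}
    for role, manifest in (
        ("binary", config.manifest),
        ("ternary", config.ternary_manifest),
    ):
        series = load_series_manifest(manifest, config.corrections)
        curve = build_quenching_curve(series, config.corrections)
        system = system_from_curve(curve, p_total=series.fixed_total, label=role)
        fits[role] = fit_binding(system)
        reports[role] = _binding_fit_report(fits[role])
    interaction = compare_systems(
        fits["binary"], fits["ternary"], threshold=config.compare_threshold
    )
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "binary": reports["binary"],
        "ternary": reports["ternary"],
        "interaction": {
            "kd_binary_molar": _sig(interaction.kd_binary),
            "kd_ternary_molar": _sig(interaction.kd_ternary),
            "ratio": _sig(interaction.ratio),
            "call": interaction.call,
            "threshold": config.compare_threshold,
        },
    }
    _write_report(config, report, "ternary_comparison")
    return report


def run_mechanism_analysis(
    manifests: dict[float, str | Path], config: RunConfig
) -> dict:
    """Stern–Volmer fits across temperatures plus the mechanism call.

    ``manifests`` maps temperature (K) to a series manifest measured at it.
    """
    if len(manifests) < 2:
        raise ConfigError("mechanism analysis needs manifests at >= 2 temperatures")
    by_temperature = []
    table = []
    for temperature in sorted(manifests):
        series = load_series_manifest(manifests[temperature], config.corrections)
        curve = build_quenching_curve(series, config.corrections)
        sv = stern_volmer_fit(curve, n_points=config.sv_n_points)
        by_temperature.append((temperature, sv))
        table.append(
            {
                "temperature_K": temperature,
                "K_q_per_molar": _sig(sv.K_q),
                "k_q_per_molar_s": _sig(sv.k_q),
                "pearson_r": _sig(sv.pearson_r),
            }
        )
    call = classify_mechanism(by_temperature, tolerance=config.mechanism_tolerance)
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stern_volmer_by_temperature": table,
        "mechanism": {
            "label": call.label,
            "diffusion_limit_exceeded": call.diffusion_limit_exceeded,
            "relative_trend_per_K": _sig(call.relative_trend),
            "tolerance": config.mechanism_tolerance,
        },
    }
    _write_report(config, report, "mechanism_analysis")
    return report


def _write_report(config: RunConfig, report: dict, stem: str) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / f"{stem}.json").open("w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
    flat = {
        k: v
        for section, payload in report.items()
        if isinstance(payload, dict)
        for k, v in ((f"{section}.{kk}", vv) for kk, vv in payload.items())
    }
    pd.DataFrame([flat]).to_csv(out / f"{stem}.csv", index=False)
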