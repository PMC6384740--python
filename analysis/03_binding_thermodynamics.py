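"""Dissociation constants and Gibbs free energies at 310.15 K.

Refits the 1:1 ligand-depletion binding model to every simulated system
(binary and ternary) at body temperature and tabulates K_D with its
standard error and ΔG = −RT ln(c⁰/K_D). On this synthetic data the fitted
constants should recover the generative values (Q 6.48 μM, AML 183.77 μM;
ternary 2.39 and 192.81 μM) within the noise-driven uncertainty. Writes
results/binding_constants.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from albind.binding import fit_binding, system_from_curve
from albind.pipeline import load_series_manifest
from albind.quenching import build_quenching_curve


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("results/simulated"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    index = json.loads((args.data_dir / "index.json").read_text())

    rows = []
    for key, manifest in index["fluorescence"].items():
        series = load_series_manifest(manifest)
        if series.temperature != 310.15:
            continue
        curve = build_quenching_curve(series)
        fit = fit_binding(system_from_curve(curve, series.fixed_total, label=key))
        rows.append(
            {
                "system": key,
                "K_D_uM": fit.K_D * 1e6,
                "K_D_stderr_uM": fit.K_D_stderr * 1e6,
                "delta_G_kJ_mol": fit.delta_g,
                "ratio_at_saturation": fit.ratio_at_saturation,
                "saturation_reached": fit.saturation_reached,
            }
        )
    table = pd.DataFrame(rows).sort_values("system").reset_index(drop=True)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out_dir / "binding_constants.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(
        "\nweaker binder (larger K_D) binds with less negative dG; "
        "all dG < 0: spontaneous association"
    )


if __name__ == "__main__":
    main()
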