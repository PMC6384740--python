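"""Amide-I Gaussian decomposition of the simulated FT-IR spectra.

Locates the amide I/II maxima, decomposes the amide I region
(1600–1700 cm⁻¹) into three Gaussian components seeded from the smoothed
second derivative, and assigns secondary-structure labels from the default
wavenumber rules. Recovered centers are compared against the generative
truth recorded by the simulation step. Writes results/amide_bands.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from albind.ftir import assign_bands, fit_amide_i_bands, locate_amide_maxima
from albind.spectra import SpectrumKind, read_spectrum


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("results/simulated"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    index = json.loads((args.data_dir / "index.json").read_text())

    rows = []
    for sample, entry in index["ftir"].items():
        spectrum = read_spectrum(entry["file"], SpectrumKind.IR_ABSORBANCE)
        amide_i, amide_ii = locate_amide_maxima(spectrum)
        bands = assign_bands(
            fit_amide_i_bands(spectrum, n_bands=3, seed=args.seed)
        )
        truth = sorted(entry["true_centers"])
        fitted = sorted(b.center for b in bands)
        worst = max(abs(f - t) for f, t in zip(fitted, truth))
        print(
            f"{sample}: amide I max {amide_i:.1f}, amide II max {amide_ii:.1f} "
            f"cm-1; worst center error {worst:.2f} cm-1"
        )
        for rank, band in enumerate(bands, start=1):
            rows.append(
                {
                    "sample": sample,
                    "intensity_rank": rank,
                    "center_cm": band.center,
                    "sigma_cm": band.width,
                    "amplitude": band.amplitude,
                    "label": band.label.value,
                }
            )
    table = pd.DataFrame(rows)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out_dir / "amide_bands.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
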