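"""Generate the synthetic study datasets every later step consumes.

Emulates the experimental design on human serum albumin (HSA): binary
fluorescence titrations of 5 μM HSA with amlodipine (0–500 μM) and
quercetin (0–83.3 μM) at 298.15/303.15/310.15 K, ternary titrations with
the partner drug preincubated, far-UV CD spectra across six ligand:protein
molar ratios, and amide-region FT-IR spectra. Ground-truth parameters are
the published dissociation constants, so the downstream scripts should
recover them. Everything is written as CSV spectra + YAML manifests under
results/simulated/.
"""

import argparse
import json
from pathlib import Path

from albind.pipeline import write_series_manifest
from albind.spectra import write_spectrum
from albind.synth import (
    AML_SERIES_M,
    FREE_HSA_AMIDE_I,
    FREE_HSA_AMIDE_II,
    Q_SERIES_M,
    TEMPERATURES_K,
    CDScenario,
    TitrationScenario,
    simulate_cd,
    simulate_ir,
    simulate_ternary,
    simulate_titration,
)
from albind.ftir import AmideBand

KD_Q, KD_AML = 6.48e-6, 183.77e-6
KD_Q_TERNARY, KD_AML_TERNARY = 2.39e-6, 192.81e-6
NOISE_SD = 0.01

# static quenching weakens on heating: the quercetin complex loosens with
# temperature, while the amlodipine K_q stays flat (static+dynamic mix)
KD_Q_BY_TEMPERATURE = {298.15: 4.2e-6, 303.15: 5.2e-6, 310.15: KD_Q}


def q_scenario(temperature=310.15, k_d=KD_Q, seed=0, noise_sd=NOISE_SD):
    return TitrationScenario(
        l_totals=Q_SERIES_M, k_d=k_d, ratio_at_saturation=0.1,
        blue_shift_at_saturation=6.0, absorbance_per_molar=(12000.0, 3000.0),
        noise_sd=noise_sd, seed=seed, temperature=temperature,
    )


def aml_scenario(temperature=310.15, seed=0, noise_sd=NOISE_SD):
    return TitrationScenario(
        l_totals=AML_SERIES_M, k_d=KD_AML, ratio_at_saturation=0.15,
        absorbance_per_molar=(1000.0, 200.0),
        noise_sd=noise_sd, seed=seed, temperature=temperature,
    )


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=Path("results/simulated"))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    out = args.out_dir
    manifest_index = {}

    # binary titrations across temperatures
    for i, temperature in enumerate(TEMPERATURES_K):
        sc_q = q_scenario(temperature, KD_Q_BY_TEMPERATURE[temperature],
                          seed=args.seed + i)
        sc_a = aml_scenario(temperature, seed=args.seed + 10 + i)
        manifest_index[f"q_binary_{temperature:.2f}K"] = str(
            write_series_manifest(simulate_titration(sc_q), out / "fluorescence",
                                  name=f"q_binary_{i}")
        )
        manifest_index[f"aml_binary_{temperature:.2f}K"] = str(
            write_series_manifest(simulate_titration(sc_a), out / "fluorescence",
                                  name=f"aml_binary_{i}")
        )

    # ternary titrations at 310.15 K: AML preincubation helps quercetin
    # (cooperative), quercetin preincubation leaves amlodipine unchanged
    ternary_q = simulate_ternary(
        q_scenario(seed=args.seed + 20), competitor_kd=KD_AML,
        competitor_total=5e-6, mode="cooperative",
        cooperative_factor=KD_Q_TERNARY / KD_Q,
    )
    ternary_aml = simulate_ternary(
        aml_scenario(seed=args.seed + 21), competitor_kd=KD_Q,
        competitor_total=5e-6, mode="cooperative",
        cooperative_factor=KD_AML_TERNARY / KD_AML,
    )
    manifest_index["q_ternary"] = str(
        write_series_manifest(ternary_q, out / "fluorescence", name="q_ternary")
    )
    manifest_index["aml_ternary"] = str(
        write_series_manifest(ternary_aml, out / "fluorescence",
                              name="aml_ternary")
    )

    # far-UV CD triplicates across molar ratios (helix truths shaped like
    # the published table: maximum near ratio 1, then a slow decline)
    cd_dir = out / "cd"
    cd_dir.mkdir(parents=True, exist_ok=True)
    helix_truths = {
        "aml": {0.0: 59.1, 0.5: 63.6, 1.0: 64.7, 2.0: 64.1, 3.0: 62.5, 4.0: 61.5},
        "q": {0.0: 59.1, 0.5: 63.0, 1.0: 65.4, 2.0: 65.2, 3.0: 66.2, 4.0: 66.3},
    }
    cd_index = {}
    for ligand, truths in helix_truths.items():
        for ratio, truth in truths.items():
            for replicate in range(3):
                sc = CDScenario(
                    helix_percent_truth=truth, noise_sd=0.05,
                    seed=args.seed + 100 + replicate + int(10 * ratio),
                )
                far_uv, _ = simulate_cd(sc)
                name = f"{ligand}_ratio{ratio:g}_rep{replicate}.csv"
                write_spectrum(far_uv, cd_dir / name)
                cd_index.setdefault(ligand, {}).setdefault(str(ratio), []).append(
                    str(cd_dir / name)
                )

    # FT-IR: free HSA and the amlodipine binary system. The AML-bound set
    # keeps the free-HSA centers but the helix component dominates; the
    # quercetin-bound set (1648/1652/1656, 4 cm⁻¹ apart) is too blended
    # for second-derivative component seeding and is out of reach of this
    # decomposition (see docs/methods.md).
    ir_dir = out / "ftir"
    ir_dir.mkdir(parents=True, exist_ok=True)
    band_sets = {
        "free_hsa": list(FREE_HSA_AMIDE_I),
        "aml_hsa": [
            AmideBand(1660.0, 3.4, 1.0),
            AmideBand(1651.0, 3.4, 0.8),
            AmideBand(1667.0, 3.0, 0.5),
        ],
    }
    ir_index = {}
    for name, bands in band_sets.items():
        spectrum = simulate_ir(
            bands + [FREE_HSA_AMIDE_II], noise_sd=0.002, seed=args.seed + 200
        )
        write_spectrum(spectrum, ir_dir / f"{name}.csv")
        ir_index[name] = {
            "file": str(ir_dir / f"{name}.csv"),
            "true_centers": [b.center for b in bands],
        }

    index = {
        "seed": args.seed,
        "fluorescence": manifest_index,
        "cd": cd_index,
        "ftir": ir_index,
    }
    out.mkdir(parents=True, exist_ok=True)
    (out / "index.json").write_text(json.dumps(index, indent=2) + "\n")
    print(f"wrote {sum(len(v) if isinstance(v, dict) else 1 for v in index.values())} "
          f"dataset groups under {out}")
    print(f"index: {out / 'index.json'}")


if __name__ == "__main__":
    main()
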