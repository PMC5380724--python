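"""Recovery of planted low-beta desynchrony through permutation + FDR.

Plants a 50 % band-power drop (13–23 Hz) at three cortical-depth voxels,
runs the full subject chain up to the sign-flip permutation test with
BH-FDR, and additionally calibrates the test's type-I error on null
data. Writes both tables.

Run from the repository root:  python analysis/03_erd_inference.py
"""

import os

import numpy as np
import pandas as pd

from meghubs.studies import erd_inference_study, null_type_i_error_study

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main(seed: int = 1) -> None:
    res = erd_inference_study(n_trials=100, erd_depth=0.5, n_rand=500, seed=seed)
    df = pd.DataFrame(
        {
            "planted_voxel": res["planted_voxels"],
            "rel_power_change": res["rel_power_change"],
            "p_value": res["p_values"],
        }
    )
    os.makedirs(OUT, exist_ok=True)
    path = os.path.join(OUT, "erd_recovery.tsv")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    print(df.to_string(index=False))
    print(
        f"\nAll planted voxels significant after FDR: {res['all_planted_significant']} "
        f"(target band power drop 50 %, recovered "
        f"{np.mean(res['rel_power_change'])*100:.0f} %)."
    )

    frac = null_type_i_error_study(n_datasets=200, n_rand=500, seed=seed)
    with open(os.path.join(OUT, "null_type_i_error.tsv"), "w") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"per_voxel_type_i_error_at_alpha_0.05\t{frac:.4f}\n")
    print(f"Per-voxel type-I error at α=0.05 on null data: {frac:.3f} "
          f"(nominal 0.05).\nWrote {path}")


if __name__ == "__main__":
    main()
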