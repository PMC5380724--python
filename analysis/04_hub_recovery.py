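"""Planted-hub recovery through connectivity + graph analysis.

Each run plants one voxel with three phase couplings (others ≤ 1) in
the left hemisphere, executes the complete subject pipeline, and checks
whether the hub's parcel attains the maximum parcel-level eigenvector
centrality and whether the laterality index classifies the hemisphere
correctly. Writes the per-run table.

Run from the repository root:  python analysis/04_hub_recovery.py
"""

import os

from meghubs.studies import hub_laterality_study

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main(seed: int = 0, n_runs: int = 10) -> None:
    df = hub_laterality_study(n_runs=n_runs, hemisphere="L", seed=seed)
    os.makedirs(OUT, exist_ok=True)
    path = os.path.join(OUT, "hub_recovery.tsv")
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    print(df.to_string(index=False))
    rate = df["hub_recovered"].mean()
    print(
        f"\nHub parcel attained the maximum parcel EVC in {rate*100:.0f}% of "
        f"{n_runs} runs; all-left coupling classified left in "
        f"{(df['category'] == 'left').mean()*100:.0f}% of runs.\nWrote {path}"
    )


if __name__ == "__main__":
    main()
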