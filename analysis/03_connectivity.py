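#!/usr/bin/env python
"""Interregional correlation matrices per group and the network-density
comparison: Fisher-Z ANOVA (genotype x exposure) with Bonferroni
contrasts over the four exposure groups.

Reads results/data/; writes results/connectivity/.
"""

import argparse
from pathlib import Path

import pandas as pd

from fosnet import compare_density, correlation_matrix
from fosnet.io import read_activity_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("results") / "data")
    parser.add_argument("--out-dir", type=Path,
                        default=Path("results") / "connectivity")
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    table, design, warnings = read_activity_table(
        args.data_dir / "counts.tsv", args.data_dir / "design.tsv"
    )
    for w in warnings:
        print("warning:", w)

    corrs = {}
    for genotype, condition in design.groups():
        corr = correlation_matrix(table, design, genotype, condition)
        corrs[(genotype, condition)] = corr
        corr.upper_triangle().to_csv(
            out / f"correlations_{genotype}_{condition}.tsv",
            sep="\t", index=False, float_format="%.6f",
        )

    exposure = [(g, c) for g in ("WT", "KO") for c in ("object", "conspecific")]
    density = compare_density([corrs[gc] for gc in exposure])
    density.anova.to_csv(out / "density_anova.tsv", sep="\t", index=False,
                         float_format="%.6f")
    density.contrasts.to_csv(out / "density_contrasts.tsv", sep="\t",
                             index=False, float_format="%.6f")
    means = pd.DataFrame(
        [{"genotype": g, "condition": c, "mean_r": density.group_mean_r[(g, c)]}
         for g, c in exposure]
    )
    means.to_csv(out / "density_means.tsv", sep="\t", index=False,
                 float_format="%.6f")

    print(f"observations in density ANOVA: {density.n_observations}")
    print(density.anova.to_string(index=False))
    print("group mean r (retransformed from mean Z):")
    print(means.to_string(index=False))


if __name__ == "__main__":
    main()
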