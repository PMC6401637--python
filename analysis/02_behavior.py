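#!/usr/bin/env python
"""Score the sociability preference indexes from the simulated
three-chamber trials and report per-genotype means.

Reads results/data/trials_{WT,KO}.tsv; writes results/behavior_indexes.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from fosnet import score_trials
from fosnet.io import read_behavior_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("results") / "data")
    parser.add_argument("--out", type=Path,
                        default=Path("results") / "behavior_indexes.tsv")
    args = parser.parse_args()

    frames = []
    for genotype in ("WT", "KO"):
        trials = read_behavior_table(args.data_dir / f"trials_{genotype}.tsv")
        result = score_trials(trials)
        frame = result.table.assign(genotype=genotype)
        frames.append(frame)
        print(
            f"{genotype}: chamber index {result.chamber_mean:.1f} "
            f"+/- {result.chamber_sd:.1f}, proximity index "
            f"{result.proximity_mean:.1f} +/- {result.proximity_sd:.1f} "
            f"(n={result.n})"
        )
    combined = pd.concat(frames, ignore_index=True)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    combined.to_csv(args.out, sep="\t", index=False, float_format="%.4f")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
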