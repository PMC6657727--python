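#!/usr/bin/env python
"""Compare candidate HMMs by BIC on genomic test subsets.

Fits 2- and 5-state annotation-trained models on 20-kb subsets and reports
which state count the Bayesian information criterion favours. Pass
--full to also trial the insertion-quantile schemes (2-6 states); this
takes several minutes.
"""

import argparse

import pandas as pd

from tnscape.pipeline import run_pipeline


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="results/pipeline")
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--full", action="store_true")
    args = parser.parse_args()
    candidates = [["annotation", 2], ["annotation", 5]]
    if args.full:
        candidates += [["quantile", n] for n in range(2, 7)]
    out = run_pipeline({
        "outdir": args.outdir, "seed": args.seed, "stages": ["select-model"],
        "select-model": {"subset_length": 20_000, "n_subsets": 4,
                         "candidates": candidates},
    })
    table = pd.read_csv(out / "model_selection.tsv", sep="\t")
    print(table[["scheme", "n", "start", "bic", "converged", "flagged"]]
          .to_string(index=False))
    best = table.loc[table.groupby("start")["bic"].idxmin()]
    print("\nBIC-preferred candidate per subset:")
    print(best[["start", "scheme", "n", "bic"]].to_string(index=False))


if __name__ == "__main__":
    main()
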