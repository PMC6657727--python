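#!/usr/bin/env python
"""100-nt window metrics and the model-free functional threshold.

Tiles the genome into 100-nt windows (insertion density, mean decoded
state, conservation, annotation class), then estimates the model-free
functional threshold: the 95th percentile of insertion density in
essential-coding windows, and the genome fraction below it.
"""

import argparse
import json

import pandas as pd

from tnscape import stats
from tnscape.pipeline import run_pipeline


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="results/pipeline")
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()
    out = run_pipeline({"outdir": args.outdir, "seed": args.seed,
                        "stages": ["windows", "threshold"]})
    windows = pd.read_csv(out / "windows.tsv", sep="\t")
    result = json.loads((out / "threshold.json").read_text())
    print(f"{len(windows)} windows of 100 nt")
    summary, tests = stats.annotation_class_summary(windows, "unique")
    print("median unique insertions per 100-nt window by class:")
    print(summary.round(2).to_string(index=False))
    print(f"\nthreshold: {result['threshold']:.1f} insertions/100 nt "
          f"(95th pct of {result['n_essential_windows']} essential windows)")
    print(f"genome fraction below threshold: "
          f"{100 * result['fraction_below']:.1f}%")


if __name__ == "__main__":
    main()
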