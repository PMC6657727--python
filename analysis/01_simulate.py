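#!/usr/bin/env python
"""Generate the synthetic study world.

Writes a two-chromosome yeast-like genome (120 + 80 kb) with gene models and
essentiality calls, nucleosome/conservation/expression tracks, true
functional states, raw insertion counts, shuffled UMI-tagged read records
with PCR duplicates and low-mappability regions, simulated in-vitro
insertion sites, and per-gene knockout fitness.
"""

import argparse

from tnscape.pipeline import run_pipeline


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="results/pipeline")
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()
    out = run_pipeline({"outdir": args.outdir, "seed": args.seed,
                        "stages": ["simulate"]})
    n_records = sum(1 for _ in open(out / "records.tsv")) - 1
    n_sites = sum(1 for _ in open(out / "sites_true.tsv")) - 1
    print(f"wrote study world to {out}")
    print(f"  {n_sites} true strand-resolved insertion sites")
    print(f"  {n_records} read records (with PCR duplicates and mapq noise)")


if __name__ == "__main__":
    main()
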