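#!/usr/bin/env python
"""Fit the 5-state ZIP-regression HMM and decode functional states.

Pretrains each state's emission on its annotation class (S1 essential CDS,
S2 nonessential CDS, S3 introns/UTRs, S4 unannotated, S5 the top decile of
insertion-dense windows, Poisson family), runs EM per chromosome, and
writes the Viterbi state track.
"""

import argparse
import json

from tnscape.pipeline import run_pipeline


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="results/pipeline")
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()
    out = run_pipeline({"outdir": args.outdir, "seed": args.seed,
                        "stages": ["fit-hmm"]})
    models = json.loads((out / "model.json").read_text())
    for chrom, model in models.items():
        status = "converged" if model["converged"] else "hit the iteration cap"
        print(f"{chrom}: EM {status} after "
              f"{len(model['loglik_trace']) - 1} iterations")
        for i, e in enumerate(model["emissions"]):
            print(f"  S{i + 1}: beta0={e['beta0']:+.2f} "
                  f"nucleosome={e['beta1']:+.2f} imss={e['beta2']:+.2f} "
                  f"omega={e['omega']:.2f} ({e['family']})")
    print(f"decoded states: {out / 'states.bedGraph'}")


if __name__ == "__main__":
    main()
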