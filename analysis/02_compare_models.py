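"""Goodness-of-fit of the simulated models against a reference sample.

Without patient recordings, the reference fingerprint sample is a held-out
subsample of the spreading-model output (a self-recovery design: the
comparison should then rank the spreading model best). Reads the feature
tables written by 01_simulate_models.py and writes the unpaired and paired
bootstrap measure tables to results/.
"""

import argparse
import pathlib
import sys

import numpy as np
import pandas as pd

from taaspread.detection import FEATURE_NAMES
from taaspread.pipeline import run_compare

MODELS = ("one_source", "two_sources", "spreading")


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-held", type=int, default=24,
                        help="held-out reference sample size")
    parser.add_argument("--results", type=pathlib.Path,
                        default=pathlib.Path("results"))
    args = parser.parse_args(argv)

    samples = {}
    for model in MODELS:
        path = args.results / f"features_{model}.csv"
        if not path.exists():
            raise SystemExit(f"missing {path}; run 01_simulate_models.py first")
        samples[model] = pd.read_csv(path)[FEATURE_NAMES].to_numpy()

    rng = np.random.default_rng(args.seed)
    Xs = samples["spreading"]
    held_idx = rng.choice(len(Xs), size=min(args.n_held, len(Xs) // 2),
                          replace=False)
    mask = np.zeros(len(Xs), dtype=bool)
    mask[held_idx] = True
    held = Xs[mask]
    models = dict(samples)
    models["spreading"] = Xs[~mask]

    measures = ("ll10", "ll50", "db", "emd")
    if min(len(x) for x in models.values()) <= 50:
        measures = ("ll10", "db", "emd")
        print("model samples too small for k=50; dropping ll50", file=sys.stderr)

    unpaired, paired = run_compare(held, models, master_seed=args.seed,
                                   reference="spreading", measures=measures)
    unpaired.to_csv(args.results / "measures_unpaired.csv", index=False)
    paired.to_csv(args.results / "measures_paired.csv", index=False)

    med = unpaired.set_index(["model", "measure"])["median"]
    print("median goodness-of-fit (reference = held-out spreading sample):",
          file=sys.stderr)
    for measure in measures:
        ranking = sorted(MODELS, key=lambda m: med[m, measure],
                         reverse=measure.startswith("ll"))
        print(f"  {measure}: best -> worst: {', '.join(ranking)}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
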