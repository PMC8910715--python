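"""Hormone class comparison: totals, fold ranges, Welch tests and stars."""

import argparse

from bulkseg.config import RunConfig
from bulkseg.pipeline import run_hormones


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    table = run_hormones(RunConfig(seed=args.seed), args.workdir)
    cols = ["class", "mean_tall", "mean_dwarf", "fold_min", "fold_max", "p", "stars"]
    print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
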