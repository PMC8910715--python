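"""Merge all stage outputs into one summary JSON and print it."""

import argparse
import json

from bulkseg.config import RunConfig
from bulkseg.pipeline import run_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    summary = run_report(RunConfig(seed=args.seed), args.workdir)
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
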