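"""Associate candidate intervals with DEGs: per-interval tallies and shares."""

import argparse

from bulkseg.config import RunConfig
from bulkseg.pipeline import run_associate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    tally = run_associate(RunConfig(seed=args.seed), args.workdir)
    print(tally.to_string(index=False))


if __name__ == "__main__":
    main()
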