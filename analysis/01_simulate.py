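"""Generate the synthetic BC8 study dataset.

Builds a 965-plant BC8 backcross of dwarf (recurrent) x tall lines, selects
36-plant tall and 40-plant dwarf pools, and writes every downstream input:
pooled allele depths (TSV + VCF), the 3-vs-3 count matrix, gene models,
hormone replicate panels and qPCR Ct tables, plus the simulation truth.
"""

import argparse

from bulkseg.config import RunConfig
from bulkseg.pipeline import run_simulate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    cfg = RunConfig(seed=args.seed)
    meta = run_simulate(cfg, args.workdir)
    print(f"wrote synthetic dataset to {args.workdir}")
    print(f"causal locus: {meta['causal']['chrom']}:{meta['causal']['pos']:,}")
    print(f"bulks: {meta['n_tall']} tall / {meta['n_dwarf']} dwarf")


if __name__ == "__main__":
    main()
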