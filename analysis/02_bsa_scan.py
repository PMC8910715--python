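"""Bulked-segregant scan: SNP-index, Δ(SNP-index), loess, candidate intervals.

Reads the pooled allele depths, filters to informative SNPs, smooths Δ per
chromosome and calls candidate intervals against simulation-derived null
thresholds.  Writes the index track, threshold table, intervals (TSV + BED)
and a scan figure.
"""

import argparse

from bulkseg.bsa import total_interval_span
from bulkseg.config import RunConfig
from bulkseg.pipeline import run_bsa


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    cfg = RunConfig(seed=args.seed)
    intervals = run_bsa(cfg, args.workdir)
    print(f"called {len(intervals)} candidate interval(s):")
    for iv in intervals:
        print(
            f"  {iv.chrom}:{iv.start:,}-{iv.end:,}  "
            f"{iv.n_snps} SNPs, peak Δ = {iv.peak_delta:.3f}"
        )
    if intervals:
        print(f"total span: {total_interval_span(intervals):.2f} Mb")
        try:
            from bulkseg.io import read_track
            from bulkseg.plots import scan_plot

            track = read_track(f"{args.workdir}/index_track.tsv")
            scan_plot(track, intervals, f"{args.workdir}/scan.png")
            print(f"figure: {args.workdir}/scan.png")
        except ImportError:
            pass


if __name__ == "__main__":
    main()
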