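"""Generate the synthetic study dataset with planted structure.

Emits the full dataset (sites, counts, per-assay pileup tracks, TF
peaks, expression table, truth labels) under scratch/sim/ — the raw
files are large, so they live outside results/ — and a compact summary
of what was planted under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from dhsdelta import SimulationConfig, simulate_dataset, write_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default=ROOT / "scratch" / "sim")
    ap.add_argument("--results", default=ROOT / "results")
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    ds = simulate_dataset(cfg)
    paths = write_dataset(ds, args.outdir)

    truth = ds.truth.to_frame()
    summary = truth.groupby(["status", "tf_bound"]).size().rename("n").reset_index()
    results = Path(args.results)
    results.mkdir(exist_ok=True)
    summary.to_csv(results / "sim_planted_summary.tsv", sep="\t", index=False)

    print(f"simulated {len(ds.sites)} DHS sites on {cfg.n_chrom} chromosomes")
    print(truth.status.value_counts().to_string())
    print(f"TF-bound fraction: {truth.tf_bound.mean():.3f}")
    print(f"promoter-proximal fraction: {truth.promoter.mean():.3f}")
    print(f"wrote {len(paths)} files under {args.outdir}")


if __name__ == "__main__":
    main()
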