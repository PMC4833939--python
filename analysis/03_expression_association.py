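"""Associate accessibility changes with nearby gene expression changes.

Maps each DHS site to its nearest gene, stratifies genes by the number
of nearest opened/closed sites, tests each stratum's expression
fold-change shift against all expressed genes (Mann-Whitney), and emits
cumulative-fraction curves. Also demonstrates the gene-set overlap
arithmetic used for knockdown comparisons.
"""

import argparse
from pathlib import Path

import pandas as pd

from dhsdelta import associate, overlap_percentage, read_bed
from dhsdelta.simulate import genes_from_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", default=ROOT / "scratch" / "sim")
    ap.add_argument("--results", default=ROOT / "results")
    args = ap.parse_args()
    simdir, results = Path(args.simdir), Path(args.results)
    results.mkdir(exist_ok=True)

    res = pd.read_csv(simdir / "differential.tsv", sep="\t")
    expression = pd.read_csv(simdir / "expression.tsv", sep="\t")
    genes = genes_from_frame(pd.read_csv(simdir / "genes.tsv", sep="\t"))
    sites = read_bed(simdir / "sites.bed")

    table, curves = associate(res, expression, genes, sites)
    table.to_csv(results / "association.tsv", sep="\t", index=False)
    curves.to_csv(simdir / "association_curves.tsv", sep="\t", index=False)

    print(table.to_string(index=False))
    up = set(expression.loc[(expression.fdr < 0.05) & (expression.log2fc > 0),
                            "gene_id"])
    planted = set(expression.loc[expression.fdr < 0.05, "gene_id"])
    inter, n, pct = overlap_percentage(up, planted)
    print(f"sanity gene-set overlap: {pct} % ({inter}/{n})")


if __name__ == "__main__":
    main()
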