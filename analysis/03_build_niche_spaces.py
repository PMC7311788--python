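"""Build the per-biome and combined niche spaces (the nested PCA).

For each biome, and for all species pooled, runs the two-stage ordination
(log10 traits -> one PCA per niche dimension -> second PCA on the six
PC1/PC2 gradient columns) and writes the dimension-level and niche-level
summary tables plus species scores.
"""

import warnings
from pathlib import Path

from nichespace.io import read_trait_table
from nichespace.comparison import combined_space
from nichespace.ordination import niche_space, summarize_space

RESULTS = Path(__file__).resolve().parents[1] / "results"


def write_space(tag, dim_results, space, outdir):
    summary = summarize_space(space, dim_results)
    summary.niche.to_csv(outdir / f"{tag}_niche_summary.tsv", sep="\t",
                         float_format="%.10g")
    summary.dimensions.to_csv(outdir / f"{tag}_dimension_summary.tsv", sep="\t",
                              index=False, float_format="%.10g")
    space.xy.to_csv(outdir / f"{tag}_scores.tsv", sep="\t", float_format="%.10g")
    pc1 = space.loadings["PC1"].abs().idxmax()
    print(f"{tag}: PC1 {space.percent_variance[0]:.1f}% "
          f"(top gradient {pc1} -> {space.gradient_dominant[pc1]}), "
          f"PC2 {space.percent_variance[1]:.1f}%")


def main() -> None:
    table, _ = read_trait_table(RESULTS / "data" / "community.tsv")
    outdir = RESULTS / "spaces"
    outdir.mkdir(parents=True, exist_ok=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for biome in table.biomes():
            dim_results, space = niche_space(table.subset(biome))
            write_space(biome, dim_results, space, outdir)
        tables = {b: table.subset(b) for b in table.biomes()}
        dim_results, pooled = combined_space(tables)
        write_space("combined", dim_results, pooled, outdir)


if __name__ == "__main__":
    main()
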