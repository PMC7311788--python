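"""Niche periodicity: family/species convergence in the central plots.

Bins each biome's niche space into 0.5 x 0.5 plots, selects the (up to)
eight multi-species plots nearest the origin and reports the
family-to-species ratio of each -- a ratio of 1 means every species sharing
the plot belongs to a different family (strong convergence of distantly
related species).  The six-species cold-temperate space typically yields no
multi-species plot at all: periodicity not assessable, mirroring the sparse
high-latitude outcome.
"""

import warnings
from pathlib import Path

import pandas as pd

from nichespace.io import read_trait_table
from nichespace.ordination import niche_space
from nichespace.periodicity import convergence_report

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table, records = read_trait_table(RESULTS / "data" / "community.tsv")
    families = pd.Series({(r.species_id, r.biome): r.family for r in records})
    outdir = RESULTS / "convergence"
    outdir.mkdir(parents=True, exist_ok=True)
    for biome in table.biomes():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, space = niche_space(table.subset(biome))
            report = convergence_report(space, families)
        report.to_frame().to_csv(outdir / f"{biome}_convergence.tsv", sep="\t",
                                 index=False, float_format="%.10g")
        if report.assessable:
            ratios = ", ".join(
                f"{p.plot_id}={r:.2f}" for p, r in zip(report.plots, report.ratios)
            )
            print(f"{biome}: mean ratio {report.mean_ratio:.2f} ({ratios})")
        else:
            print(f"{biome}: periodicity not assessable (no multi-species plot)")


if __name__ == "__main__":
    main()
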