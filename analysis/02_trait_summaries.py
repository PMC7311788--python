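"""Per-biome trait summaries of the simulated community.

Reports mean and standard deviation of each of the 11 traits per biome on
the natural scale -- the simulated analogue of the field summary (e.g. stem
tissue density means near 0.6 g/cm3 in the tropical forest and lower,
narrower values in the cold-temperate forest).
"""

from pathlib import Path

import pandas as pd

from nichespace.io import read_trait_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table, _ = read_trait_table(RESULTS / "data" / "community.tsv")
    summary = (
        table.data.groupby(level="biome")
        .agg(["mean", "std"])
        .reindex(["TF", "SF", "WF", "CF"])
        .round(3)
    )
    summary.columns = [f"{trait}_{stat}" for trait, stat in summary.columns]
    out = RESULTS / "trait_summary.tsv"
    summary.to_csv(out, sep="\t")
    print(f"trait summary -> {out}")
    std = summary[["STD_mean", "STD_std"]]
    print("stem tissue density (g/cm3) by biome:")
    print(std.to_string())
    print("SLA (cm2/g) by biome:")
    print(summary[["SLA_mean", "SLA_std"]].to_string())


if __name__ == "__main__":
    main()
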