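"""End-to-end pipeline driver: traits -> spaces -> convergence -> comparison.

Given one canonical trait file covering up to four biomes, the driver builds
a niche space per biome and for the pooled community, writes the
niche-variation and per-dimension summary tables, the central-plot
convergence reports, the biome comparison and a provenance manifest.  All
outputs are plain delimited text; a rerun from the same manifest is
bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .comparison import compare_axes, combined_space
from .io import read_trait_table, write_manifest
from .ordination import niche_space, summarize_space
from .periodicity import convergence_report
from .traits import DEFAULT_SCHEME, DimensionScheme, TraitTable

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

#: Fewer species than this in a biome triggers the small-n warning path.
MIN_SPECIES_FOR_SPACE = 3


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


@dataclass
class RunConfig:
    """Validated knobs of one pipeline run; echoed into the manifest."""

    input_path: Path
    out_dir: Path
    scheme: DimensionScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    bin_width: float = 0.5
    n_plots: int = 8
    alpha: float = 0.05
    adjust: str = "holm"
    drop_invalid: bool = False
    allow_wraparound: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.input_path = Path(self.input_path)
        self.out_dir = Path(self.out_dir)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")

    def manifest_dict(self) -> dict:
        d = asdict(self)
        d["scheme"] = self.scheme.mapping
        return d


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and return the artifact name -> path map."""
    artifacts: dict[str, Path] = {}
    out = config.out_dir

    try:
        table, records = read_trait_table(
            config.input_path,
            drop_invalid=config.drop_invalid,
            allow_wraparound=config.allow_wraparound,
        )
    except Exception as err:
        raise PipelineError(f"[ingest] {err}") from err

    families = pd.Series(
        {(r.species_id, r.biome): r.family for r in records}, name="family"
    )
    biomes = table.biomes()

    per_biome: dict[str, TraitTable] = {}
    for biome in biomes:
        sub = table.subset(biome)
        if len(sub.data) < MIN_SPECIES_FOR_SPACE:
            log.warning("[space:%s] only %d species; biome skipped from its own "
                        "ordination (still pooled)", biome, len(sub.data))
            per_biome[biome] = sub
            continue
        per_biome[biome] = sub
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dim_results, space = niche_space(sub, config.scheme)
        except Exception as err:
            raise PipelineError(f"[space:{biome}] {err}") from err
        summary = summarize_space(space, dim_results)
        artifacts[f"{biome}_niche_summary"] = _write(
            summary.niche, out / f"{biome}_niche_summary.tsv")
        artifacts[f"{biome}_dimension_summary"] = _write(
            summary.dimensions, out / f"{biome}_dimension_summary.tsv", index=False)
        artifacts[f"{biome}_scores"] = _write(space.xy, out / f"{biome}_scores.tsv")
        try:
            report = convergence_report(
                space, families, width=config.bin_width, k=config.n_plots)
        except Exception as err:
            raise PipelineError(f"[converge:{biome}] {err}") from err
        frame = report.to_frame()
        if not report.assessable:
            log.warning("[converge:%s] no multi-species central plot; "
                        "periodicity not assessable", biome)
        artifacts[f"{biome}_convergence"] = _write(
            frame, out / f"{biome}_convergence.tsv", index=False)

    if len(biomes) >= 2:
        try:
            dim_results, pooled = combined_space(per_biome, config.scheme)
        except Exception as err:
            raise PipelineError(f"[combined] {err}") from err
        summary = summarize_space(pooled, dim_results)
        artifacts["combined_niche_summary"] = _write(
            summary.niche, out / "combined_niche_summary.tsv")
        artifacts["combined_dimension_summary"] = _write(
            summary.dimensions, out / "combined_dimension_summary.tsv", index=False)
        artifacts["combined_scores"] = _write(pooled.xy, out / "combined_scores.tsv")
        report = convergence_report(
            pooled, families, width=config.bin_width, k=config.n_plots)
        artifacts["combined_convergence"] = _write(
            report.to_frame(), out / "combined_convergence.tsv", index=False)
        try:
            results = compare_axes(pooled, alpha=config.alpha, adjust=config.adjust)
        except Exception as err:
            raise PipelineError(f"[compare] {err}") from err
        artifacts["comparison"] = _write(
            pd.concat([r.to_frame() for r in results]),
            out / "comparison.tsv", index=False)
    else:
        log.warning("[compare] fewer than 2 biomes; comparison skipped")

    artifacts["manifest"] = write_manifest(
        out / "manifest.json", config.manifest_dict(), [config.input_path])
    return artifacts
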