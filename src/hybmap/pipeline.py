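"""End-to-end pipeline: simulate → sites → genotype → phase → map → distortion.

Holds the configuration dataclass and a single entry point,
:func:`run_pipeline`, that every driver (CLI subcommand ``all``, the
numbered analysis scripts, the acceptance script and the test suite) calls
so results are produced by one code path. All randomness flows through one
seed via ``numpy.random.SeedSequence`` children per stage, so identical
configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import block_genotyper, distortion_analysis, informative_sites, map_builder
from . import phase_crossovers, sim_cross
from .core import (
    ChromosomeSpec,
    COModel,
    Parent,
    Strain,
    ViabilitySelection,
    default_karyotype,
)


@dataclass
class PipelineConfig:
    """Study-condition defaults: 93 F2, obligate single crossover per
    chromosome per meiosis, ~5x shotgun coverage, 100-kb blocks."""

    n_f2: int = sim_cross.DEFAULT_N_F2
    chromosomes: Sequence[ChromosomeSpec] = field(default_factory=default_karyotype)
    co_model_paternal: COModel = field(default_factory=COModel)
    co_model_maternal: COModel = field(default_factory=COModel)
    selection: ViabilitySelection | None = None
    sites_per_mb: float = sim_cross.DEFAULT_SITES_PER_MB
    coverage: float = sim_cross.DEFAULT_COVERAGE
    error_rate: float = sim_cross.DEFAULT_ERROR_RATE
    block_size: int = block_genotyper.DEFAULT_BLOCK_SIZE
    thresholds: block_genotyper.ClassifierThresholds = field(
        default_factory=block_genotyper.ClassifierThresholds
    )
    min_sites: int = 100
    max_uncalled_fraction: float = 0.30
    distortion_alpha: float = 0.001
    mapping_function: str = "morgan"
    male_x_strain: Strain = Strain.CA
    require_wa: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    config: PipelineConfig
    parental: pd.DataFrame
    sites: pd.DataFrame
    rejected_sites: pd.DataFrame
    truth: sim_cross.SimTruth
    blocks: pd.DataFrame  # with kept / drop_reason columns
    calls: np.ndarray  # (n_blocks, n_f2)
    call_reasons: np.ndarray
    depth_tensor: np.ndarray  # (n_f2, n_blocks, 3)
    f2_ids: list[str]
    distortion: pd.DataFrame
    chromatids: pd.DataFrame
    chromatid_summary: dict
    maps: dict[tuple[str, Parent], map_builder.GeneticMap]
    funnel: dict

    @property
    def kept_mask(self) -> np.ndarray:
        return self.blocks["kept"].to_numpy()


def stage_seeds(seed: int, n: int = 4) -> list[np.random.Generator]:
    """Independent per-stage generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on a freshly simulated cohort."""
    cfg = config or PipelineConfig()
    rng_panel, rng_cohort, rng_depth, _ = stage_seeds(cfg.seed)

    # simulate
    parental = sim_cross.make_parental_panel(
        cfg.chromosomes, cfg.sites_per_mb, rng_panel
    )
    truth = sim_cross.simulate_f2_cohort(
        cfg.n_f2,
        cfg.chromosomes,
        {Parent.PATERNAL: cfg.co_model_paternal, Parent.MATERNAL: cfg.co_model_maternal},
        cfg.selection,
        rng_cohort,
        male_x_strain=cfg.male_x_strain,
        require_wa=cfg.require_wa,
    )

    # informative sites
    bounds = informative_sites.compute_depth_bounds(parental)
    sites, rejected = informative_sites.classify_table(parental, bounds)

    # block genotyping
    blocks = block_genotyper.bin_sites(sites, cfg.chromosomes, cfg.block_size)
    depth_iter = sim_cross.sample_depths(
        truth, sites, cfg.coverage, cfg.error_rate, rng_depth
    )
    calls, reasons, depth_tensor, f2_ids = block_genotyper.genotype_cohort(
        depth_iter,
        sites,
        blocks,
        cfg.chromosomes,
        cfg.thresholds,
        cfg.block_size,
        cfg.male_x_strain,
    )

    # distortion (reported on the unfiltered matrix; used by the filter)
    distortion = distortion_analysis.distortion_table(
        calls, blocks, list(cfg.chromosomes), cfg.male_x_strain
    )
    blocks = block_genotyper.filter_blocks(
        blocks,
        calls,
        distortion["p"].to_numpy(),
        cfg.min_sites,
        cfg.max_uncalled_fraction,
        cfg.distortion_alpha,
    )

    # phasing and maps on kept blocks
    kept = blocks["kept"].to_numpy()
    chromatids = phase_crossovers.phase_cohort(
        calls, blocks, list(cfg.chromosomes), f2_ids, kept_mask=kept
    )
    summary = phase_crossovers.tally_chromatids(chromatids)
    maps = map_builder.build_maps(
        calls, blocks, list(cfg.chromosomes), kept, cfg.mapping_function
    )

    funnel = {
        "sites_total": int(len(parental)),
        "sites_accepted": int(len(sites)),
        "sites_rejected_by_reason": rejected["reason"].value_counts().to_dict()
        if len(rejected)
        else {},
        "blocks_total": int(len(blocks)),
        "blocks_kept": int(kept.sum()),
        "blocks_dropped_by_reason": blocks.loc[~kept, "drop_reason"]
        .value_counts()
        .to_dict(),
        "no_call_rate": float((calls < 0).mean()) if calls.size else float("nan"),
        "chromatids_suspect": int(chromatids["suspect"].sum()),
    }
    return PipelineResult(
        cfg,
        parental,
        sites,
        rejected,
        truth,
        blocks,
        calls,
        reasons,
        depth_tensor,
        f2_ids,
        distortion,
        chromatids,
        summary,
        maps,
        funnel,
    )


def map_length_table(result: PipelineResult) -> pd.DataFrame:
    """Total map length per chromosome per parent (cM)."""
    rows = [
        {
            "chromosome": chrom,
            "parent": str(parent),
            "is_x": any(c.is_x and c.name == chrom for c in result.config.chromosomes),
            "total_cM": gmap.total_cm,
            "n_bins": gmap.n_bins,
        }
        for (chrom, parent), gmap in result.maps.items()
    ]
    return pd.DataFrame(rows)
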