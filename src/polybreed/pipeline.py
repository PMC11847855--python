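"""End-to-end scenario pipeline: founder genome -> panels -> effects -> scheme.

A scenario is a ``GenomeSpec`` (genome structure and historical-population
parameters) plus a ``BreedingConfig``. ``prepare_founders`` runs the
historical Fisher-Wright phase, samples the breeding founders, draws the
QTL/marker panels under the MAF and allelism constraints and generates the
functional effects on the founders. ``replicate_experiment`` nests scheme
replicates inside founder replicates and summarizes the accuracy and
genetic-gain metrics across them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import spawn_rng
from .genome import (
    GenomePopulation,
    LociPanel,
    random_genetic_map,
    restrict_to_loci,
    sample_individuals,
    select_loci,
    simulate_historical_population,
)
from .scheme import BreedingConfig, Trajectory, run_breeding_scheme
from .traits import EffectSet, generate_effects

__all__ = [
    "GenomeSpec",
    "potato_chromosome_lengths",
    "prepare_genome",
    "prepare_founders",
    "replicate_experiment",
    "summarize_replicates",
]

# relative chromosome lengths emulating the potato genetic map (12 chromosomes,
# longest ~1.6x the shortest), scaled so the genome totals 888.6 cM
_POTATO_REL = np.array([1.30, 1.01, 0.96, 0.94, 0.87, 0.81, 0.79, 0.75, 0.74, 0.71, 0.68, 0.46])


def potato_chromosome_lengths(total_cM: float = 888.6) -> np.ndarray:
    return total_cM * _POTATO_REL / _POTATO_REL.sum()


@dataclass
class GenomeSpec:
    """Genome structure and historical-population parameters of a scenario."""

    chrom_lengths: np.ndarray = field(default_factory=potato_chromosome_lengths)
    n_marker_loci: int = 50_000
    n_qtl_loci: int = 10_000
    qtl_alleles: int = 2
    Ne: int = 200
    n_hist_generations: int = 1000
    bottleneck: tuple[int, int, int] | None = (901, 950, 100)
    maf_min: float = 0.05
    n_markers: int = 10_000
    n_qtl: int = 2_000


def prepare_genome(
    spec: GenomeSpec, config: BreedingConfig, seed: int, founder_rep: int = 0
) -> tuple[GenomePopulation, LociPanel]:
    """One founder replicate: LD genome, breeding founders and locus panels.

    The returned population is restricted to the panel loci (all later
    breeding-phase meiosis only needs those), with the panel indices remapped
    accordingly. Reusable across trait models: the same founder haplotypes
    can carry different effect sets (e.g., an additive-only and a full
    non-additive study on the same genomes).
    """
    rng_map = spawn_rng(seed, "map", founder_rep)
    gmap = random_genetic_map(
        spec.chrom_lengths, spec.n_marker_loci, spec.n_qtl_loci, spec.qtl_alleles, rng_map
    )
    rng_hist = spawn_rng(seed, "historical", founder_rep)
    hist = simulate_historical_population(
        gmap, spec.Ne, spec.n_hist_generations, config.ploidy, spec.bottleneck, rng_hist
    )
    rng_founders = spawn_rng(seed, "founders", founder_rep)
    founders = sample_individuals(hist, config.n_founders, rng_founders)
    rng_panel = spawn_rng(seed, "panel", founder_rep)
    panel = select_loci(
        founders, spec.n_qtl, spec.n_markers, spec.maf_min, config.allelism_profile, rng_panel
    )

    all_loci = np.concatenate([panel.qtl, panel.markers])
    founders_r, remap = restrict_to_loci(founders, all_loci)
    panel_r = LociPanel(
        qtl=remap[: len(panel.qtl)],
        qtl_seg_alleles=panel.qtl_seg_alleles,
        markers=remap[len(panel.qtl):],
        qtl_freqs=panel.qtl_freqs,
        marker_freqs=panel.marker_freqs,
        n_b=panel.n_b,
        maf_min=panel.maf_min,
    )
    return founders_r, panel_r


def prepare_founders(
    spec: GenomeSpec, config: BreedingConfig, seed: int, founder_rep: int = 0
) -> tuple[GenomePopulation, LociPanel, EffectSet]:
    """Genome preparation plus effect generation for one founder replicate."""
    founders_r, panel_r = prepare_genome(spec, config, seed, founder_rep)
    rng_eff = spawn_rng(seed, "effects", founder_rep)
    effects = generate_effects(founders_r, panel_r, config.trait, config.n_ep, rng_eff)
    return founders_r, panel_r, effects


def replicate_experiment(
    spec: GenomeSpec,
    config: BreedingConfig,
    n_founder_reps: int,
    n_scheme_reps: int,
    seed: int,
    scenario: str = "",
) -> pd.DataFrame:
    """Nested replication: per-replicate trajectory metrics as a DataFrame.

    Rows carry the founder and scheme replicate indices plus accuracy, the
    additive and total-genetic-value gain rates, and the REML estimates.
    """
    rows = []
    for fr in range(n_founder_reps):
        founders, panel, effects = prepare_founders(spec, config, seed, fr)
        for sr in range(n_scheme_reps):
            rng = spawn_rng(seed, "scheme", fr, sr)
            traj = run_breeding_scheme(config, founders, panel, effects, rng)
            rows.append(
                {
                    "scenario": scenario,
                    "founder_rep": fr,
                    "scheme_rep": sr,
                    "accuracy": traj.accuracy,
                    "gain_u": traj.gain_u,
                    "gain_g": traj.gain_g,
                    "reml_sigma_u2": traj.reml_variances.get("u", float("nan")),
                    "reml_sigma_e2": traj.reml_sigma_e2,
                    "reml_converged": traj.reml_converged,
                    "model_used": traj.model_used,
                }
            )
    return pd.DataFrame(rows)


def summarize_replicates(replicates: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD over replicates of the headline metrics, per scenario."""
    metrics = ["accuracy", "gain_u", "gain_g"]
    out = replicates.groupby("scenario")[metrics].agg(["mean", "std", "count"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
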