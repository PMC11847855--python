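"""Reference scenario presets for the two worked studies.

``example1`` is the additive-only study (additive simulation model, additive
GBLUP prediction, allelism profiles x ploidies). ``example2`` is the
non-additive study (additive + dominance + two-locus epistasis simulation
model; prediction models with additive, additive+dominance or the full set
of terms), run on the same founder genomes as example 1.

Two scales are provided. ``scale="paper"`` carries the full published study
conditions (50k marker + 10k QTL initial loci, panels of 10k markers and 2k
QTL). ``scale="desk"`` is the reduced workstation scale used by this
package's own tests and acceptance runs: the breeding scheme (80 parents, 80
crosses x 10 offspring over 13 generations, REML on the 4,000 accumulated
records), the QTL panel (2,000 QTL; 1,000 epistatic pairs in the full model)
and the historical duration for bi-allelic scenarios (Ne=200 for 1,000
generations with a bottleneck) are kept at full size, while the marker panel
is thinned to 2,000 and the initial candidate-locus pools are resized so the
panels remain drawable after drift (pure-drift allele loss makes surviving
fractions the binding constraint; see docs/methods.md). Scenarios with
quad-allelic QTL cannot retain four alleles at frequency >= 0.05 through
1,000 generations of pure drift at Ne=200, so their desk-scale history is
shortened to 150 generations (bottleneck at 101-130); use
``example1_bi_short_history`` as the matched bi-allelic comparator when
contrasting allelism levels.
"""

from __future__ import annotations

from .pipeline import GenomeSpec
from .scheme import BreedingConfig
from .traits import TraitModel

__all__ = [
    "example1",
    "example2",
    "example1_bi_short_history",
    "BI_ALLELIC",
    "MIXED_20_80",
]

BI_ALLELIC = [(2, 1.0)]
MIXED_20_80 = [(2, 0.2), (4, 0.8)]

_SHORT_HISTORY = dict(n_hist_generations=150, bottleneck=(101, 130, 100))


def _genome(scale: str, profile, ploidy: int) -> GenomeSpec:
    qtl_alleles = max(c for c, _ in profile)
    if scale == "paper":
        return GenomeSpec(qtl_alleles=qtl_alleles)
    if scale != "desk":
        raise ValueError(f"unknown scale {scale!r}")
    if qtl_alleles > 2:
        # multi-allelic QTL survive 1,000 generations of pure drift far too
        # rarely; shorten the history and size the QTL pool for the profile
        return GenomeSpec(
            n_marker_loci=4_000,
            n_qtl_loci=20_000,
            qtl_alleles=qtl_alleles,
            n_markers=2_000,
            n_qtl=2_000,
            **_SHORT_HISTORY,
        )
    # bi-allelic: full-length history; pools sized for the survival fraction
    # of bi-allelic loci at MAF >= 0.05 (~10% diploid, ~37% tetraploid)
    mk_pool, qtl_pool = (30_000, 25_000) if ploidy == 2 else (8_000, 8_000)
    return GenomeSpec(
        n_marker_loci=mk_pool, n_qtl_loci=qtl_pool, qtl_alleles=2, n_markers=2_000, n_qtl=2_000
    )


def example1(
    ploidy: int = 2, allelism_profile=None, scale: str = "desk"
) -> tuple[GenomeSpec, BreedingConfig]:
    """Additive-only study: sigma_A2 = 1, sigma_e2 = 2, additive prediction."""
    profile = BI_ALLELIC if allelism_profile is None else list(allelism_profile)
    trait = TraitModel(sigma_a2=1.0, sigma_e2=2.0)
    config = BreedingConfig(
        trait=trait, ploidy=ploidy, allelism_profile=profile, selection_model="additive", n_ep=0
    )
    return _genome(scale, profile, ploidy), config


def example1_bi_short_history(ploidy: int = 2) -> tuple[GenomeSpec, BreedingConfig]:
    """Bi-allelic example-1 scenario on the shortened (150-generation)
    history — the matched comparator for the multi-allelic desk scenarios."""
    genome, config = example1(ploidy=ploidy, scale="desk")
    genome = GenomeSpec(
        n_marker_loci=4_000,
        n_qtl_loci=4_000,
        qtl_alleles=2,
        n_markers=genome.n_markers,
        n_qtl=genome.n_qtl,
        **_SHORT_HISTORY,
    )
    return genome, config


def example2(
    ploidy: int = 2,
    allelism_profile=None,
    selection_model: str = "additive",
    scale: str = "desk",
) -> tuple[GenomeSpec, BreedingConfig]:
    """Full non-additive simulation model with a choice of prediction model.

    Functional variances: sigma_A2 = 1.0 and 0.25 for dominance, additive x
    additive, additive-dominance and dominance x dominance; sigma_e2 = 2.
    Each QTL sits in exactly one epistatic pair (n_ep = n_qtl / 2).
    """
    profile = BI_ALLELIC if allelism_profile is None else list(allelism_profile)
    trait = TraitModel(
        sigma_a2=1.0, sigma_d2=0.25, sigma_aa2=0.25, sigma_ad2=0.25, sigma_dd2=0.25, sigma_e2=2.0
    )
    genome = _genome(scale, profile, ploidy)
    config = BreedingConfig(
        trait=trait,
        ploidy=ploidy,
        allelism_profile=profile,
        selection_model=selection_model,
        n_ep=genome.n_qtl // 2,
    )
    return genome, config
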