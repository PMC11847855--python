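"""YAML configuration loading and dumping for scenario runs.

The schema mirrors :class:`~polybreed.pipeline.GenomeSpec`,
:class:`~polybreed.traits.TraitModel` and
:class:`~polybreed.scheme.BreedingConfig`, under the top-level sections
``genome``, ``trait`` and ``scheme``. Omitted fields take the documented
defaults (e.g., the dominance-degree distribution (0.19, 0.097)); unknown or
invalid fields raise an error naming the field.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .pipeline import GenomeSpec, potato_chromosome_lengths
from .scheme import BreedingConfig
from .traits import TraitModel

__all__ = ["load_config", "dump_config"]

_SECTIONS = {"genome": GenomeSpec, "trait": TraitModel, "scheme": BreedingConfig}


def _build(section: str, cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    if section == "scheme":
        fields.discard("trait")
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown field {sorted(unknown)[0]!r} in section {section!r}")
    kwargs = dict(data)
    if section == "genome":
        if "chrom_lengths" in kwargs:
            kwargs["chrom_lengths"] = np.asarray(kwargs["chrom_lengths"], dtype=float)
        if kwargs.get("bottleneck") is not None and "bottleneck" in kwargs:
            kwargs["bottleneck"] = tuple(kwargs["bottleneck"])
    if section == "trait" and "dominance_degree" in kwargs:
        kwargs["dominance_degree"] = tuple(kwargs["dominance_degree"])
    if section == "scheme" and "allelism_profile" in kwargs:
        kwargs["allelism_profile"] = [tuple(x) for x in kwargs["allelism_profile"]]
    return kwargs


def load_config(path) -> tuple[GenomeSpec, BreedingConfig]:
    """Load and validate a scenario configuration file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown section {sorted(unknown)[0]!r} in {path}")
    try:
        genome = GenomeSpec(**_build("genome", GenomeSpec, raw.get("genome", {})))
        trait = TraitModel(**_build("trait", TraitModel, raw.get("trait", {})))
        scheme_kwargs = _build("scheme", BreedingConfig, raw.get("scheme", {}))
        config = BreedingConfig(trait=trait, **scheme_kwargs)
    except TypeError as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
    return genome, config


def dump_config(genome: GenomeSpec, config: BreedingConfig, path=None) -> str:
    """Serialize a scenario configuration to YAML (round-trips with load)."""
    doc = {
        "genome": {
            "chrom_lengths": [float(x) for x in genome.chrom_lengths],
            "n_marker_loci": genome.n_marker_loci,
            "n_qtl_loci": genome.n_qtl_loci,
            "qtl_alleles": genome.qtl_alleles,
            "Ne": genome.Ne,
            "n_hist_generations": genome.n_hist_generations,
            "bottleneck": list(genome.bottleneck) if genome.bottleneck else None,
            "maf_min": genome.maf_min,
            "n_markers": genome.n_markers,
            "n_qtl": genome.n_qtl,
        },
        "trait": {
            "sigma_a2": config.trait.sigma_a2,
            "sigma_d2": config.trait.sigma_d2,
            "sigma_aa2": config.trait.sigma_aa2,
            "sigma_ad2": config.trait.sigma_ad2,
            "sigma_dd2": config.trait.sigma_dd2,
            "sigma_e2": config.trait.sigma_e2,
            "dominance_degree": list(config.trait.dominance_degree),
            "rescale_method": config.trait.rescale_method,
        },
        "scheme": {
            "n_parents": config.n_parents,
            "n_families": config.n_families,
            "family_size": config.family_size,
            "max_contrib": config.max_contrib,
            "no_selfing": config.no_selfing,
            "n_generations": config.n_generations,
            "random_selection_until": config.random_selection_until,
            "reml_at_generation": config.reml_at_generation,
            "selection_model": config.selection_model,
            "ploidy": config.ploidy,
            "allelism_profile": [list(x) for x in config.allelism_profile],
            "n_ep": config.n_ep,
            "n_founders": config.n_founders,
        },
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
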