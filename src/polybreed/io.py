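"""Output writers, run manifests and deterministic test fixtures."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import spawn_rng
from .genome import GeneticMap, GenomePopulation, LociPanel
from .traits import EffectSet, TraitModel, generate_effects

__all__ = [
    "RunManifest",
    "make_fixture",
    "write_outputs",
    "write_marker_vcf",
    "save_effects",
    "load_effects",
    "save_population",
    "load_population",
]

_EFFECTS_FORMAT_VERSION = 1
_POPULATION_FORMAT_VERSION = 1


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bitwise: config hash and seeds."""

    config_hash: str
    master_seed: int
    software_version: str
    n_founder_reps: int = 1
    n_scheme_reps: int = 1
    outputs: dict = field(default_factory=dict)

    @staticmethod
    def hash_config(config_text: str) -> str:
        return hashlib.sha256(config_text.encode("utf-8")).hexdigest()

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_effects(effects: EffectSet, path) -> None:
    """Write a versioned JSON bundle of an effect set (alleles x loci tables,
    the epistatic pair map and centering offsets) for re-runs."""
    doc = {
        "format_version": _EFFECTS_FORMAT_VERSION,
        "nonadd_offset": effects.nonadd_offset,
        "pairs": effects.pairs.tolist(),
        "a_offset": effects.a_offset.tolist(),
    }
    for name in ("a", "d", "aa", "ad", "da", "dd"):
        doc[name] = getattr(effects, name).tolist()
    Path(path).write_text(json.dumps(doc))


def load_effects(path) -> EffectSet:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _EFFECTS_FORMAT_VERSION:
        raise ValueError(f"unsupported effect-bundle version {doc.get('format_version')!r}")
    return EffectSet(
        a=np.array(doc["a"]),
        d=np.array(doc["d"]),
        aa=np.array(doc["aa"]),
        ad=np.array(doc["ad"]),
        da=np.array(doc["da"]),
        dd=np.array(doc["dd"]),
        pairs=np.array(doc["pairs"], dtype=np.int64).reshape(-1, 2),
        a_offset=np.array(doc["a_offset"]),
        nonadd_offset=float(doc["nonadd_offset"]),
    )


def save_population(pop: GenomePopulation, path) -> None:
    """Haplotype store: per-chromosome integer arrays in an .npz container
    plus a JSON sidecar (``<path>.json``) holding the map metadata."""
    path = Path(path)
    arrays = {f"chrom_{c}": h for c, h in enumerate(pop.haplotypes)}
    arrays.update(ids=pop.ids, parents=pop.parents, generation=pop.generation)
    np.savez_compressed(path, **arrays)
    gmap = pop.gmap
    sidecar = {
        "format_version": _POPULATION_FORMAT_VERSION,
        "ploidy": pop.ploidy,
        "chrom_lengths": gmap.chrom_lengths.tolist(),
        "chrom": gmap.chrom.tolist(),
        "pos": gmap.pos.tolist(),
        "n_alleles": gmap.n_alleles.tolist(),
        "is_qtl_candidate": gmap.is_qtl_candidate.tolist(),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def load_population(path) -> GenomePopulation:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    if sidecar.get("format_version") != _POPULATION_FORMAT_VERSION:
        raise ValueError(f"unsupported haplotype-store version {sidecar.get('format_version')!r}")
    gmap = GeneticMap(
        np.array(sidecar["chrom_lengths"]),
        np.array(sidecar["chrom"]),
        np.array(sidecar["pos"]),
        np.array(sidecar["n_alleles"]),
        np.array(sidecar["is_qtl_candidate"]),
    )
    npz = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
    with np.load(npz if Path(npz).exists() else path) as data:
        haps = [data[f"chrom_{c}"] for c in range(gmap.n_chrom)]
        return GenomePopulation(
            gmap, int(sidecar["ploidy"]), haps, data["ids"], data["parents"], data["generation"]
        )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def _single_locus_pop(ploidy: int, dosages: list[int]) -> tuple[GenomePopulation, LociPanel]:
    """Population with one bi-allelic QTL covering the given allele-1... counts.

    ``dosages`` are copies of allele B1 (allele index 0) per individual.
    """
    gmap = GeneticMap(
        chrom_lengths=np.array([100.0]),
        chrom=np.array([0]),
        pos=np.array([50.0]),
        n_alleles=np.array([2]),
        is_qtl_candidate=np.array([True]),
    )
    haps = np.array([[[0] * t + [1] * (ploidy - t)] for t in dosages], dtype=np.uint8)
    haps = haps.reshape(len(dosages), ploidy, 1)
    n = len(dosages)
    pop = GenomePopulation(
        gmap, ploidy, [haps], np.arange(n), np.full((n, 2), -1), np.zeros(n, dtype=int)
    )
    freq0 = np.array(dosages).mean() / ploidy
    panel = LociPanel(
        qtl=np.array([0]),
        qtl_seg_alleles=np.array([2]),
        markers=np.array([], dtype=np.int64),
        qtl_freqs=np.array([[freq0, 1 - freq0]]),
        marker_freqs=np.array([]),
        n_b=2,
    )
    return pop, panel


def _tiny_population(ploidy: int, qtl_alleles: int, seed: int):
    rng = spawn_rng(seed, "fixture", ploidy, qtl_alleles)
    gmap = GeneticMap(
        chrom_lengths=np.array([80.0, 60.0]),
        chrom=np.array([0, 0, 0, 1, 1]),
        pos=np.array([10.0, 35.0, 70.0, 20.0, 55.0]),
        n_alleles=np.array([2, qtl_alleles, 2, qtl_alleles, 2]),
        is_qtl_candidate=np.array([False, True, False, True, False]),
    )
    n = 10
    haps = []
    for c in range(2):
        sl = gmap.chrom_loci(c)
        n_all = gmap.n_alleles[sl]
        arr = (rng.integers(0, 1 << 16, size=(n * ploidy, sl.stop - sl.start)) % n_all).astype(np.uint8)
        haps.append(arr.reshape(n, ploidy, -1))
    pop = GenomePopulation(gmap, ploidy, haps, np.arange(n), np.full((n, 2), -1), np.zeros(n, dtype=int))
    freqs = pop.allele_freqs()
    panel = LociPanel(
        qtl=np.array([1, 3]),
        qtl_seg_alleles=(freqs[[1, 3]] > 0).sum(axis=1),
        markers=np.array([0, 2, 4]),
        qtl_freqs=freqs[[1, 3], :qtl_alleles],
        marker_freqs=freqs[[0, 2, 4], 1],
        n_b=qtl_alleles,
    )
    trait = TraitModel(sigma_a2=1.0, sigma_d2=0.25, sigma_aa2=0.1, sigma_ad2=0.1, sigma_dd2=0.1, sigma_e2=1.0)
    effects = generate_effects(pop, panel, trait, n_ep=1, rng=spawn_rng(seed, "fixture-effects"))
    return pop, panel, effects


def make_fixture(kind: str, seed: int = 0):
    """Deterministic small instances for tests and worked examples.

    ``tiny_diploid`` / ``tiny_tetraploid``: 2 chromosomes, 5 loci (2 QTL of
    which one epistatic pair, 3 bi-allelic markers), 10 individuals, full
    effect set. ``worked_tables``: single bi-allelic locus populations whose
    genotype classes cover every dosage row of the diploid (B1B1, B1B2, B2B2)
    and tetraploid (B1 dosage 4..0) conversion tables, as
    ``{"diploid": (pop, panel), "tetraploid": (pop, panel)}``.
    """
    if kind == "tiny_diploid":
        return _tiny_population(2, 2, seed)
    if kind == "tiny_tetraploid":
        return _tiny_population(4, 4, seed)
    if kind == "worked_tables":
        return {
            "diploid": _single_locus_pop(2, [2, 1, 0]),
            "tetraploid": _single_locus_pop(4, [4, 3, 2, 1, 0]),
        }
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_outputs(
    trajectories: list, replicates: pd.DataFrame, summary: pd.DataFrame, out_dir, manifest: RunManifest
) -> dict:
    """Write per-replicate trajectory CSVs, the summary CSV and the manifest.

    Returns the mapping of logical names to written paths (also recorded in
    the manifest).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for i, traj in enumerate(trajectories):
        p = out_dir / f"trajectory_{i:03d}.csv"
        traj.table.to_csv(p, index=False)
        paths[f"trajectory_{i:03d}"] = str(p)
    p = out_dir / "replicates.csv"
    replicates.to_csv(p, index=False)
    paths["replicates"] = str(p)
    p = out_dir / "summary.csv"
    summary.to_csv(p, index=False)
    paths["summary"] = str(p)
    manifest.outputs = paths
    manifest.to_json(out_dir / "manifest.json")
    paths["manifest"] = str(out_dir / "manifest.json")
    return paths


_VCF_ALLELES = ("A", "C", "G", "T")


def write_marker_vcf(pop: GenomePopulation, panel: LociPanel, path) -> None:
    """Export marker genotypes as a (multi-allelic capable) VCF.

    Abstract allele indices are encoded as symbolic nucleotides (allele 0 ->
    A, 1 -> C, ...); cM positions are mapped to integer coordinates at 10 kb
    per cM, nudged to stay strictly increasing. Genotype calls carry the full
    ploidy (e.g. 0/0/1/1 for a tetraploid duplex marker).
    """
    import pysam

    path = str(path)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for c, length in enumerate(pop.gmap.chrom_lengths):
        header.contigs.add(f"chr{c + 1}", length=int(length * 10_000) + 10_000)
    for ind in pop.ids:
        header.add_sample(f"ind{ind}")
    block = pop.haplotype_block(panel.markers)
    chrom, _ = pop.gmap.local_index(panel.markers)
    pos_cm = pop.gmap.pos[panel.markers]
    with pysam.VariantFile(path, "w", header=header) as vf:
        last = {}
        for j in range(len(panel.markers)):
            c = int(chrom[j])
            bp = int(pos_cm[j] * 10_000) + 1
            bp = max(bp, last.get(c, 0) + 1)
            last[c] = bp
            n_all = int(pop.gmap.n_alleles[panel.markers[j]])
            rec = vf.new_record(
                contig=f"chr{c + 1}", start=bp - 1, stop=bp, alleles=_VCF_ALLELES[:n_all]
            )
            for i, ind in enumerate(pop.ids):
                rec.samples[f"ind{ind}"]["GT"] = tuple(int(a) for a in block[i, :, j])
            vf.write(rec)
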