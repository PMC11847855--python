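"""Founder-genome simulation, meiosis and locus-panel selection.

The genome model: a set of chromosomes with map lengths in centimorgans,
carrying point loci at continuous cM positions. Individuals at an even ploidy
``p`` carry ``p`` homologs per chromosome, each an array of allele indices.

Founder linkage disequilibrium is built forward-in-time with a Fisher-Wright
model: discrete generations of random mating among ``Ne`` monoecious parents
(no selfing), pure drift plus recombination, no mutation, starting from equal
allele frequencies at every locus. Meiosis uses strict bivalent pairing: the
``p`` homologs of a chromosome are randomly partitioned into ``p/2`` pairs,
each pair recombines like a diploid bivalent (crossover count Poisson in the
map length in Morgans, positions uniform — Haldane, no interference) and
contributes one recombinant product to the gamete. Double reduction cannot
occur under this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng

__all__ = [
    "GeneticMap",
    "GenomePopulation",
    "LociPanel",
    "random_genetic_map",
    "simulate_historical_population",
    "meiosis",
    "mate",
    "sample_individuals",
    "restrict_to_loci",
    "select_loci",
    "dosage_matrix",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Chromosome lengths and locus coordinates.

    Loci are stored globally, sorted by (chromosome, position); ``chrom[i]``
    and ``pos[i]`` give the chromosome index and cM position of locus ``i``.
    ``n_alleles[i]`` is the number of alleles *defined* at the locus (the
    maximum allele index + 1); ``is_qtl_candidate`` marks loci eligible to
    become QTL (the rest are marker candidates).
    """

    chrom_lengths: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    n_alleles: np.ndarray
    is_qtl_candidate: np.ndarray

    def __post_init__(self) -> None:
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        self.pos = np.asarray(self.pos, dtype=float)
        self.n_alleles = np.asarray(self.n_alleles, dtype=np.int16)
        self.is_qtl_candidate = np.asarray(self.is_qtl_candidate, dtype=bool)
        if self.chrom.shape != self.pos.shape:
            raise ValueError("chrom and pos must have the same length")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            raise ValueError("loci must be sorted by (chromosome, position)")
        if np.any(self.pos < 0):
            raise ValueError("locus positions must be >= 0")
        if np.any(self.pos > self.chrom_lengths[self.chrom]):
            raise ValueError("locus position beyond chromosome length")
        # global index of the first locus of each chromosome
        self._starts = np.searchsorted(self.chrom, np.arange(len(self.chrom_lengths)))

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_lengths)

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    @property
    def total_length(self) -> float:
        return float(self.chrom_lengths.sum())

    def chrom_loci(self, c: int) -> slice:
        """Global-index slice of the loci on chromosome ``c``."""
        lo = self._starts[c]
        hi = self._starts[c + 1] if c + 1 < self.n_chrom else self.n_loci
        return slice(int(lo), int(hi))

    def local_index(self, loci: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map global locus indices to (chromosome, within-chromosome column)."""
        loci = np.asarray(loci)
        c = self.chrom[loci]
        return c, loci - self._starts[c]


@dataclass
class GenomePopulation:
    """Haplotypes, pedigree and generation labels for a set of individuals.

    ``haplotypes[c]`` is a ``(n_individuals, ploidy, n_loci_on_c)`` array of
    allele indices for chromosome ``c``. ``parents`` holds parent ids
    (-1 for founders); parents always precede offspring in id order.
    """

    gmap: GeneticMap
    ploidy: int
    haplotypes: list[np.ndarray]
    ids: np.ndarray
    parents: np.ndarray
    generation: np.ndarray

    def __post_init__(self) -> None:
        if self.ploidy % 2 != 0 or self.ploidy < 2:
            raise ValueError(f"ploidy must be an even integer >= 2, got {self.ploidy}")
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.parents = np.asarray(self.parents, dtype=np.int64).reshape(len(self.ids), 2)
        self.generation = np.asarray(self.generation, dtype=np.int32)
        for c, hap in enumerate(self.haplotypes):
            if hap.shape != (len(self.ids), self.ploidy, self.gmap.chrom_loci(c).stop - self.gmap.chrom_loci(c).start):
                raise ValueError(f"haplotype array for chromosome {c} has shape {hap.shape}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def haplotype_block(self, loci: np.ndarray) -> np.ndarray:
        """Gather haplotypes at the given global loci: ``(n, ploidy, len(loci))``."""
        loci = np.asarray(loci)
        c, col = self.gmap.local_index(loci)
        out = np.empty((self.n, self.ploidy, len(loci)), dtype=np.uint8)
        for cc in np.unique(c):
            sel = c == cc
            out[:, :, sel] = self.haplotypes[cc][:, :, col[sel]]
        return out

    def allele_freqs(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Per-locus allele frequencies, shape ``(n_loci, max_n_alleles)``."""
        if loci is None:
            loci = np.arange(self.gmap.n_loci)
        loci = np.asarray(loci)
        block = self.haplotype_block(loci)
        n_all = int(self.gmap.n_alleles[loci].max())
        freqs = np.empty((len(loci), n_all))
        denom = self.n * self.ploidy
        for a in range(n_all):
            freqs[:, a] = (block == a).sum(axis=(0, 1)) / denom
        return freqs

    def subset(self, idx: np.ndarray) -> "GenomePopulation":
        idx = np.asarray(idx)
        return GenomePopulation(
            gmap=self.gmap,
            ploidy=self.ploidy,
            haplotypes=[h[idx] for h in self.haplotypes],
            ids=self.ids[idx],
            parents=self.parents[idx],
            generation=self.generation[idx],
        )


@dataclass
class LociPanel:
    """QTL/marker split of segregating loci with allele-frequency context.

    ``qtl_seg_alleles[j]`` is the segregating-allele count assigned to QTL
    ``j`` when the panel was drawn. Markers are strictly bi-allelic; the
    counted marker allele is allele index 1 and ``marker_freqs`` holds its
    frequency in the reference population the panel was drawn from. ``n_b``
    is the defined allele count used for effect matrices (shared by all QTL,
    even when not all alleles segregate at a given QTL).
    """

    qtl: np.ndarray
    qtl_seg_alleles: np.ndarray
    markers: np.ndarray
    qtl_freqs: np.ndarray
    marker_freqs: np.ndarray
    n_b: int
    maf_min: float = 0.0

    def __post_init__(self) -> None:
        self.qtl = np.asarray(self.qtl, dtype=np.int64)
        self.markers = np.asarray(self.markers, dtype=np.int64)
        if np.intersect1d(self.qtl, self.markers).size:
            raise ValueError("QTL and marker sets must be disjoint")
        if len(self.qtl) and not np.allclose(self.qtl_freqs.sum(axis=1), 1.0):
            raise ValueError("QTL allele frequencies must sum to 1 per locus")

    @property
    def n_qtl(self) -> int:
        return len(self.qtl)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


# ---------------------------------------------------------------------------
# Map construction
# ---------------------------------------------------------------------------


def random_genetic_map(
    chrom_lengths,
    n_marker_loci: int,
    n_qtl_loci: int,
    qtl_alleles: int = 2,
    rng=None,
) -> GeneticMap:
    """Place marker and QTL candidate loci uniformly at random along the map.

    Marker candidates are defined bi-allelic; QTL candidates carry
    ``qtl_alleles`` defined alleles.
    """
    rng = as_rng(rng)
    chrom_lengths = np.asarray(chrom_lengths, dtype=float)
    n_total = n_marker_loci + n_qtl_loci
    probs = chrom_lengths / chrom_lengths.sum()
    chrom = rng.choice(len(chrom_lengths), size=n_total, p=probs)
    pos = rng.random(n_total) * chrom_lengths[chrom]
    is_qtl = np.zeros(n_total, dtype=bool)
    is_qtl[rng.choice(n_total, size=n_qtl_loci, replace=False)] = True
    n_alleles = np.where(is_qtl, qtl_alleles, 2).astype(np.int16)
    order = np.lexsort((pos, chrom))
    return GeneticMap(chrom_lengths, chrom[order], pos[order], n_alleles[order], is_qtl[order])


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------


def _gamete_batch(
    hap: np.ndarray,
    parent_idx: np.ndarray,
    pos: np.ndarray,
    length_cM: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized bivalent meiosis for one chromosome.

    ``hap`` is ``(n_parents, ploidy, m)``; returns ``(n_gametes, ploidy/2, m)``
    recombinant products, one per bivalent.
    """
    n_par, ploidy, m = hap.shape
    if m == 0:
        raise ValueError("cannot perform meiosis on an empty chromosome")
    parent_idx = np.asarray(parent_idx)
    n_gam = len(parent_idx)
    n_biv = ploidy // 2
    units = n_gam * n_biv

    # random partition of homologs into bivalents, independently per meiosis
    perm = rng.random((n_gam, ploidy)).argsort(axis=1)
    hom_a = perm[:, 0::2].ravel()  # unit order: gamete-major, bivalent-minor
    hom_b = perm[:, 1::2].ravel()
    par_rep = np.repeat(parent_idx, n_biv)

    # Haldane: crossover count per bivalent product ~ Poisson(length in Morgans)
    n_co = rng.poisson(length_cM / 100.0, size=units)
    start = rng.integers(0, 2, size=units, dtype=np.int8)
    total = int(n_co.sum())
    h = np.broadcast_to(start[:, None], (units, m)).copy()
    if total:
        unit_of_event = np.repeat(np.arange(units), n_co)
        xpos = rng.random(total) * length_cM
        bins = np.searchsorted(pos, xpos)
        keep = bins < m
        switches = np.zeros((units, m), dtype=np.int8)
        np.add.at(switches, (unit_of_event[keep], bins[keep]), 1)
        h = (start[:, None] + np.cumsum(switches, axis=1)) & 1

    ha = hap[par_rep, hom_a, :]
    hb = hap[par_rep, hom_b, :]
    gam = np.where(h == 0, ha, hb)
    return gam.reshape(n_gam, n_biv, m)


def meiosis(pop: GenomePopulation, individual: int, rng=None) -> list[np.ndarray]:
    """One gamete from one parent: per-chromosome ``(ploidy/2, m)`` arrays."""
    rng = as_rng(rng)
    out = []
    for c in range(pop.gmap.n_chrom):
        sl = pop.gmap.chrom_loci(c)
        gam = _gamete_batch(
            pop.haplotypes[c], np.array([individual]), pop.gmap.pos[sl], pop.gmap.chrom_lengths[c], rng
        )
        out.append(gam[0])
    return out


def mate(
    pop: GenomePopulation,
    mother_idx: np.ndarray,
    father_idx: np.ndarray,
    rng=None,
    first_id: int | None = None,
    generation: int | None = None,
) -> GenomePopulation:
    """Produce one offspring per (mother, father) pair by uniting two gametes."""
    rng = as_rng(rng)
    mother_idx = np.asarray(mother_idx)
    father_idx = np.asarray(father_idx)
    n_off = len(mother_idx)
    haps = []
    for c in range(pop.gmap.n_chrom):
        sl = pop.gmap.chrom_loci(c)
        pos = pop.gmap.pos[sl]
        length = pop.gmap.chrom_lengths[c]
        gm = _gamete_batch(pop.haplotypes[c], mother_idx, pos, length, rng)
        gf = _gamete_batch(pop.haplotypes[c], father_idx, pos, length, rng)
        haps.append(np.concatenate([gm, gf], axis=1))
    if first_id is None:
        first_id = int(pop.ids.max()) + 1
    gen = generation if generation is not None else int(pop.generation.max()) + 1
    return GenomePopulation(
        gmap=pop.gmap,
        ploidy=pop.ploidy,
        haplotypes=haps,
        ids=np.arange(first_id, first_id + n_off),
        parents=np.column_stack([pop.ids[mother_idx], pop.ids[father_idx]]),
        generation=np.full(n_off, gen),
    )


# ---------------------------------------------------------------------------
# Historical population (Fisher-Wright with recombination, no mutation)
# ---------------------------------------------------------------------------


def _balanced_initial(gmap: GeneticMap, n_ind: int, ploidy: int, rng) -> list[np.ndarray]:
    """Initial haplotypes with (near-)exactly equal allele frequencies."""
    total = n_ind * ploidy
    haps = []
    for c in range(gmap.n_chrom):
        sl = gmap.chrom_loci(c)
        n_all = gmap.n_alleles[sl]
        m = sl.stop - sl.start
        # balanced fill per column, then an independent shuffle per column
        base = (np.arange(total)[:, None] * n_all[None, :].astype(np.int64)) // total
        ranks = rng.random((total, m)).argsort(axis=0)
        arr = np.take_along_axis(base.astype(np.uint8), ranks, axis=0)
        haps.append(arr.reshape(n_ind, ploidy, m))
    return haps


def simulate_historical_population(
    gmap: GeneticMap,
    Ne: int,
    n_generations: int,
    ploidy: int = 2,
    bottleneck: tuple[int, int, int] | None = None,
    rng=None,
    prune_every: int = 25,
) -> GenomePopulation:
    """Random-mating drift with recombination from equal allele frequencies.

    ``bottleneck`` is an optional ``(first_gen, last_gen, Ne_reduced)``
    schedule (generations counted from 1). Returns the final generation of
    ``Ne`` individuals. Loci fixed along the way stay fixed (no mutation) and
    are temporarily dropped from the simulation for speed, then restored in
    the returned population.
    """
    rng = as_rng(rng)
    if ploidy % 2 != 0 or ploidy < 2:
        raise ValueError(f"ploidy must be an even integer >= 2, got {ploidy}")
    if Ne < 2:
        raise ValueError("Ne must be >= 2")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    if bottleneck is not None and bottleneck[2] < 2:
        raise ValueError("bottleneck Ne must be >= 2")

    cur = _balanced_initial(gmap, Ne, ploidy, rng)
    active = [np.arange(h.shape[2]) for h in cur]
    fixed_cols: list[list[np.ndarray]] = [[] for _ in cur]
    fixed_vals: list[list[np.ndarray]] = [[] for _ in cur]

    n_cur = Ne
    for g in range(1, n_generations + 1):
        n_next = Ne
        if bottleneck is not None and bottleneck[0] <= g <= bottleneck[1]:
            n_next = bottleneck[2]
        mothers = rng.integers(0, n_cur, n_next)
        fathers = rng.integers(0, n_cur - 1, n_next)
        fathers[fathers >= mothers] += 1  # random mating without selfing
        for c in range(gmap.n_chrom):
            if cur[c].shape[2] == 0:
                continue
            pos_act = gmap.pos[gmap.chrom_loci(c)][active[c]]
            length = gmap.chrom_lengths[c]
            gm = _gamete_batch(cur[c], mothers, pos_act, length, rng)
            gf = _gamete_batch(cur[c], fathers, pos_act, length, rng)
            cur[c] = np.concatenate([gm, gf], axis=1)
        n_cur = n_next
        if prune_every and g % prune_every == 0 and g < n_generations:
            for c in range(gmap.n_chrom):
                if cur[c].shape[2] == 0:
                    continue
                flat = cur[c].reshape(-1, cur[c].shape[2])
                is_fixed = (flat == flat[0]).all(axis=0)
                if is_fixed.any():
                    fixed_cols[c].append(active[c][is_fixed])
                    fixed_vals[c].append(flat[0, is_fixed].copy())
                    keep = ~is_fixed
                    cur[c] = cur[c][:, :, keep]
                    active[c] = active[c][keep]

    haps = []
    for c in range(gmap.n_chrom):
        sl = gmap.chrom_loci(c)
        m = sl.stop - sl.start
        full = np.empty((n_cur, ploidy, m), dtype=np.uint8)
        full[:, :, active[c]] = cur[c]
        for cols, vals in zip(fixed_cols[c], fixed_vals[c]):
            full[:, :, cols] = vals[None, None, :]
        haps.append(full)
    return GenomePopulation(
        gmap=gmap,
        ploidy=ploidy,
        haplotypes=haps,
        ids=np.arange(n_cur),
        parents=np.full((n_cur, 2), -1),
        generation=np.zeros(n_cur, dtype=np.int32),
    )


def sample_individuals(pop: GenomePopulation, n: int, rng=None) -> GenomePopulation:
    """Random subset of ``n`` individuals (e.g., breeding founders)."""
    rng = as_rng(rng)
    if n > pop.n:
        raise ValueError(f"cannot sample {n} individuals from a population of {pop.n}")
    idx = np.sort(rng.choice(pop.n, size=n, replace=False))
    return pop.subset(idx)


def restrict_to_loci(pop: GenomePopulation, loci: np.ndarray) -> tuple[GenomePopulation, np.ndarray]:
    """Drop all loci except ``loci`` (global indices, any order).

    Returns the restricted population (with a new map) and the positions of
    the requested loci in the new global ordering.
    """
    loci = np.asarray(loci)
    keep = np.unique(loci)
    gmap = pop.gmap
    new_map = GeneticMap(
        gmap.chrom_lengths,
        gmap.chrom[keep],
        gmap.pos[keep],
        gmap.n_alleles[keep],
        gmap.is_qtl_candidate[keep],
    )
    haps = []
    for c in range(gmap.n_chrom):
        sl = gmap.chrom_loci(c)
        sel = keep[(keep >= sl.start) & (keep < sl.stop)] - sl.start
        haps.append(pop.haplotypes[c][:, :, sel])
    new_pop = GenomePopulation(new_map, pop.ploidy, haps, pop.ids, pop.parents, pop.generation)
    remap = np.searchsorted(keep, loci)
    return new_pop, remap


# ---------------------------------------------------------------------------
# Panel selection
# ---------------------------------------------------------------------------


def _class_counts(n_qtl: int, profile: list[tuple[int, float]]) -> list[tuple[int, int]]:
    """Split ``n_qtl`` across allelism classes by largest remainder."""
    if n_qtl == 0:
        return []
    props = np.array([p for _, p in profile], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("allelism profile proportions must sum to 1")
    raw = props * n_qtl
    counts = np.floor(raw).astype(int)
    rem = n_qtl - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return [(c, int(k)) for (c, _), k in zip(profile, counts)]


def select_loci(
    pop: GenomePopulation,
    n_qtl: int,
    n_markers: int,
    maf_min: float,
    allelism_profile: list[tuple[int, float]],
    rng=None,
) -> LociPanel:
    """Draw the QTL and marker panels under MAF and allelism constraints.

    Markers come from the bi-allelic marker-candidate loci with both alleles
    at frequency >= ``maf_min``. A QTL assigned allelism class ``c`` has
    exactly ``c`` alleles at frequency >= ``maf_min`` in the reference
    population ``pop``. Raises a ``ValueError`` naming the deficient class if
    the eligible pools are too small.
    """
    rng = as_rng(rng)
    gmap = pop.gmap
    freqs = pop.allele_freqs()
    seg_count = (freqs >= maf_min).sum(axis=1)

    mk_pool = np.flatnonzero(~gmap.is_qtl_candidate & (seg_count == 2))
    if len(mk_pool) < n_markers:
        raise ValueError(
            f"insufficient eligible marker loci: need {n_markers}, "
            f"have {len(mk_pool)} bi-allelic loci with MAF >= {maf_min}"
        )
    markers = np.sort(rng.choice(mk_pool, size=n_markers, replace=False))

    qtl_sel: list[np.ndarray] = []
    qtl_cls: list[np.ndarray] = []
    for c, k in _class_counts(n_qtl, allelism_profile):
        pool = np.flatnonzero(gmap.is_qtl_candidate & (seg_count == c))
        if len(pool) < k:
            raise ValueError(
                f"insufficient eligible QTL loci for the {c}-allele class: "
                f"need {k}, have {len(pool)} with all {c} alleles at MAF >= {maf_min}"
            )
        chosen = rng.choice(pool, size=k, replace=False)
        qtl_sel.append(chosen)
        qtl_cls.append(np.full(k, c))
    qtl = np.concatenate(qtl_sel) if qtl_sel else np.array([], dtype=np.int64)
    cls = np.concatenate(qtl_cls) if qtl_cls else np.array([], dtype=np.int64)
    order = np.argsort(qtl)
    qtl, cls = qtl[order], cls[order]

    n_b = int(gmap.n_alleles[qtl].max()) if len(qtl) else 2
    qtl_freqs = freqs[qtl][:, :n_b]
    marker_freqs = freqs[markers][:, 1]
    return LociPanel(qtl, cls, markers, qtl_freqs, marker_freqs, n_b, maf_min)


# ---------------------------------------------------------------------------
# Dosages
# ---------------------------------------------------------------------------


def dosage_matrix(pop: GenomePopulation, loci: np.ndarray, n_alleles: int | None = None) -> np.ndarray:
    """Raw allele dosages ``t``: ``(n_individuals, n_loci, n_alleles)`` counts.

    At every (individual, locus) the dosages over alleles sum to the ploidy.
    """
    loci = np.asarray(loci)
    if np.any(loci < 0) or np.any(loci >= pop.gmap.n_loci):
        raise ValueError("unknown locus index")
    block = pop.haplotype_block(loci)
    if n_alleles is None:
        n_alleles = int(pop.gmap.n_alleles[loci].max()) if len(loci) else 2
    out = np.empty((pop.n, len(loci), n_alleles), dtype=np.int16)
    for a in range(n_alleles):
        out[:, :, a] = (block == a).sum(axis=1)
    return out


def marker_dosage(pop: GenomePopulation, panel: LociPanel) -> np.ndarray:
    """Counted-allele (allele 1) dosage at the panel markers: ``(n, n_markers)``."""
    block = pop.haplotype_block(panel.markers)
    return (block == 1).sum(axis=1).astype(np.int16)
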