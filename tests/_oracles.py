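"""Independent brute-force evaluators used as test oracles.

These deliberately use explicit Python loops and the raw covariate formulas,
sharing no code path with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def cov_a(t: float, ploidy: int) -> float:
    return (t - ploidy / 2.0) * (2.0 / ploidy)


def cov_d(t: float, ploidy: int) -> float:
    return t * (ploidy - t) * (2.0 / ploidy) ** 2


def oracle_components(dosage: np.ndarray, effects, ploidy: int) -> dict:
    """Loop-based genotypic-value components (raw, uncentered)."""
    n, n_qtl, n_b = dosage.shape
    out = {k: np.zeros(n) for k in ("a", "d", "aa", "ad", "dd")}
    for i in range(n):
        for j in range(n_qtl):
            for b in range(n_b):
                t = dosage[i, j, b]
                out["a"][i] += cov_a(t, ploidy) * effects.a[b, j]
                out["d"][i] += cov_d(t, ploidy) * effects.d[b, j]
        for e, (k, l) in enumerate(effects.pairs):
            for bl in range(n_b):
                for bk in range(n_b):
                    idx = bl * n_b + bk  # locus-k allele index runs fastest
                    tak = cov_a(dosage[i, k, bk], ploidy)
                    tdk = cov_d(dosage[i, k, bk], ploidy)
                    tal = cov_a(dosage[i, l, bl], ploidy)
                    tdl = cov_d(dosage[i, l, bl], ploidy)
                    out["aa"][i] += tal * tak * effects.aa[idx, e]
                    out["ad"][i] += tdl * tak * effects.ad[idx, e] + tal * tdk * effects.da[idx, e]
                    out["dd"][i] += tdl * tdk * effects.dd[idx, e]
    return out


def oracle_total_g(dosage: np.ndarray, effects, ploidy: int) -> np.ndarray:
    comp = oracle_components(dosage, effects, ploidy)
    return (
        comp["a"]
        - effects.a_offset.sum()
        + comp["d"]
        + comp["aa"]
        + comp["ad"]
        + comp["dd"]
        - effects.nonadd_offset
    )


def random_instance(rng: np.random.Generator, n_b: int, ploidy: int, n_qtl: int, n_ep: int, n: int = 3):
    """A random dosage tensor + effect set for oracle-equivalence checks."""
    from polybreed.traits import EffectSet

    probs = rng.dirichlet(np.ones(n_b), size=(n, n_qtl))
    dosage = np.zeros((n, n_qtl, n_b), dtype=int)
    for i in range(n):
        for j in range(n_qtl):
            dosage[i, j] = rng.multinomial(ploidy, probs[i, j])
    pairs = rng.permutation(n_qtl)[: 2 * n_ep].reshape(n_ep, 2)
    nb2 = n_b * n_b
    effects = EffectSet(
        a=rng.normal(size=(n_b, n_qtl)),
        d=rng.normal(size=(n_b, n_qtl)),
        aa=rng.normal(size=(nb2, n_ep)),
        ad=rng.normal(size=(nb2, n_ep)),
        da=rng.normal(size=(nb2, n_ep)),
        dd=rng.normal(size=(nb2, n_ep)),
        pairs=pairs,
        a_offset=rng.normal(size=n_qtl),
        nonadd_offset=float(rng.normal()),
    )
    return dosage, effects
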