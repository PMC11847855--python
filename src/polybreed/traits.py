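"""Genotypic-effect models for multi-allelic QTL at arbitrary even ploidy.

Locus-level model: with raw allele dosages ``t`` (counts of each allele,
summing to the ploidy), the additive genotypic value of a locus is
``a = sum_i t_a(t_i) * a_i`` with the scaled covariate
``t_a = (t - ploidy/2) * (2/ploidy)``, and the (digenic) dominance value is
``d = sum_i t_d(t_i) * d_i`` with ``t_d = t*(ploidy-t)*(2/ploidy)**2``. For
bi-allelic diploids this reduces to the textbook -a/0/+a coding with
``a = a2 - a1`` the substitution effect.

Two-locus epistasis for a designated pair (k, l) uses Kronecker products of
the per-locus covariate vectors with per-allele-pair effect vectors of length
``n_b**2``: additive x additive, additive x dominance plus dominance x
additive, and dominance x dominance. Element order in all ``n_b**2`` vectors
runs with the locus-k allele index fastest.

Functional effects are sampled, centered and rescaled on the founder
population so that each variance component hits its user-defined functional
variance exactly; they are then frozen for all later generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng
from .genome import GenomePopulation, LociPanel, dosage_matrix

__all__ = [
    "TraitModel",
    "EffectSet",
    "GeneticValues",
    "additive_covariate",
    "dominance_covariate",
    "locus_values",
    "epistatic_pair_values",
    "total_genetic_value",
    "generate_effects",
    "functional_variance",
    "simulate_phenotypes",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TraitModel:
    """Functional variance targets and the dominance-degree distribution.

    All variances are in squared trait units. ``dominance_degree`` is the
    (mean, variance) of the normal distribution the per-allele dominance
    degrees are drawn from; the default (0.19, 0.097) gives mostly partial,
    positive dominance. ``rescale_method`` chooses how the founder functional
    variance of each component is measured when effects are rescaled:
    ``by_individual`` (variance of component totals across founders; captures
    between-locus LD covariance) or ``by_locus`` (sum of per-locus variances).
    """

    sigma_a2: float = 1.0
    sigma_d2: float = 0.0
    sigma_aa2: float = 0.0
    sigma_ad2: float = 0.0
    sigma_dd2: float = 0.0
    sigma_e2: float = 1.0
    dominance_degree: tuple[float, float] = (0.19, 0.097)
    rescale_method: str = "by_locus"

    def __post_init__(self) -> None:
        for name in ("sigma_a2", "sigma_d2", "sigma_aa2", "sigma_ad2", "sigma_dd2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dominance_degree[1] < 0:
            raise ValueError("dominance-degree variance must be >= 0")
        if self.rescale_method not in ("by_individual", "by_locus"):
            raise ValueError(f"unknown rescale_method {self.rescale_method!r}")


@dataclass
class EffectSet:
    """Functional allele effects, the epistatic pair map and centering offsets.

    ``a`` and ``d`` are ``(n_b, n_qtl)``; the four epistatic matrices are
    ``(n_b**2, n_ep)`` with locus-k-fastest element order. ``pairs`` holds
    (k, l) as indices into the QTL panel, each QTL in at most one pair.
    ``a_offset[j]`` is the founder mean of the raw additive value at QTL j
    (per-locus centering); ``nonadd_offset`` is the founder mean of the summed
    dominance + epistatic values (the total is centered through it, matching a
    model where only additive effects are centered per locus). ``mu`` is the
    founder population mean of the raw total genotypic value.
    """

    a: np.ndarray
    d: np.ndarray
    aa: np.ndarray
    ad: np.ndarray
    da: np.ndarray
    dd: np.ndarray
    pairs: np.ndarray
    a_offset: np.ndarray
    nonadd_offset: float = 0.0

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        n_b, n_qtl = self.a.shape
        if self.d.shape != (n_b, n_qtl):
            raise ValueError("a and d must have the same shape")
        n_ep = self.pairs.shape[0]
        for name in ("aa", "ad", "da", "dd"):
            m = getattr(self, name)
            if m.shape != (n_b * n_b, n_ep):
                raise ValueError(f"{name} must have shape ({n_b * n_b}, {n_ep})")
        flat = self.pairs.ravel()
        if len(np.unique(flat)) != len(flat):
            raise ValueError("each QTL may appear in at most one epistatic pair")
        if len(flat) and (flat.min() < 0 or flat.max() >= n_qtl):
            raise ValueError("pair indices out of range")

    @property
    def n_b(self) -> int:
        return self.a.shape[0]

    @property
    def n_qtl(self) -> int:
        return self.a.shape[1]

    @property
    def n_ep(self) -> int:
        return self.pairs.shape[0]

    @property
    def mu(self) -> float:
        """Founder mean of the raw (uncentered) total genotypic value."""
        return float(self.a_offset.sum() + self.nonadd_offset)


@dataclass
class GeneticValues:
    """Per-individual genotypic value components (founder-centered)."""

    a_total: np.ndarray
    d_total: np.ndarray
    aa_total: np.ndarray
    ad_total: np.ndarray
    dd_total: np.ndarray
    nonadd_offset: float = 0.0

    @property
    def g(self) -> np.ndarray:
        """Total genotypic value, zero-mean in the founder population."""
        return (
            self.a_total
            + self.d_total
            + self.aa_total
            + self.ad_total
            + self.dd_total
            - self.nonadd_offset
        )


# ---------------------------------------------------------------------------
# Covariates and locus-level values
# ---------------------------------------------------------------------------


def _check_dosage(t, ploidy: int) -> np.ndarray:
    t = np.asarray(t)
    if np.any(t < 0) or np.any(t > ploidy):
        raise ValueError(f"raw dosage must lie in [0, {ploidy}]")
    return t


def additive_covariate(t, ploidy: int):
    """Scaled additive dosage ``(t - ploidy/2) * (2/ploidy)``, in [-1, 1]."""
    t = _check_dosage(t, ploidy)
    return (t - ploidy / 2.0) * (2.0 / ploidy)


def dominance_covariate(t, ploidy: int):
    """Scaled digenic-dominance dosage ``t*(ploidy-t)*(2/ploidy)**2``, in [0, 1]."""
    t = _check_dosage(t, ploidy)
    return t * (ploidy - t) * (2.0 / ploidy) ** 2


def locus_values(dosages, a_col, d_col, ploidy: int) -> tuple[float, float]:
    """Additive and dominance genotypic values of one locus."""
    dosages = np.asarray(dosages, dtype=float)
    a_col = np.asarray(a_col, dtype=float)
    d_col = np.asarray(d_col, dtype=float)
    if dosages.shape != a_col.shape or dosages.shape != d_col.shape:
        raise ValueError("dosage and effect vectors must have equal length")
    if not np.isclose(dosages.sum(), ploidy):
        raise ValueError(f"dosages must sum to the ploidy ({ploidy})")
    ta = additive_covariate(dosages, ploidy)
    td = dominance_covariate(dosages, ploidy)
    return float(ta @ a_col), float(td @ d_col)


def _kron_lk(v_l: np.ndarray, v_k: np.ndarray) -> np.ndarray:
    # element index runs with the locus-k allele fastest: i = i_l * n_b + i_k
    return np.kron(v_l, v_k)


def epistatic_pair_values(
    dosages_k, dosages_l, aa_col, ad_col, da_col, dd_col, ploidy: int
) -> tuple[float, float, float]:
    """Epistatic genotypic values (aa, ad + da, dd) for one pair of loci."""
    dk = np.asarray(dosages_k, dtype=float)
    dl = np.asarray(dosages_l, dtype=float)
    n_b = len(dk)
    for name, col in (("aa", aa_col), ("ad", ad_col), ("da", da_col), ("dd", dd_col)):
        if np.asarray(col).shape != (n_b * n_b,):
            raise ValueError(f"{name} effect vector must have length n_b**2 = {n_b * n_b}")
    ta_k, td_k = additive_covariate(dk, ploidy), dominance_covariate(dk, ploidy)
    ta_l, td_l = additive_covariate(dl, ploidy), dominance_covariate(dl, ploidy)
    aa = _kron_lk(ta_l, ta_k) @ np.asarray(aa_col, dtype=float)
    ad_da = _kron_lk(td_l, ta_k) @ np.asarray(ad_col, dtype=float) + _kron_lk(ta_l, td_k) @ np.asarray(
        da_col, dtype=float
    )
    dd = _kron_lk(td_l, td_k) @ np.asarray(dd_col, dtype=float)
    return float(aa), float(ad_da), float(dd)


# ---------------------------------------------------------------------------
# Individual totals
# ---------------------------------------------------------------------------


def _covariate_tensors(dosage: np.ndarray, ploidy: int) -> tuple[np.ndarray, np.ndarray]:
    """Additive/dominance covariate tensors from a (n, n_qtl, n_b) dosage tensor."""
    t = dosage.astype(float)
    ta = (t - ploidy / 2.0) * (2.0 / ploidy)
    td = t * (ploidy - t) * (2.0 / ploidy) ** 2
    return ta, td


def _component_totals(dosage: np.ndarray, effects: EffectSet, ploidy: int) -> dict[str, np.ndarray]:
    """Raw (uncentered) per-individual totals of every component."""
    n = dosage.shape[0]
    ta, td = _covariate_tensors(dosage, ploidy)
    out = {
        "a": np.einsum("njb,bj->n", ta, effects.a),
        "d": np.einsum("njb,bj->n", td, effects.d),
    }
    if effects.n_ep:
        k, l = effects.pairs[:, 0], effects.pairs[:, 1]
        n_b = effects.n_b

        def pair_cov(vl: np.ndarray, vk: np.ndarray) -> np.ndarray:
            # (n, n_ep, n_b**2) with locus-k allele index fastest
            return (vl[:, l, :, None] * vk[:, k, None, :]).reshape(n, effects.n_ep, n_b * n_b)

        out["aa"] = np.einsum("nei,ie->n", pair_cov(ta, ta), effects.aa)
        out["ad"] = np.einsum("nei,ie->n", pair_cov(td, ta), effects.ad) + np.einsum(
            "nei,ie->n", pair_cov(ta, td), effects.da
        )
        out["dd"] = np.einsum("nei,ie->n", pair_cov(td, td), effects.dd)
    else:
        z = np.zeros(n)
        out["aa"], out["ad"], out["dd"] = z, z.copy(), z.copy()
    return out


def total_genetic_value(dosage: np.ndarray, effects: EffectSet, ploidy: int) -> GeneticValues:
    """Genotypic value components for a batch of individuals.

    ``dosage`` is the ``(n, n_qtl, n_b)`` raw dosage tensor over the QTL
    panel, in the same QTL order as ``effects``.
    """
    dosage = np.asarray(dosage)
    if dosage.ndim != 3 or dosage.shape[1] != effects.n_qtl or dosage.shape[2] != effects.n_b:
        raise ValueError(
            f"dosage tensor must be (n, {effects.n_qtl}, {effects.n_b}), got {dosage.shape}"
        )
    raw = _component_totals(dosage, effects, ploidy)
    # per-locus additive values need per-locus centering; subtract summed offsets
    return GeneticValues(
        a_total=raw["a"] - effects.a_offset.sum(),
        d_total=raw["d"],
        aa_total=raw["aa"],
        ad_total=raw["ad"],
        dd_total=raw["dd"],
        nonadd_offset=effects.nonadd_offset,
    )


# ---------------------------------------------------------------------------
# Effect generation: sampling -> centering -> rescaling on the founders
# ---------------------------------------------------------------------------


def _founder_variance(values: np.ndarray, method: str) -> float:
    """Founder functional variance of per-locus (or per-pair) values.

    ``values`` is (n_founders, n_terms): per-locus or per-pair genotypic
    values. ``by_individual`` takes the variance of row sums (totals across
    terms, including LD covariance); ``by_locus`` sums per-term variances.
    """
    if method == "by_individual":
        return float(values.sum(axis=1).var())
    if method == "by_locus":
        return float(values.var(axis=0).sum())
    raise ValueError(f"unknown rescale method {method!r}")


def _rescale(prior: float, target: float, what: str) -> float:
    if target == 0.0:
        return 0.0
    if prior <= 0.0:
        raise ValueError(
            f"cannot rescale {what} effects: realized prior variance is zero "
            f"but the target variance is {target}"
        )
    return float(np.sqrt(target / prior))


def generate_effects(
    founders: GenomePopulation,
    panel: LociPanel,
    trait: TraitModel,
    n_ep: int = 0,
    rng=None,
) -> EffectSet:
    """Sample, center and rescale functional effects on the founder haplotypes.

    Additive effects are sampled N(0, sigma_a2) per allele, centered per locus
    (the founder mean of every locus's additive value becomes zero) and
    rescaled so the realized founder additive variance equals ``sigma_a2``
    exactly under the chosen rescale method. Dominance effects come from
    per-allele dominance degrees ``delta ~ N(mu_delta, sigma_delta2)`` as
    ``d* = delta * a`` (proportional to the rescaled additive effect, the
    mean degree giving directional dominance) and are rescaled to
    ``sigma_d2``. Epistatic effect vectors are sampled and rescaled per
    component; additive x dominance and dominance x additive are rescaled
    jointly so their summed value hits ``sigma_ad2``. Dominance and epistatic
    components are not centered individually; the total is centered through
    the founder-mean offset so founder mean g = 0.

    ``n_ep`` epistatic pairs are drawn as random disjoint QTL pairs (a random
    perfect matching when ``n_ep == n_qtl // 2``).
    """
    rng = as_rng(rng)
    if founders.n == 0:
        raise ValueError("founder population is empty")
    n_b, n_qtl = panel.n_b, panel.n_qtl
    if 2 * n_ep > n_qtl:
        raise ValueError(f"cannot form {n_ep} disjoint pairs from {n_qtl} QTL")

    dosage = dosage_matrix(founders, panel.qtl, n_alleles=n_b)
    ta, td = _covariate_tensors(dosage, founders.ploidy)

    # --- additive: sample, rescale to target, then record per-locus centering offsets
    a_s = rng.normal(0.0, np.sqrt(trait.sigma_a2), size=(n_b, n_qtl))
    vals = np.einsum("njb,bj->nj", ta, a_s)
    vals_c = vals - vals.mean(axis=0, keepdims=True)
    scale_a = _rescale(_founder_variance(vals_c, trait.rescale_method), trait.sigma_a2, "additive")
    a = a_s * scale_a

    # --- dominance: degrees times |a|, rescaled
    delta = rng.normal(trait.dominance_degree[0], np.sqrt(trait.dominance_degree[1]), size=(n_b, n_qtl))
    d_s = delta * a
    d_vals = np.einsum("njb,bj->nj", td, d_s)
    scale_d = _rescale(
        _founder_variance(d_vals, trait.rescale_method) if trait.sigma_d2 > 0 else 1.0,
        trait.sigma_d2,
        "dominance",
    )
    d = d_s * scale_d

    # --- epistatic pairs
    pairs = rng.permutation(n_qtl)[: 2 * n_ep].reshape(n_ep, 2)
    nb2 = n_b * n_b
    if n_ep:
        k, l = pairs[:, 0], pairs[:, 1]
        n = founders.n

        def pair_cov(vl: np.ndarray, vk: np.ndarray) -> np.ndarray:
            return (vl[:, l, :, None] * vk[:, k, None, :]).reshape(n, n_ep, nb2)

        cov_aa = pair_cov(ta, ta)
        cov_ad = pair_cov(td, ta)
        cov_da = pair_cov(ta, td)
        cov_dd = pair_cov(td, td)

        aa_s = rng.normal(0.0, np.sqrt(trait.sigma_aa2), size=(nb2, n_ep))
        aa_vals = np.einsum("nei,ie->ne", cov_aa, aa_s)
        aa = aa_s * _rescale(
            _founder_variance(aa_vals, trait.rescale_method) if trait.sigma_aa2 > 0 else 1.0,
            trait.sigma_aa2,
            "additive x additive",
        )

        ad_s = rng.normal(0.0, np.sqrt(trait.sigma_ad2), size=(nb2, n_ep))
        da_s = rng.normal(0.0, np.sqrt(trait.sigma_ad2), size=(nb2, n_ep))
        ad_vals = np.einsum("nei,ie->ne", cov_ad, ad_s) + np.einsum("nei,ie->ne", cov_da, da_s)
        scale_ad = _rescale(
            _founder_variance(ad_vals, trait.rescale_method) if trait.sigma_ad2 > 0 else 1.0,
            trait.sigma_ad2,
            "additive-dominance",
        )
        ad, da = ad_s * scale_ad, da_s * scale_ad

        dd_s = rng.normal(0.0, np.sqrt(trait.sigma_dd2), size=(nb2, n_ep))
        dd_vals = np.einsum("nei,ie->ne", cov_dd, dd_s)
        dd = dd_s * _rescale(
            _founder_variance(dd_vals, trait.rescale_method) if trait.sigma_dd2 > 0 else 1.0,
            trait.sigma_dd2,
            "dominance x dominance",
        )
    else:
        aa = ad = da = dd = np.zeros((nb2, 0))

    effects = EffectSet(
        a=a, d=d, aa=aa, ad=ad, da=da, dd=dd, pairs=pairs,
        a_offset=np.zeros(n_qtl), nonadd_offset=0.0,
    )
    # centering offsets from the final effects on the founders
    a_vals = np.einsum("njb,bj->nj", ta, a)
    effects.a_offset = a_vals.mean(axis=0)
    raw = _component_totals(dosage, effects, founders.ploidy)
    effects.nonadd_offset = float((raw["d"] + raw["aa"] + raw["ad"] + raw["dd"]).mean())
    return effects


def functional_variance(
    component: str,
    effects: EffectSet,
    founders: GenomePopulation,
    panel: LociPanel,
    method: str = "by_locus",
) -> float:
    """Realized founder functional variance of one component.

    ``component`` is one of additive, dominance, aa, ad, dd. ``by_locus``
    sums per-locus (or per-pair) variances and so ignores between-locus LD
    covariance; ``by_individual`` is the variance of the component totals.
    """
    if method not in ("by_individual", "by_locus"):
        raise ValueError(f"unknown method {method!r}")
    dosage = dosage_matrix(founders, panel.qtl, n_alleles=effects.n_b)
    ta, td = _covariate_tensors(dosage, founders.ploidy)
    n = founders.n
    if component in ("additive", "a"):
        vals = np.einsum("njb,bj->nj", ta, effects.a)
    elif component in ("dominance", "d"):
        vals = np.einsum("njb,bj->nj", td, effects.d)
    elif component in ("aa", "ad", "dd"):
        if effects.n_ep == 0:
            return 0.0
        k, l = effects.pairs[:, 0], effects.pairs[:, 1]
        nb2 = effects.n_b ** 2

        def pair_cov(vl, vk):
            return (vl[:, l, :, None] * vk[:, k, None, :]).reshape(n, effects.n_ep, nb2)

        if component == "aa":
            vals = np.einsum("nei,ie->ne", pair_cov(ta, ta), effects.aa)
        elif component == "dd":
            vals = np.einsum("nei,ie->ne", pair_cov(td, td), effects.dd)
        else:
            vals = np.einsum("nei,ie->ne", pair_cov(td, ta), effects.ad) + np.einsum(
                "nei,ie->ne", pair_cov(ta, td), effects.da
            )
    else:
        raise ValueError(f"unknown component {component!r}")
    if component in ("additive", "a"):
        vals = vals - vals.mean(axis=0, keepdims=True)
    return _founder_variance(vals, method)


def simulate_phenotypes(g: np.ndarray, mu: float, sigma_e2: float, rng=None) -> np.ndarray:
    """Phenotypes ``y = mu + g + e`` with ``e ~ N(0, sigma_e2)`` iid."""
    rng = as_rng(rng)
    if sigma_e2 < 0:
        raise ValueError("sigma_e2 must be >= 0")
    g = np.asarray(g, dtype=float)
    return mu + g + rng.normal(0.0, np.sqrt(sigma_e2), size=g.shape)
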