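"""Breeding-scheme orchestration: crossing, selection, generation loop, metrics.

The simulated program runs discrete generations. Each generation, parents are
crossed pseudo-randomly (no selfing, a cap on how many crosses a parent may
enter) into full-sib families. Offspring are phenotyped and genotyped; up to
a switch generation parents are selected at random, afterwards by truncation
on GBLUP-predicted breeding values. Variance components are estimated by REML
once, when the accumulated phenotype records reach the evaluation generation,
and reused in later evaluations. Reported metrics are the prediction accuracy
(Pearson correlation of true and predicted breeding values of the selection
candidates at the REML generation) and the rate of genetic gain (change in
the population genetic mean over the selection generations, per generation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from ._rng import as_rng
from .genome import GenomePopulation, LociPanel, dosage_matrix, marker_dosage, mate
from .gblup import GRM, additive_grm, dominance_grm, epistatic_grms, reml_estimate, solve_gblup
from .gblup import _spectral_reml
from .traits import EffectSet, TraitModel, simulate_phenotypes, total_genetic_value

__all__ = [
    "BreedingConfig",
    "Trajectory",
    "make_crosses",
    "advance_generation",
    "select_parents",
    "run_breeding_scheme",
    "accuracy",
    "rate_of_gain",
]

SELECTION_MODELS = ("additive", "additive_dominance", "additive_dominance_epistasis")


@dataclass
class BreedingConfig:
    """Parameters of the breeding program and its genetic evaluation."""

    trait: TraitModel = field(default_factory=TraitModel)
    n_parents: int = 80
    n_families: int = 80
    family_size: int = 10
    max_contrib: int = 4
    no_selfing: bool = True
    n_generations: int = 13
    random_selection_until: int = 5
    reml_at_generation: int = 6
    selection_model: str = "additive"
    ploidy: int = 2
    allelism_profile: list = field(default_factory=lambda: [(2, 1.0)])
    n_ep: int = 0
    n_founders: int = 100

    def __post_init__(self) -> None:
        if self.selection_model not in SELECTION_MODELS:
            raise ValueError(f"selection_model must be one of {SELECTION_MODELS}")
        if 2 * self.n_families > self.max_contrib * self.n_parents:
            raise ValueError(
                f"infeasible crossing design: {self.n_families} families need "
                f"{2 * self.n_families} parent slots but {self.n_parents} parents "
                f"with contribution cap {self.max_contrib} provide only "
                f"{self.max_contrib * self.n_parents}"
            )
        if self.n_parents > self.n_families * self.family_size:
            raise ValueError("cannot select more parents than offspring per generation")
        if not (0 < self.random_selection_until < self.reml_at_generation <= self.n_generations):
            raise ValueError("need 0 < random_selection_until < reml_at_generation <= n_generations")

    @property
    def offspring_per_generation(self) -> int:
        return self.n_families * self.family_size


@dataclass
class Trajectory:
    """Per-generation summaries and the headline metrics of one replicate."""

    table: pd.DataFrame
    accuracy: float
    gain_u: float
    gain_g: float
    reml_variances: dict
    reml_sigma_e2: float
    reml_converged: bool
    model_used: str
    events: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Crossing and selection
# ---------------------------------------------------------------------------


def make_crosses(
    parents: np.ndarray,
    n_families: int,
    max_contrib: int = 4,
    no_selfing: bool = True,
    rng=None,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Pseudo-random cross plan: ``(n_families, 2)`` parent ids.

    No pair mates an individual with itself when ``no_selfing``; every parent
    appears in at most ``max_contrib`` crosses. Sampled by rejection: parents
    are drawn uniformly among those with remaining capacity, restarting the
    plan on a dead end.
    """
    rng = as_rng(rng)
    parents = np.asarray(parents)
    n_par = len(parents)
    if 2 * n_families > max_contrib * n_par:
        raise ValueError(
            f"infeasible: {n_families} families need {2 * n_families} slots, "
            f"{n_par} parents x cap {max_contrib} provide {max_contrib * n_par}"
        )
    if no_selfing and n_par < 2:
        raise ValueError("need at least two parents when selfing is excluded")
    for _ in range(max_attempts):
        cap = np.full(n_par, max_contrib)
        plan = np.empty((n_families, 2), dtype=np.int64)
        ok = True
        for fam in range(n_families):
            avail = np.flatnonzero(cap > 0)
            if len(avail) == 0:
                ok = False
                break
            mother = avail[rng.integers(len(avail))]
            pool = avail[avail != mother] if no_selfing else avail
            if len(pool) == 0:
                ok = False
                break
            father = pool[rng.integers(len(pool))]
            cap[mother] -= 1
            cap[father] -= 1
            plan[fam] = (mother, father)
        if ok:
            return parents[plan]
    raise RuntimeError("failed to sample a feasible cross plan")


def select_parents(candidates: np.ndarray, criterion: str, ebvs, n: int, rng=None) -> np.ndarray:
    """Choose ``n`` parents: uniformly at random, or the top-n by EBV.

    EBV ties are broken by ascending candidate id (deterministic).
    """
    candidates = np.asarray(candidates)
    if n > len(candidates):
        raise ValueError(f"cannot select {n} parents from {len(candidates)} candidates")
    if criterion == "random":
        rng = as_rng(rng)
        return np.sort(rng.choice(candidates, size=n, replace=False))
    if criterion == "ebv":
        if ebvs is None:
            raise ValueError("EBV selection requested but no EBVs supplied")
        ebvs = np.asarray(ebvs, dtype=float)
        if ebvs.shape != candidates.shape:
            raise ValueError("EBV vector must match the candidate list")
        order = np.lexsort((candidates, -ebvs))
        return candidates[order[:n]]
    raise ValueError(f"unknown selection criterion {criterion!r}")


def advance_generation(
    parents_pop: GenomePopulation,
    cross_plan_idx: np.ndarray,
    family_size: int,
    panel: LociPanel,
    effects: EffectSet,
    trait: TraitModel,
    rng=None,
    first_id: int | None = None,
    generation: int | None = None,
):
    """Create one generation of full-sib families and phenotype it.

    ``cross_plan_idx`` holds positional (mother, father) indices into
    ``parents_pop``. Returns ``(offspring, genetic_values, phenotypes)``.
    """
    rng = as_rng(rng)
    plan = np.asarray(cross_plan_idx).reshape(-1, 2)
    mothers = np.repeat(plan[:, 0], family_size)
    fathers = np.repeat(plan[:, 1], family_size)
    offspring = mate(parents_pop, mothers, fathers, rng, first_id=first_id, generation=generation)
    dos = dosage_matrix(offspring, panel.qtl, n_alleles=effects.n_b)
    gv = total_genetic_value(dos, effects, offspring.ploidy)
    y = simulate_phenotypes(gv.g, 0.0, trait.sigma_e2, rng)
    return offspring, gv, y


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def accuracy(true_u: np.ndarray, predicted_u: np.ndarray) -> float:
    """Pearson correlation between true and predicted breeding values."""
    true_u = np.asarray(true_u, dtype=float)
    predicted_u = np.asarray(predicted_u, dtype=float)
    if true_u.shape != predicted_u.shape:
        raise ValueError("vectors must have the same length")
    if true_u.std() == 0.0 or predicted_u.std() == 0.0:
        warnings.warn("zero variance in true or predicted values; accuracy undefined")
        return float("nan")
    return float(np.corrcoef(true_u, predicted_u)[0, 1])


def rate_of_gain(mean_early: float, mean_late: float, n_generations: int = 8) -> float:
    """Genetic gain per generation between two population means."""
    return (mean_late - mean_early) / n_generations


# ---------------------------------------------------------------------------
# Genetic evaluation helpers
# ---------------------------------------------------------------------------


class _AdditiveEvaluator:
    """Incremental marker-space GBLUP for the additive-only model.

    Exactly equivalent to GBLUP with the VanRaden G built from the same
    markers (marker-effect form of the mixed-model equations); the normal
    equations are accumulated generation by generation so each evaluation
    costs one (m + n_gen) solve. Marker allele frequencies are frozen when
    the evaluator is first frozen (at the REML generation) so that G keeps a
    constant scale for the variance components estimated then.
    """

    def __init__(self, ploidy: int):
        self.ploidy = ploidy
        self.p = None
        self.keep = None
        self.denom = None
        self.wtw = None
        self.wty = None
        self.gen_counts: dict[int, int] = {}
        self.gen_wsum: dict[int, np.ndarray] = {}
        self.gen_ysum: dict[int, float] = {}

    def freeze(self, dosage_rows: np.ndarray) -> None:
        p = dosage_rows.mean(axis=0) / self.ploidy
        self.keep = (p > 0.0) & (p < 1.0)
        self.p = p[self.keep]
        self.denom = self.ploidy * float((self.p * (1.0 - self.p)).sum())

    def center(self, dosage_rows: np.ndarray) -> np.ndarray:
        return dosage_rows[:, self.keep] - self.ploidy * self.p

    def add(self, gen: int, dosage_rows: np.ndarray, y: np.ndarray) -> None:
        w = self.center(dosage_rows.astype(float))
        if self.wtw is None:
            m = w.shape[1]
            self.wtw = np.zeros((m, m))
            self.wty = np.zeros(m)
        self.wtw += w.T @ w
        self.wty += w.T @ y
        self.gen_counts[gen] = self.gen_counts.get(gen, 0) + len(y)
        self.gen_wsum[gen] = self.gen_wsum.get(gen, 0.0) + w.sum(axis=0)
        self.gen_ysum[gen] = self.gen_ysum.get(gen, 0.0) + float(y.sum())

    def solve(self, sigma_u2: float, sigma_e2: float, candidate_dosage: np.ndarray) -> np.ndarray:
        """BLUP breeding values for the candidate rows."""
        gens = sorted(self.gen_counts)
        n_g = len(gens)
        m = self.wtw.shape[0]
        c = np.zeros((n_g + m, n_g + m))
        rhs = np.zeros(n_g + m)
        for i, g in enumerate(gens):
            c[i, i] = self.gen_counts[g]
            c[i, n_g:] = self.gen_wsum[g]
            c[n_g:, i] = self.gen_wsum[g]
            rhs[i] = self.gen_ysum[g]
        c[n_g:, n_g:] = self.wtw
        # u = W beta with beta ~ N(0, I sigma_u2 / denom)
        c[np.arange(n_g, n_g + m), np.arange(n_g, n_g + m)] += sigma_e2 * self.denom / sigma_u2
        rhs[n_g:] = self.wty
        sol = linalg.solve(c, rhs, assume_a="pos")
        beta = sol[n_g:]
        return self.center(candidate_dosage.astype(float)) @ beta


def _grm_set(dosage_rows: np.ndarray, ploidy: int, p_frozen: np.ndarray, model: str) -> dict[str, GRM]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gu = additive_grm(dosage_rows, ploidy, freqs=p_frozen)
        grms = {"u": gu}
        if model in ("additive_dominance", "additive_dominance_epistasis"):
            gv = dominance_grm(dosage_rows, ploidy, freqs=p_frozen)
            grms["v"] = gv
            if model == "additive_dominance_epistasis":
                guu, guv, gvv = epistatic_grms(gu, gv)
                grms.update({"uu": guu, "uv": guv, "vv": gvv})
    return grms


_FALLBACK = {
    "additive_dominance_epistasis": "additive_dominance",
    "additive_dominance": "additive",
}


# ---------------------------------------------------------------------------
# Generation loop
# ---------------------------------------------------------------------------


def run_breeding_scheme(
    config: BreedingConfig,
    founders: GenomePopulation,
    panel: LociPanel,
    effects: EffectSet,
    rng=None,
) -> Trajectory:
    """Run one replicate of the breeding program and collect its trajectory.

    ``founders`` (generation 0) supply the first parents by random selection.
    Phenotypes and marker genotypes of generations 1 up to the current
    generation enter each genetic evaluation, with generation as the only
    fixed effect; REML runs once, at the evaluation generation, on the
    records accumulated before it, and its variance components are reused
    afterwards. If REML does not converge for the configured prediction
    model, progressively simpler models are tried (logged in ``events``).
    """
    rng = as_rng(rng)
    if founders.n < config.n_parents:
        raise ValueError("founder population smaller than the number of parents")

    events: list[str] = []
    additive_only = config.selection_model == "additive"
    evaluator = _AdditiveEvaluator(config.ploidy) if additive_only else None

    mk_rows: list[np.ndarray] = []
    y_rows: list[np.ndarray] = []
    gen_rows: list[np.ndarray] = []
    u_rows: list[np.ndarray] = []

    # generation 0 -> first parents: random handoff from the founders
    sel_idx = np.sort(rng.choice(founders.n, size=config.n_parents, replace=False))
    parents_pop = founders.subset(sel_idx)
    next_id = int(founders.ids.max()) + 1

    traj_rows = []
    acc = float("nan")
    reml_info = {"variances": {}, "sigma_e2": float("nan"), "converged": False, "model": ""}
    p_frozen = None
    ebv_cur = None

    for g in range(1, config.n_generations + 1):
        plan_ids = make_crosses(
            np.arange(parents_pop.n), config.n_families, config.max_contrib, config.no_selfing, rng
        )
        offspring, gv, y = advance_generation(
            parents_pop, plan_ids, config.family_size, panel, effects, config.trait, rng,
            first_id=next_id, generation=g,
        )
        next_id = int(offspring.ids.max()) + 1
        mk = marker_dosage(offspring, panel)
        u_true = gv.a_total
        g_true = gv.g

        mk_rows.append(mk)
        y_rows.append(y)
        gen_rows.append(np.full(len(y), g))
        u_rows.append(u_true)
        traj_rows.append(
            {
                "generation": g,
                "n": len(y),
                "mean_u": float(u_true.mean()),
                "var_u": float(u_true.var()),
                "mean_g": float(g_true.mean()),
                "var_g": float(g_true.var()),
            }
        )

        ebv_cur = None
        # evaluate when EBVs will be used for selection (g < n_generations)
        # and at the REML generation itself, where accuracy is recorded
        needs_eval = g >= config.reml_at_generation and (
            g < config.n_generations or g == config.reml_at_generation
        )
        if needs_eval:
            if g == config.reml_at_generation:
                # REML on the records accumulated before this generation
                hist_mk = np.vstack(mk_rows[:-1])
                hist_y = np.concatenate(y_rows[:-1])
                hist_gen = np.concatenate(gen_rows[:-1])
                if additive_only:
                    evaluator.freeze(hist_mk)
                    phen_x = (hist_gen[:, None] == np.unique(hist_gen)[None, :]).astype(float)
                    f = evaluator.center(hist_mk.astype(float)) / np.sqrt(evaluator.denom)
                    su2, se2, ll, ok, boundary, _log = _spectral_reml(hist_y, phen_x, f, 200, 1e-8)
                    reml_info = {
                        "variances": {"u": su2},
                        "sigma_e2": se2,
                        "converged": ok and not boundary,
                        "model": "additive",
                    }
                    if not reml_info["converged"]:
                        events.append("additive REML hit a boundary or failed to converge")
                    for gg in sorted(set(hist_gen)):
                        sel = hist_gen == gg
                        evaluator.add(int(gg), hist_mk[sel], hist_y[sel])
                else:
                    p_frozen = hist_mk.mean(axis=0) / config.ploidy
                    model = config.selection_model
                    while True:
                        grms = _grm_set(hist_mk, config.ploidy, p_frozen, model)
                        method = "spectral" if model == "additive" else "ai"
                        fit = reml_estimate(hist_y, hist_gen, grms, method=method, max_iter=100)
                        if fit.converged or model == "additive":
                            break
                        events.append(f"REML for model {model!r} did not converge; falling back")
                        model = _FALLBACK[model]
                    reml_info = {
                        "variances": fit.variances,
                        "sigma_e2": fit.sigma_e2,
                        "converged": fit.converged,
                        "model": model,
                    }

            # evaluation with all records up to and including generation g
            if additive_only:
                evaluator.add(g, mk, y)
                ebv_cur = evaluator.solve(
                    max(reml_info["variances"]["u"], 1e-8), reml_info["sigma_e2"], mk
                )
            else:
                all_mk = np.vstack(mk_rows)
                all_y = np.concatenate(y_rows)
                all_gen = np.concatenate(gen_rows)
                grms = _grm_set(all_mk, config.ploidy, p_frozen, reml_info["model"])
                variances = {k: max(v, 1e-8) for k, v in reml_info["variances"].items()}
                fit = solve_gblup(all_y, all_gen, grms, variances, reml_info["sigma_e2"])
                ebv_cur = fit.ebv[-len(y):]
            if g == config.reml_at_generation:
                acc = accuracy(u_true, ebv_cur)

        if g < config.n_generations:
            cand = np.arange(offspring.n)
            if g <= config.random_selection_until:
                chosen = select_parents(cand, "random", None, config.n_parents, rng)
            else:
                chosen = select_parents(cand, "ebv", ebv_cur, config.n_parents, rng)
            parents_pop = offspring.subset(chosen)

    table = pd.DataFrame(traj_rows)
    by_gen = table.set_index("generation")
    span = config.n_generations - config.random_selection_until
    gain_u = rate_of_gain(
        by_gen.loc[config.random_selection_until, "mean_u"],
        by_gen.loc[config.n_generations, "mean_u"],
        span,
    )
    gain_g = rate_of_gain(
        by_gen.loc[config.random_selection_until, "mean_g"],
        by_gen.loc[config.n_generations, "mean_g"],
        span,
    )
    return Trajectory(
        table=table,
        accuracy=acc,
        gain_u=gain_u,
        gain_g=gain_g,
        reml_variances=reml_info["variances"],
        reml_sigma_e2=reml_info["sigma_e2"],
        reml_converged=reml_info["converged"],
        model_used=reml_info["model"],
        events=events,
    )
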