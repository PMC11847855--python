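"""Shared fixtures. The heavy scenario runs are session-scoped and shared by
the acceptance tests and the scheme-level invariant tests."""

from __future__ import annotations

import numpy as np
import pytest

from polybreed import generate_effects, run_breeding_scheme, spawn_rng
from polybreed.pipeline import prepare_genome
from polybreed.presets import MIXED_20_80, example1, example1_bi_short_history, example2

SEED = 1234
N_REPS = 5


def run_reps(config, founders, panel, effects, label, n_reps=N_REPS):
    return [
        run_breeding_scheme(config, founders, panel, effects, spawn_rng(SEED, "scheme", label, r))
        for r in range(n_reps)
    ]


@pytest.fixture(scope="session")
def diploid_genome():
    spec, cfg = example1(ploidy=2, scale="desk")
    founders, panel = prepare_genome(spec, cfg, SEED)
    return founders, panel, cfg


@pytest.fixture(scope="session")
def tetraploid_genome():
    spec, cfg = example1(ploidy=4, scale="desk")
    founders, panel = prepare_genome(spec, cfg, SEED)
    return founders, panel, cfg


@pytest.fixture(scope="session")
def bi_short_genome():
    spec, cfg = example1_bi_short_history(ploidy=2)
    founders, panel = prepare_genome(spec, cfg, SEED)
    return founders, panel, cfg


@pytest.fixture(scope="session")
def mixed_genome():
    spec, cfg = example1(ploidy=2, allelism_profile=MIXED_20_80, scale="desk")
    founders, panel = prepare_genome(spec, cfg, SEED)
    return founders, panel, cfg


@pytest.fixture(scope="session")
def diploid_e1_runs(diploid_genome):
    founders, panel, cfg = diploid_genome
    eff = generate_effects(founders, panel, cfg.trait, cfg.n_ep, spawn_rng(SEED, "fx", "d1"))
    return run_reps(cfg, founders, panel, eff, "d1")


@pytest.fixture(scope="session")
def tetraploid_e1_runs(tetraploid_genome):
    founders, panel, cfg = tetraploid_genome
    eff = generate_effects(founders, panel, cfg.trait, cfg.n_ep, spawn_rng(SEED, "fx", "t1"))
    return run_reps(cfg, founders, panel, eff, "t1")


@pytest.fixture(scope="session")
def diploid_e2_runs(diploid_genome):
    founders, panel, _ = diploid_genome
    _, cfg = example2(ploidy=2, scale="desk")
    eff = generate_effects(founders, panel, cfg.trait, cfg.n_ep, spawn_rng(SEED, "fx", "d2"))
    return run_reps(cfg, founders, panel, eff, "d2")


@pytest.fixture(scope="session")
def tetraploid_e2_runs(tetraploid_genome):
    founders, panel, _ = tetraploid_genome
    _, cfg = example2(ploidy=4, scale="desk")
    eff = generate_effects(founders, panel, cfg.trait, cfg.n_ep, spawn_rng(SEED, "fx", "t2"))
    return run_reps(cfg, founders, panel, eff, "t2")


@pytest.fixture(scope="session")
def bi_short_runs(bi_short_genome):
    founders, panel, cfg = bi_short_genome
    eff = generate_effects(founders, panel, cfg.trait, cfg.n_ep, spawn_rng(SEED, "fx", "bs"))
    return run_reps(cfg, founders, panel, eff, "bs")


@pytest.fixture(scope="session")
def mixed_runs(mixed_genome):
    founders, panel, cfg = mixed_genome
    eff = generate_effects(founders, panel, cfg.trait, cfg.n_ep, spawn_rng(SEED, "fx", "mx"))
    return run_reps(cfg, founders, panel, eff, "mx")
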