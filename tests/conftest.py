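"""Shared fixtures: a factory for random valid specs across all techniques."""
from __future__ import annotations

import numpy as np
import pytest

from rrapp import RandomizationSpec, Technique

ALL_TECHNIQUES = [t.value for t in Technique]


def _tileable_total(rng: np.random.Generator, candidates: list[int]) -> int:
    """A total that is a sum of candidate block sizes (so strict mode works)."""
    return int(sum(rng.choice(candidates) for _ in range(int(rng.integers(1, 5)))))


def make_random_spec(rng: np.random.Generator, technique: str | None = None) -> RandomizationSpec:
    """A random structurally and semantically valid strict-mode spec."""
    technique = technique or str(rng.choice(ALL_TECHNIQUES))
    n_arms = int(rng.integers(2, 5))
    data: dict = {
        "technique": technique,
        "seed": int(rng.integers(0, 2**20)),
        "n_arms": n_arms,
    }
    base = technique.removeprefix("stratified").removeprefix("_") or "stratified"
    if technique in ("stratified", "stratified_block", "stratified_permuted_block"):
        if rng.random() < 0.5:
            n_strata = int(rng.integers(1, 5))
            strata: dict = {"count": n_strata}
        else:
            factors = [("sex", ["male", "female"])]
            if rng.random() < 0.5:
                factors.append(("race", ["white", "nonwhite"]))
            n_strata = 2 ** len(factors)
            strata = {"factors": factors}
        if base in ("block",):
            b = n_arms * int(rng.integers(1, 4))
            data["block_size"] = b
            strata["per_stratum_n"] = [b * int(rng.integers(1, 4)) for _ in range(n_strata)]
        elif base == "permuted_block":
            cands = [2 * n_arms, 3 * n_arms]
            strata["per_stratum_n"] = [_tileable_total(rng, cands) for _ in range(n_strata)]
        else:
            strata["per_stratum_n"] = [int(rng.integers(1, 21)) for _ in range(n_strata)]
        data["strata"] = strata
    elif technique == "block":
        b = n_arms * int(rng.integers(1, 4))
        data["block_size"] = b
        data["total_n"] = b * int(rng.integers(1, 5))
    elif technique == "permuted_block":
        data["total_n"] = _tileable_total(rng, [2 * n_arms, 3 * n_arms])
    else:  # simple
        data["total_n"] = int(rng.integers(1, 41))
    return RandomizationSpec.model_validate(data)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)


@pytest.fixture
def spec_factory():
    return make_random_spec
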