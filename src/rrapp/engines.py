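"""Allocation-sequence engines for the six randomization techniques.

Every engine is a pure function of its integer seed: identical inputs give
bit-identical output across runs.  The pseudo-random stream is numpy's
``Generator`` over the PCG64 bit generator, seeded through ``SeedSequence``
(which hashes the integer seed, so nearby seeds give independent streams);
the generator identifier is recorded in every scheme's metadata.

Draw-order contract (pinned so schemes stay stable across versions):

* simple — one vectorized categorical draw of all ``total_n`` codes;
* block — one uniform permutation of the balanced multiset per block, in
  block order;
* permuted block — per block, first the size draw (consumed only when more
  than one candidate is eligible), then the within-block permutation;
* stratified variants — one fresh stream per stratum, seeded by
  :func:`derive_stratum_seed`, so each stratum's list is independently
  reproducible and unaffected by edits to other strata.
"""
from __future__ import annotations

from datetime import datetime, timezone
from typing import Optional

import numpy as np

from ._version import __version__
from .model import (
    Assignment,
    GenerationError,
    RandomizationSpec,
    Scheme,
    SpecValidationError,
    Stratum,
    Technique,
    MAX_STRATA,
    reachable,
    resolve_strata,
    validate_spec,
)

#: Pinned RNG algorithm; recorded in scheme metadata and checked on regenerate.
GENERATOR_ID = "numpy.random.Generator(PCG64)"

#: Unstratified schemes carry this stratum label.
UNSTRATIFIED_LABEL = "ALL"


def derive_stratum_seed(master_seed: int, stratum_index: int) -> int:
    """Sub-seed for one stratum: ``master_seed * 10000 + stratum_index``.

    The map is injective over all (master_seed, index) pairs with
    0 <= index < 10000, so every stratum of every master seed gets a
    distinct stream, and changing the master seed changes every stratum's
    sub-seed.  PCG64 seeding hashes the integer, so consecutive sub-seeds
    are statistically independent streams.
    """
    if stratum_index < 0:
        raise GenerationError("BAD_STRATUM_INDEX", f"stratum index {stratum_index} < 0")
    if stratum_index >= MAX_STRATA:
        raise GenerationError(
            "BAD_STRATUM_INDEX", f"at most {MAX_STRATA} strata per master seed"
        )
    return master_seed * MAX_STRATA + stratum_index


def generate_simple(
    seed: int,
    n_arms: int,
    total_n: int,
    allocation_ratio: Optional[list[int]] = None,
) -> list[int]:
    """Simple randomization: each slot drawn independently.

    Arm ``i`` (1-based) is drawn with probability ``ratio_i / sum(ratio)``;
    the default ratio is equal (a fair coin for two arms).  No balance is
    guaranteed at any interim point — that is the technique's known
    trade-off, not a defect.
    """
    ratio = allocation_ratio if allocation_ratio is not None else [1] * n_arms
    if len(ratio) != n_arms:
        raise GenerationError("RATIO_LENGTH_MISMATCH", f"{len(ratio)} ratio entries for {n_arms} arms")
    p = np.asarray(ratio, dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    codes = rng.choice(np.arange(1, n_arms + 1), size=total_n, p=p)
    return [int(c) for c in codes]


def draw_block(n_arms: int, block_size: int, rng: np.random.Generator) -> list[int]:
    """One balanced block: ``block_size/n_arms`` slots per arm, uniformly permuted.

    The permutation is uniform over all orderings of the balanced multiset
    (e.g. the 6 arrangements of AABB for 2 arms, block size 4).
    """
    if block_size < 1 or block_size % n_arms != 0:
        raise GenerationError(
            "BLOCK_SIZE_NOT_MULTIPLE",
            f"block size {block_size} is not a positive multiple of {n_arms} arms",
        )
    base = np.repeat(np.arange(1, n_arms + 1), block_size // n_arms)
    return [int(c) for c in rng.permutation(base)]


def _assignment(seq, stratum_label, block_index, block_size_used, code, labels):
    return Assignment(
        sequence=seq,
        stratum_label=stratum_label,
        block_index=block_index,
        block_size_used=block_size_used,
        arm_code=code,
        arm_label=labels[code - 1],
    )


def generate_block(
    seed: int,
    n_arms: int,
    total_n: int,
    block_size: int,
    allow_truncation: bool = False,
    arm_labels: Optional[list[str]] = None,
    stratum_label: str = UNSTRATIFIED_LABEL,
) -> list[Assignment]:
    """Fixed-size block randomization.

    ``total_n / block_size`` balanced blocks (strict mode requires exact
    divisibility), so the scheme ends with exactly ``total_n / n_arms``
    subjects per arm and is balanced at every block boundary.  With
    ``allow_truncation`` the final partial block is cut at ``total_n``.
    """
    if not allow_truncation and total_n % block_size != 0:
        raise GenerationError(
            "N_NOT_MULTIPLE_OF_BLOCK",
            f"strict mode: total_n {total_n} is not a multiple of block size {block_size}",
        )
    labels = arm_labels or [f"Arm_{i}" for i in range(1, n_arms + 1)]
    rng = np.random.default_rng(seed)
    out: list[Assignment] = []
    seq, block_index = 0, 0
    while seq < total_n:
        block_index += 1
        for code in draw_block(n_arms, block_size, rng):
            if seq >= total_n:
                break
            seq += 1
            out.append(_assignment(seq, stratum_label, block_index, block_size, code, labels))
    return out


def generate_permuted_block(
    seed: int,
    n_arms: int,
    total_n: int,
    block_size_candidates: Optional[list[int]] = None,
    allow_truncation: bool = False,
    arm_labels: Optional[list[str]] = None,
    stratum_label: str = UNSTRATIFIED_LABEL,
) -> list[Assignment]:
    """Permuted-block randomization: the block size itself is random.

    Default candidates are {2k, 3k} for k arms (4 and 6 for a two-arm
    trial).  Before each block, the size is drawn uniformly among the
    candidates that still fit; in strict mode the draw is further limited
    to sizes that leave a remainder tileable by the candidate set, so the
    sequence can never dead-end short of ``total_n`` (a total that is not
    tileable at all is rejected up front).  With ``allow_truncation``, when
    no candidate fits the remaining slots a size is drawn from the full set
    and the final block is cut at ``total_n``.

    The size draw consumes randomness only when more than one candidate is
    eligible, so a single-candidate set reproduces fixed-block generation
    bit-for-bit under the same seed.
    """
    cands = sorted(set(block_size_candidates)) if block_size_candidates else [2 * n_arms, 3 * n_arms]
    if not cands:
        raise GenerationError("EMPTY_CANDIDATES", "candidate block-size set must be non-empty")
    for c in cands:
        if c < 1 or c % n_arms != 0:
            raise GenerationError(
                "CANDIDATE_SIZE_NOT_MULTIPLE",
                f"candidate size {c} is not a positive multiple of {n_arms} arms",
            )
    strict = not allow_truncation
    ctuple = tuple(cands)
    if strict and not reachable(total_n, ctuple):
        raise GenerationError(
            "TOTAL_UNREACHABLE_BY_CANDIDATES",
            f"total_n {total_n} cannot be tiled by block sizes {cands}",
        )
    labels = arm_labels or [f"Arm_{i}" for i in range(1, n_arms + 1)]
    rng = np.random.default_rng(seed)
    out: list[Assignment] = []
    seq, block_index = 0, 0
    while seq < total_n:
        block_index += 1
        remaining = total_n - seq
        if strict:
            eligible = [c for c in cands if c <= remaining and reachable(remaining - c, ctuple)]
        else:
            eligible = [c for c in cands if c <= remaining]
        if not eligible:  # only in truncation mode
            eligible = cands
        if len(eligible) > 1:
            size = eligible[int(rng.integers(len(eligible)))]
        else:
            size = eligible[0]
        for code in draw_block(n_arms, size, rng):
            if seq >= total_n:
                break
            seq += 1
            out.append(_assignment(seq, stratum_label, block_index, size, code, labels))
    return out


_BASE_TECHNIQUE = {
    Technique.stratified: Technique.simple,
    Technique.stratified_block: Technique.block,
    Technique.stratified_permuted_block: Technique.permuted_block,
}


def _run_base(
    technique: Technique,
    spec: RandomizationSpec,
    seed: int,
    total_n: int,
    stratum_label: str,
) -> list[Assignment]:
    labels = spec.resolved_arm_labels()
    if technique is Technique.simple:
        codes = generate_simple(seed, spec.n_arms, total_n, spec.resolved_ratio())
        return [
            _assignment(i + 1, stratum_label, None, None, code, labels)
            for i, code in enumerate(codes)
        ]
    if technique is Technique.block:
        return generate_block(
            seed, spec.n_arms, total_n, spec.block_size,
            allow_truncation=not spec.strict, arm_labels=labels, stratum_label=stratum_label,
        )
    if technique is Technique.permuted_block:
        return generate_permuted_block(
            seed, spec.n_arms, total_n, spec.resolved_candidates(),
            allow_truncation=not spec.strict, arm_labels=labels, stratum_label=stratum_label,
        )
    raise GenerationError("UNKNOWN_TECHNIQUE", f"no base engine for {technique!r}")


def apply_stratification(base: Technique, spec: RandomizationSpec) -> list[Assignment]:
    """Run ``base`` once per stratum under its derived sub-seed and concatenate.

    Stratum *i*'s sub-list depends only on the master seed, *i*, and stratum
    *i*'s own parameters: editing another stratum's sample size leaves it
    bit-identical.
    """
    out: list[Assignment] = []
    for stratum in resolve_strata(spec):
        try:
            out.extend(_run_base(base, spec, stratum.sub_seed, stratum.n, stratum.label))
        except GenerationError as e:
            raise GenerationError(e.code, f"stratum {stratum.label!r}: {e}") from e
    return out


def _is_truncated(assignments: list[Assignment]) -> bool:
    """True when any block holds fewer slots than its drawn size."""
    counts: dict[tuple[str, int], int] = {}
    sizes: dict[tuple[str, int], int] = {}
    for a in assignments:
        if a.block_index is None:
            continue
        key = (a.stratum_label, a.block_index)
        counts[key] = counts.get(key, 0) + 1
        sizes[key] = a.block_size_used
    return any(counts[k] < sizes[k] for k in counts)


def generate(spec: RandomizationSpec, validate: bool = True) -> Scheme:
    """Generate the full scheme for a spec.

    Validates first (raising :class:`SpecValidationError` carrying the full
    report when invalid), dispatches to the technique's engine, and wraps
    the assignment list in a :class:`Scheme` with a deep copy of the spec,
    a UTC timestamp, and the pinned generator identifier — everything
    needed to reproduce the scheme bit-for-bit later.
    """
    if validate:
        report = validate_spec(spec)
        if not report.valid:
            raise SpecValidationError(report)
    if spec.technique in _BASE_TECHNIQUE:
        assignments = apply_stratification(_BASE_TECHNIQUE[spec.technique], spec)
    else:
        assignments = _run_base(spec.technique, spec, spec.seed, spec.total_n, UNSTRATIFIED_LABEL)
    return Scheme(
        spec_echo=spec.model_copy(deep=True),
        assignments=assignments,
        generated_at=datetime.now(timezone.utc),
        tool_version=__version__,
        generator=GENERATOR_ID,
        truncated=_is_truncated(assignments),
    )
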