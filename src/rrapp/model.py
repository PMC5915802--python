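"""Domain model for randomization schemes.

A :class:`RandomizationSpec` is the complete declarative request a trialist
makes: which of the six techniques to use, the reproducibility seed, the
treatment arms, the sample size(s), and — depending on the technique — a
block size, a candidate block-size set, an allocation ratio, or a
stratification scheme.  The model layer owns structural parsing (via
pydantic), the per-technique required-input matrix, stratum enumeration,
and all semantic validation rules.  Validation produces a
:class:`ValidationReport` with machine-readable codes rather than raising,
so a front-end can show every problem at once.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from functools import lru_cache
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator


class Technique(str, Enum):
    """The six supported randomization techniques."""

    simple = "simple"
    stratified = "stratified"
    block = "block"
    permuted_block = "permuted_block"
    stratified_block = "stratified_block"
    stratified_permuted_block = "stratified_permuted_block"


#: Techniques that allocate within prognostic-factor strata.
STRATIFIED_TECHNIQUES = frozenset(
    {Technique.stratified, Technique.stratified_block, Technique.stratified_permuted_block}
)
#: Techniques with a single fixed block size (require ``block_size``).
FIXED_BLOCK_TECHNIQUES = frozenset({Technique.block, Technique.stratified_block})
#: Techniques that draw the block size at random from a candidate set.
PERMUTED_TECHNIQUES = frozenset({Technique.permuted_block, Technique.stratified_permuted_block})
#: Techniques honoring an unequal allocation ratio (blocks force equal allocation).
RATIO_TECHNIQUES = frozenset({Technique.simple, Technique.stratified})

#: The three input elements mandatory for every technique.  ``sample_size``
#: maps to ``total_n`` for unstratified techniques and to the per-stratum
#: sizes (``strata.per_stratum_n`` or ``strata.total_n``) for stratified ones.
UNIVERSAL_INPUTS = frozenset({"seed", "n_arms", "sample_size"})

#: Maximum number of strata a single master seed can drive (see engines).
MAX_STRATA = 10_000


class RandomizationError(Exception):
    """Base error carrying a machine-readable ``code``."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"{code}: {message}")


class GenerationError(RandomizationError):
    """Raised by the engines when a spec cannot be generated."""


class ExportError(RandomizationError):
    """Raised by the export layer for unserviceable export requests."""


class SpecValidationError(RandomizationError):
    """Raised when generation is attempted on an invalid spec."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        codes = ", ".join(v.code for v in report.violations)
        super().__init__("INVALID_SPEC", f"spec failed validation: {codes}")


@dataclass(frozen=True)
class Violation:
    code: str
    message: str
    field: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_spec`; valid iff no violations."""

    violations: list[Violation] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def add(self, code: str, message: str, field_name: str) -> None:
        self.violations.append(Violation(code, message, field_name))

    def codes(self) -> list[str]:
        return [v.code for v in self.violations]


class StrataSpec(BaseModel):
    """Stratification request: named prognostic factors or a bare count.

    ``factors`` is an ordered list of ``(factor_name, [level, ...])`` pairs;
    the strata are the Cartesian product of the levels, enumerated with the
    first factor varying slowest.  Alternatively ``count`` asks for that many
    anonymous strata labelled ``Stratum_1``…  Per-stratum sample sizes come
    either as an explicit list (``per_stratum_n``) or as a single
    ``total_n`` split as equally as possible, remainders going to the
    lowest-index strata.
    """

    model_config = ConfigDict(extra="forbid")

    factors: Optional[list[tuple[str, list[str]]]] = None
    count: Optional[int] = None
    per_stratum_n: Optional[list[int]] = None
    total_n: Optional[int] = None

    @field_validator("factors", mode="before")
    @classmethod
    def _factors_from_mapping(cls, v):
        if isinstance(v, dict):
            return [(name, list(levels)) for name, levels in v.items()]
        return v

    def n_strata(self) -> Optional[int]:
        """Number of strata implied, or None if neither mode is given."""
        if self.factors is not None:
            n = 1
            for _, levels in self.factors:
                n *= len(levels)
            return n
        return self.count

    def resolve_per_stratum_n(self, n_strata: int) -> list[int]:
        """Concrete per-stratum sizes, splitting a bare total equally."""
        if self.per_stratum_n is not None:
            if len(self.per_stratum_n) != n_strata:
                raise RandomizationError(
                    "STRATA_N_LENGTH_MISMATCH",
                    f"{len(self.per_stratum_n)} sizes for {n_strata} strata",
                )
            return list(self.per_stratum_n)
        if self.total_n is None:
            raise RandomizationError("MISSING_REQUIRED_INPUT", "no per-stratum sample sizes")
        base, rem = divmod(self.total_n, n_strata)
        return [base + 1 if i < rem else base for i in range(n_strata)]


@dataclass
class Stratum:
    """One prognostic subgroup with its own independent allocation list."""

    index: int  # 0-based position in enumeration order
    label: str
    factor_levels: dict[str, str]
    n: Optional[int] = None
    sub_seed: Optional[int] = None


@dataclass(frozen=True)
class Assignment:
    """A single allocation slot in generation order."""

    sequence: int  # 1-based within stratum
    stratum_label: str  # "ALL" for unstratified schemes
    block_index: Optional[int]  # None for simple techniques
    block_size_used: Optional[int]
    arm_code: int  # 1-based in arm-label order
    arm_label: str


class RandomizationSpec(BaseModel):
    """Complete declarative randomization request.

    Only structurally ill-formed input (wrong types, unknown keys) raises
    here; semantic rules are checked by :func:`validate_spec`.
    """

    model_config = ConfigDict(extra="forbid")

    technique: Technique
    seed: int
    n_arms: int
    arm_labels: Optional[list[str]] = None
    total_n: Optional[int] = None
    block_size: Optional[int] = None
    block_size_candidates: Optional[list[int]] = None
    allocation_ratio: Optional[list[int]] = None
    strata: Optional[StrataSpec] = None
    strict: bool = True  # strict divisibility / reachability; False permits truncation

    @field_validator("block_size_candidates")
    @classmethod
    def _dedupe_candidates(cls, v):
        if v is None:
            return v
        return sorted(set(v))

    # -- resolved defaults -------------------------------------------------
    def resolved_arm_labels(self) -> list[str]:
        if self.arm_labels is not None:
            return list(self.arm_labels)
        return [f"Arm_{i}" for i in range(1, self.n_arms + 1)]

    def resolved_ratio(self) -> list[int]:
        if self.allocation_ratio is not None:
            return list(self.allocation_ratio)
        return [1] * self.n_arms

    def resolved_candidates(self) -> list[int]:
        """Candidate block sizes; default {2k, 3k} for k arms (4 and 6 for 2 arms)."""
        if self.block_size_candidates:
            return list(self.block_size_candidates)
        return [2 * self.n_arms, 3 * self.n_arms]


@dataclass
class Scheme:
    """A generated randomization scheme plus the metadata to reproduce it."""

    spec_echo: RandomizationSpec
    assignments: list[Assignment]
    generated_at: datetime
    tool_version: str
    generator: str
    truncated: bool = False


def required_inputs(technique: Technique | str) -> frozenset[str]:
    """Mandatory input elements for a technique.

    Every technique requires the three universal elements (seed, number of
    arms, sample size).  Fixed-block techniques add ``block_size``;
    stratified techniques add ``strata``.  The permuted variants need no
    block size (candidates are optional with a sensible default).
    """
    try:
        technique = Technique(technique)
    except ValueError:
        raise RandomizationError("UNKNOWN_TECHNIQUE", f"unknown technique {technique!r}") from None
    req = set(UNIVERSAL_INPUTS)
    if technique in FIXED_BLOCK_TECHNIQUES:
        req.add("block_size")
    if technique in STRATIFIED_TECHNIQUES:
        req.add("strata")
    return frozenset(req)


def enumerate_strata(strata: StrataSpec) -> list[Stratum]:
    """Enumerate strata in canonical order (sizes and sub-seeds unresolved).

    Factor mode: Cartesian product of levels, first factor varying slowest,
    levels in declared order; labels are the level labels joined by ``|``.
    Count mode: ``Stratum_1`` … ``Stratum_count``.
    """
    if strata.factors is not None:
        for name, levels in strata.factors:
            if not levels:
                raise RandomizationError("EMPTY_FACTOR", f"factor {name!r} has no levels")
        names = [name for name, _ in strata.factors]
        out = []
        for i, combo in enumerate(itertools.product(*(lv for _, lv in strata.factors))):
            out.append(
                Stratum(index=i, label="|".join(combo), factor_levels=dict(zip(names, combo)))
            )
        return out
    if strata.count is None or strata.count < 1:
        raise RandomizationError("BAD_STRATA_COUNT", f"strata count must be >= 1, got {strata.count}")
    return [Stratum(index=i, label=f"Stratum_{i + 1}", factor_levels={}) for i in range(strata.count)]


@lru_cache(maxsize=4096)
def reachable(total: int, candidates: tuple[int, ...]) -> bool:
    """Whether ``total`` is a sum of candidate block sizes (with repetition)."""
    if total < 0:
        return False
    dp = bytearray(total + 1)
    dp[0] = 1
    for t in range(1, total + 1):
        for c in candidates:
            if c <= t and dp[t - c]:
                dp[t] = 1
                break
    return bool(dp[total])


def _validate_strata(spec: RandomizationSpec, rep: ValidationReport) -> Optional[list[int]]:
    """Strata-related rules; returns resolved per-stratum sizes when possible."""
    st = spec.strata
    assert st is not None
    if st.factors is None and st.count is None:
        rep.add("BAD_STRATA_SPEC", "strata need factors or a count", "strata")
        return None
    try:
        strata = enumerate_strata(st)
    except RandomizationError as e:
        rep.add(e.code, str(e), "strata")
        return None
    if len(strata) > MAX_STRATA:
        rep.add("BAD_STRATA_COUNT", f"at most {MAX_STRATA} strata supported", "strata")
        return None
    if st.per_stratum_n is None and st.total_n is None:
        rep.add("MISSING_REQUIRED_INPUT", "stratified techniques need per-stratum or total sample size", "sample_size")
        return None
    try:
        sizes = st.resolve_per_stratum_n(len(strata))
    except RandomizationError as e:
        rep.add(e.code, str(e), "strata.per_stratum_n")
        return None
    if any(n < 0 for n in sizes):
        rep.add("NEGATIVE_N", "per-stratum sample sizes must be >= 0", "strata.per_stratum_n")
        return None
    return sizes


def validate_spec(spec: RandomizationSpec) -> ValidationReport:
    """Check every semantic rule; violations are data, not exceptions.

    A spec with ``valid`` report generates without error, and vice versa.
    """
    rep = ValidationReport()
    if spec.seed < 0:
        rep.add("NEGATIVE_SEED", "seed must be a non-negative integer", "seed")
    if spec.n_arms < 2:
        rep.add("TOO_FEW_ARMS", "randomization requires at least 2 treatment arms", "n_arms")

    if spec.arm_labels is not None:
        if len(spec.arm_labels) != spec.n_arms:
            rep.add("ARM_LABELS_LENGTH_MISMATCH",
                    f"{len(spec.arm_labels)} labels for {spec.n_arms} arms", "arm_labels")
        if len(set(spec.arm_labels)) != len(spec.arm_labels):
            rep.add("DUPLICATE_ARM_LABELS", "arm labels must be distinct", "arm_labels")

    if spec.allocation_ratio is not None:
        if len(spec.allocation_ratio) != spec.n_arms:
            rep.add("RATIO_LENGTH_MISMATCH",
                    f"ratio has {len(spec.allocation_ratio)} entries for {spec.n_arms} arms",
                    "allocation_ratio")
        elif any(r < 1 for r in spec.allocation_ratio):
            rep.add("BAD_RATIO", "allocation ratio entries must be >= 1", "allocation_ratio")
        elif spec.technique not in RATIO_TECHNIQUES and len(set(spec.allocation_ratio)) > 1:
            # blocks hand out block_size/n_arms per arm: only equal allocation works
            rep.add("RATIO_UNSUPPORTED",
                    "unequal allocation ratios are only supported by simple/stratified techniques",
                    "allocation_ratio")

    stratified = spec.technique in STRATIFIED_TECHNIQUES

    sizes: Optional[list[int]] = None
    if stratified:
        if spec.strata is None:
            rep.add("MISSING_REQUIRED_INPUT",
                    f"technique {spec.technique.value!r} requires strata", "strata")
        else:
            sizes = _validate_strata(spec, rep)
    else:
        if spec.total_n is None:
            rep.add("MISSING_REQUIRED_INPUT",
                    f"technique {spec.technique.value!r} requires total_n", "sample_size")
        elif spec.total_n < 0:
            rep.add("NEGATIVE_N", "sample size must be >= 0", "total_n")
        else:
            sizes = [spec.total_n]

    if spec.technique in FIXED_BLOCK_TECHNIQUES:
        if spec.block_size is None:
            rep.add("MISSING_REQUIRED_INPUT",
                    f"technique {spec.technique.value!r} requires block_size", "block_size")
        elif spec.block_size < 1:
            rep.add("BAD_BLOCK_SIZE", "block size must be a positive integer", "block_size")
        elif spec.n_arms >= 2 and spec.block_size % spec.n_arms != 0:
            rep.add("BLOCK_SIZE_NOT_MULTIPLE",
                    f"block size {spec.block_size} is not a multiple of {spec.n_arms} arms",
                    "block_size")
        elif spec.strict and sizes is not None:
            for i, n in enumerate(sizes):
                if n % spec.block_size != 0:
                    where = "total_n" if not stratified else f"strata[{i}].n"
                    rep.add("N_NOT_MULTIPLE_OF_BLOCK",
                            f"sample size {n} is not a multiple of block size {spec.block_size}",
                            where)

    if spec.technique in PERMUTED_TECHNIQUES:
        cands = spec.resolved_candidates()
        if spec.block_size_candidates is not None and not spec.block_size_candidates:
            rep.add("EMPTY_CANDIDATES", "candidate block-size set must be non-empty",
                    "block_size_candidates")
        elif any(c < 1 for c in cands):
            rep.add("BAD_BLOCK_SIZE", "candidate block sizes must be positive",
                    "block_size_candidates")
        elif spec.n_arms >= 2 and any(c % spec.n_arms != 0 for c in cands):
            bad = [c for c in cands if c % spec.n_arms != 0]
            rep.add("CANDIDATE_SIZE_NOT_MULTIPLE",
                    f"candidate sizes {bad} are not multiples of {spec.n_arms} arms",
                    "block_size_candidates")
        elif spec.strict and sizes is not None:
            for i, n in enumerate(sizes):
                if not reachable(n, tuple(cands)):
                    where = "total_n" if not stratified else f"strata[{i}].n"
                    rep.add("TOTAL_UNREACHABLE_BY_CANDIDATES",
                            f"sample size {n} cannot be tiled by block sizes {cands}", where)

    return rep


def resolve_strata(spec: RandomizationSpec) -> list[Stratum]:
    """Enumerate strata with sample sizes and sub-seeds filled in."""
    from .engines import derive_stratum_seed  # local import: engines depends on model

    if spec.strata is None:
        raise RandomizationError("MISSING_REQUIRED_INPUT", "spec has no strata")
    strata = enumerate_strata(spec.strata)
    sizes = spec.strata.resolve_per_stratum_n(len(strata))
    return [
        replace(s, n=n, sub_seed=derive_stratum_seed(spec.seed, s.index))
        for s, n in zip(strata, sizes)
    ]
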