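# Methods

## Allocation models

Let *k* be the number of treatment arms and *N* the sample size.

**Simple randomization.** Each slot is an independent categorical draw:
arm *i* with probability *rᵢ / Σr*, where the allocation ratio *r* defaults
to all ones (equal allocation). The whole sequence is one vectorized draw
from the seeded stream, so it is fully determined by the seed. Simple
randomization makes no balance guarantee at any interim point; that is the
technique's documented trade-off, not something the implementation smooths
over.

**Block randomization.** The scheme is a concatenation of balanced blocks
of fixed size *b*, with *b* a multiple of *k*. Each block is a uniformly
random permutation of the multiset containing *b/k* copies of every arm —
uniform over all distinct balanced orderings (the standard construction;
how the permutation is drawn is a design choice here, since balance alone
does not pin it down). Consequences checked by the tests: every completed
block contributes *b/k* per arm, cumulative counts are equal at every block
boundary, and a strict-mode scheme of *N = m·b* subjects ends with exactly
*N/k* per arm.

**Permuted block randomization.** Before each block, the size is drawn
uniformly from a candidate set (default {2k, 3k}; every candidate must be a
multiple of *k*), then the block is filled as above. Two rules the
published description of the technique leaves open were fixed as follows:

* *Feasibility filter (strict mode).* The size draw is restricted to
  candidates that both fit the remaining slots **and** leave a remainder
  expressible as a sum of candidate sizes (a coin-problem reachability
  test, computed by dynamic programming and cached). Without this filter a
  greedy draw can dead-end — for N=10 with candidates {4, 6}, drawing 4
  twice leaves 2 unfillable slots. With it, the only realizable size
  sequences for that example are (4, 6) and (6, 4), each with probability
  ½, and a total that is not tileable at all is rejected up front
  (`TOTAL_UNREACHABLE_BY_CANDIDATES`).
* *Truncation mode.* With `strict=False`, the size draw is uniform over
  candidates that fit; when none fit, a size is drawn from the full set and
  the final block is cut at *N* (recorded via the scheme's `truncated`
  flag and visible in the audit table as a block with fewer rows than
  `block_size_used`).

The size draw consumes randomness only when more than one candidate is
eligible. This makes a single-candidate set reproduce fixed-block
generation bit-for-bit under the same seed, and keeps the draw-order
contract simple: per block, size first, then permutation.

**Stratification.** Strata are enumerated as the Cartesian product of the
declared factor levels, first factor varying slowest, levels in declared
order, labelled `level1|level2|…`; alternatively a bare count yields
`Stratum_1…Stratum_m`. Each stratum runs the base engine (simple, block,
or permuted block) under its own sub-seed

```
sub_seed = master_seed * 10000 + stratum_index
```

an arithmetic map that is injective over all (master, index) pairs with
index < 10 000 and transparent enough to audit by eye. numpy seeds
generators through `SeedSequence`, which hashes the integer, so adjacent
sub-seeds give statistically independent streams. One stream per stratum —
rather than one global stream — means stratum *i*'s list depends only on
the master seed, *i*, and stratum *i*'s own parameters: editing another
stratum's sample size leaves it bit-identical, which is what makes
per-stratum amendments auditable.

## Reproducibility contract

The RNG is pinned to `numpy.random.Generator` over PCG64 and that
identifier is written into every metadata record; `regenerate` refuses
records from a different generator, metadata format, or tool major version
(`GENERATOR_VERSION_MISMATCH`) rather than risk silently different output.
A SHA-256 checksum over the resolved spec and the full assignment list
(timestamps excluded) is stored in the metadata; on regeneration a mismatch
— e.g. a hand-edited seed — is reported as a warning while the regenerated
scheme is still written, since the record itself documents what was
requested.

## Parameters and defaults

| Parameter | Default | Notes |
|---|---|---|
| `seed` | required | non-negative integer; the sole source of randomness |
| `n_arms` | required | ≥ 2 |
| `arm_labels` | `Arm_1…Arm_k` | distinct; arm codes are 1-based in label order (REDCap convention) |
| `block_size` | required for block techniques | must be a multiple of `n_arms` |
| `block_size_candidates` | `{2k, 3k}` | permuted techniques; each a multiple of `n_arms` |
| `allocation_ratio` | all 1s | simple/stratified only; blocks assume equal allocation, so unequal ratios with block techniques are rejected (`RATIO_UNSUPPORTED`) |
| `strict` | `True` | exact tiling of the sample size required; `False` permits a truncated final block |
| strata sizes | — | explicit per-stratum list, or one total split as equally as possible with remainders to the lowest-index strata |

A sample size of 0 is accepted as a degenerate spec producing an empty
scheme; its metadata still documents every input and round-trips through
`regenerate`. Negative sizes are validation errors.

## Validation

`validate_spec` reports every violated rule at once as (code, message,
field) triples instead of failing fast — a front-end can show the complete
picture. The validator and the engines are kept consistent by a property
test over randomized specs: a spec passes validation **iff** generation
raises no error, including the strict-mode divisibility and reachability
rules.

## What the randomized test material covers — and what it does not

Tests and the acceptance script draw random specs with 2–4 arms, block
sizes of 1–3 multiples of the arm count, totals of 1–5 blocks (up to ~40
subjects per list), and 1–4 strata — the small-trial regime where block
randomization matters most. This exercises every code path and the exact
balance/independence invariants, which hold by construction at any size.
It does not emulate operational realities of real trials — dropout,
mid-trial amendments of arms or factors, or enrollment that ignores the
precomputed order — and passing tests say nothing about those. Statistical
checks (uniformity of block orderings, the ≈50/50 split of (4,6)/(6,4)
size sequences) are run at 10,000–60,000 replicates with a chi-square
test at α = 0.001, chosen so that a correct implementation fails at a rate
far below once per thousand runs while gross non-uniformity is detected
immediately; fixed internal seeds make the suite deterministic.

## Known limitations

* No covariate-adaptive, minimization, biased-coin/Efron, urn, or
  response-adaptive designs — such schemes warrant a statistician's design
  work, not an automated generator, and are deliberately out of scope.
* Unequal allocation is available only for simple/stratified techniques.
* At most 10 000 strata per master seed (the sub-seed map's injectivity
  range); practical trials are orders of magnitude below this.
* REDCap export requires factor-based strata, because REDCap matches
  allocation rows on real data-collection fields; count-based strata have
  no such fields and are rejected (`REDCAP_NEEDS_FACTORS`). The column
  layout (target field `randomization_group`, then lower-snake-cased
  factor names) follows REDCap's allocation-table convention and is
  overridable.
* The CLI's acknowledgment gate (`--ack` or interactive confirmation) is a
  procedural safeguard, not access control: it documents that the person
  generating the scheme attests to not being involved in patient
  screening. It also guards `regenerate`, since regenerating reveals the
  same allocations.
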