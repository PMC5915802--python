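# rrapp — reproducible randomization schemes for clinical trials

`rrapp` generates the precomputed treatment-allocation lists that a
randomized clinical trial needs before the first patient is enrolled. It is
aimed at trialists and biostatisticians who want rigorous, auditable,
seed-exact randomization without a commercial system: the same integer seed
always regenerates the identical scheme, every input element is documented
alongside the output, and the allocation table can be imported directly into
REDCap's randomization module.

## The six techniques

For a trial with *k* arms and total sample size *N*:

* **Simple randomization** — each subject is assigned independently with
  preset probabilities (a fair coin for two equal arms; an optional
  allocation ratio *r₁:…:r_k* sets unequal probabilities). Unpredictable,
  but interim arm sizes can drift.
* **Block randomization** — assignments are generated in balanced blocks of
  fixed size *b* (a multiple of *k*): each block holds exactly *b/k*
  subjects per arm, giving *N/b* blocks and a final count of *N/k* per arm.
  Balance holds at every block boundary, which matters when recruitment may
  stop early.
* **Permuted block randomization** — the block size itself is drawn at
  random from a candidate set (default {2k, 3k}, i.e. {4, 6} for two arms),
  so staff cannot deduce upcoming assignments from a known fixed block
  length. This protects allocation concealment.
* **Stratified** variants of all three — a separate, independently seeded
  allocation list per stratum, where strata are the Cartesian product of
  prognostic-factor levels (e.g. sex × race → male|white, male|nonwhite,
  female|white, female|nonwhite) or simply a count of subgroups.

Three input elements are mandatory for every technique — the seed, the
number of arms, and the sample size. Block techniques additionally need the
block size; stratified techniques need the strata definition.

## Worked example

A two-arm trial stratified on sex and race, eight subjects per stratum,
blocks of four:

```bash
rrapp generate --technique stratified_block --seed 20240117 \
    --arms 2 --arm-labels "placebo,treatment" --block-size 4 \
    --factor "sex=male,female" --factor "race=white,nonwhite" \
    --per-stratum-n 8,8,8,8 --out-dir demo --ack
```

prints the echoed request, then:

```
Validation: OK
Wrote demo/rrapp_stratified_block_20261001-212706.csv
Wrote demo/rrapp_stratified_block_20261001-212706.json
Wrote demo/redcap_rrapp_stratified_block_20261001-212706.csv
```

The audit table starts:

```
sequence,stratum_label,block_index,block_size_used,arm_code,arm_label
1,male|white,1,4,1,placebo
2,male|white,1,4,2,treatment
3,male|white,1,4,1,placebo
4,male|white,1,4,2,treatment
5,male|white,2,4,2,treatment
```

Each stratum gets its own 1-based sequence; every block of four contains
exactly two `placebo` and two `treatment` slots, so each stratum ends at
4/4. The REDCap file holds the coded arm plus one coded column per factor
(`randomization_group,sex,race` — here row one is `1,1,1`: placebo,
male, white), with a `*_codes.json` sidecar documenting every code ↔ label
pair. The JSON metadata records the full specification, the RNG identifier
(`numpy.random.Generator(PCG64)`), the tool version and a checksum, and

```bash
rrapp regenerate demo/rrapp_stratified_block_20261001-212706.json --out-dir again --ack
```

reproduces the identical scheme (a tampered record is flagged by the
checksum; `--ack` confirms you are not involved in patient screening —
schemes must stay concealed from recruiting staff to avoid selection bias).

The same workflow is available as a library:

```python
from rrapp import RandomizationSpec, generate

spec = RandomizationSpec(technique="block", seed=42, n_arms=2,
                         total_n=12, block_size=4)
scheme = generate(spec)
[a.arm_code for a in scheme.assignments]
# [2, 2, 1, 1, 2, 2, 1, 1, 1, 2, 2, 1]  — three blocks, six per arm
```

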