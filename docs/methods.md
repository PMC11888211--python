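# Methods

## Model

A query V sequence, threaded onto the reference MSA, is modeled as emitted by
a hidden path over `2NK` states: for each of `N` germline references and `K`
mutation-rate classes there is one "non-chimeric" state (class `U`) and one
"chimeric" state (class `C`). Paths start uniformly over the `NK` `U` states.
Cross-reference transitions are only permitted *into* `C`, so membership in
`C` at the terminal column is equivalent to "switched reference at least
once", and the Forward mass of terminal `C` states divided by the total
evidence is the posterior probability that the query is a PCR chimera.

Emissions are a single-parameter substitution model per state: match `1 − m`,
mismatch `m/3`, and probability 1 for gap/`N` observations (such columns are
uninformative and contribute nothing to discrimination — this is also how
partial-V coverage is handled, since uncovered columns are threaded as gaps).
The model deliberately ignores position- and motif-specific SHM biases and
substitution asymmetries; one free rate per state keeps the state space small
and the per-reference rate identifiable.

Two conventions are worth stating because the emission law leaves them open:

* a *reference* gap opposite a query base is scored as a mismatch (`m/3`);
  this is isolated in `emission_prob` and shared by all code paths;
* posteriors are reported raw (no clamping, no log-odds transform).

## Linear-time recursions

The transition matrix has only four distinct values (self, within-reference,
cross-reference-into-C, zero), so the Forward induction for all `2NK` states
needs only three aggregates per column: the global sum of α, the per-
(reference, class) sum, and the per-reference sum over both classes. Per
column this is O(NK) work instead of O((NK)²). The Backward pass uses the
transposed decomposition (outgoing mass splits into self, same-reference and
into-C terms), and Viterbi replaces the sums with maxima — per-(reference,
class) top-2 over rate classes plus the global top-2 over per-reference
maxima, so the best cross-reference predecessor is available in O(1) per
state. Ties between equal-scoring predecessors resolve to the lowest state
index, which makes paths deterministic inside homology tracts; the reported
breakpoint is the first column of the new segment, and within a tract where
the two parents are identical its placement is conventional, not evidential.

Numerics: the Forward/Backward kernels use per-column rescaling (each α
column is normalized to sum 1 and the log-normalizers accumulate into the log
evidence), which vectorizes well across queries; the test suite cross-checks
it against an independent dense log-space implementation (`logsumexp`) of the
unrearranged quadratic recursions, on random instances, to relative error
below 1e-10. The `m = 0` rate class is legal (it simply explains no
mismatched column); the only degenerate configuration — a single rate class
with `m = 0` and a query that mismatches a column in every reference — raises
a `NumericalDegeneracyError` rather than dividing by zero. `N = 1` and
`K = 1` short-circuit the corresponding transition branches (self mass
`1 − μ`, `1 − ψ`, or exactly 1), and `N = 1` or `ψ = 0` give posterior
exactly 0 because `C` has no inflow.

## Parameters

| parameter | default | meaning |
|---|---|---|
| ψ | 1e-4 /column | prior switch rate to a different reference (chimeric move) |
| μ | 1e-3 /column | switch rate to another rate class of the same reference |
| rate grid | 15 classes, [0, 0.25] | DB mode SHM discretization (IG-type data) |
| fixed rate | 0.005 | DB mode single class for TCR (sequencing error only) |
| BW init rate | 0.05 | starting per-reference rate for EM |
| threshold | 0.95 | posterior at or above which a query is called chimeric |

ψ is a user prior, not a fitted quantity. The default 1e-4 puts the prior
probability of at least one switch over a typical ~300-column V at about 3%,
which keeps non-chimeric posteriors far from the 0.95 threshold while the
likelihood ratio of a true chimera of diverged parents easily overwhelms it.
μ matters only for DB mode with `K > 1`; 1e-3 allows paths to move between
rate classes without materially competing with the self-transition.

BW mode estimates one rate per reference by EM: the E-step accumulates
expected mismatch and informative-emission counts from the posterior state
occupancies γ (pooling the `U` and `C` states of each reference, aggregated
over the whole dataset — per-query rates would be unidentifiable for short
queries), and the M-step is the ratio estimator clamped to [1e-6, 0.3]. The
loop stops when the total log-likelihood improves by less than 1e-3 or after
10 iterations; the log-likelihood is non-decreasing by the EM property and
the suite asserts it. ψ and μ are never re-estimated.

## Simulation framework

The simulator provides the calibration bed. A synthetic germline set is drawn
as a star phylogeny of families: family roots at pairwise divergence ≈
`between_div` from a common ancestor, genes within a family at ≈ `within_div`
(per-branch rates are solved from the pairwise target via
`p = 2e(1−e) + (2/3)e²`). Defaults — 50 genes, 7 families, `within_div` 0.06,
`between_div` 0.30, 300 columns — emulate an IGHV-like personal genotype:
same-family genes ~94% identical, cross-family genes diverged enough that
most chimeric joins are identifiable. Repertoires contain an exact (rounded)
number of chimeras — 10,000 sequences at a 5% chimerism rate gives exactly
500 chimeric and 9,500 non-chimeric — rather than Bernoulli draws. Chimeras
join two *distinct*, uniformly chosen alleles at a breakpoint uniform on
`[2, L]` (each parent contributes at least one column); same-allele chimerism
is excluded because it is undetectable by construction in a reference-based
model. Every sequence is mutated uniformly at the configured
difference-from-reference (DFR), which stands in for SHM in BCR data and
sequencing error in TCR data.

The emitted AIRR table carries a perfect pairwise alignment of each simulated
sequence against its (left) parent — deliberately the *left* parent for
chimeras, so threading uses a partially wrong reference exactly as a real
annotator would assign. What the simulator does **not** emulate: clonal
lineage structure, indels, motif-biased SHM, quality artifacts, or
multi-breakpoint chimeras. Passing calibration here therefore shows the model
is well calibrated under its own assumptions (uniform independent
substitution), not that real repertoires are free of other failure modes.

All simulator randomness flows from a single seeded generator; outputs are
bit-reproducible given (inputs, seed).

## Problem sizes and evaluation choices

The packaged calibration runs use the full benchmark design (10,000 sequences
per condition, ~50 references, 300 columns, 15 rate classes), which the
vectorized kernels process in about a minute per DB condition and a few
minutes for a BW fit on one CPU. Power at DFR 0 is summarized by ROC AUC and
TPR at the 0.95 threshold over *well-determined* chimeras — those whose
parents differ at ≥ 10 columns on each side of the breakpoint. Chimeras
without flanking divergence on both sides are information-free (the sequence
is exactly a mutated copy of a single reference), so including them bounds
every method's ROC identically and measures the simulator, not the detector.
At high DFR (20%) an occasional non-chimeric sequence (≈0–1 per 9,500 across
repertoire draws) accumulates enough coincidental similarity to a mosaic
explanation to cross the 0.95 posterior — the "perfect fake chimera"
phenomenon, inherent to the problem rather than to the implementation (the
dense-oracle cross-check agrees on such sequences to machine precision).

## Interface notes

`detect --threads` is accepted for command-line compatibility but the kernels
are vectorized single-process; queries are independent in DB mode and within
an EM iteration in BW mode, so results are order-stable by construction.
Multi-allele `v_call` annotations use the first listed allele for threading
(the HMM marginalizes over all references regardless; the choice only affects
the column mapping). Unknown alleles are skipped with a logged count by
default and fatal under `--strict`. The recombination table reports raw
single-breakpoint counts; normalized visualizations are left to the user.

## Known limitations

Only the V segment is modeled; D/J chimerism is out of scope. Same-allele
chimeras are undetectable by design. The emission model ignores SHM hotspot
and substitution biases, so heavily mutated IgG data may be scored
conservatively. An incomplete reference database can make genuine alleles
look like recombinants of the alleles that are present; detection rates
should be compared across databases before being interpreted as chimerism.
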