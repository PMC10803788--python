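# Methods

## Model

A Fermatean fuzzy number (FFN) is a pair (μ, ν) ∈ [0, 1]² with
μ³ + ν³ ≤ 1. The admissible region strictly contains the intuitionistic
(μ + ν ≤ 1) and Pythagorean (μ² + ν² ≤ 1) regions, so elicitation that
produces pairs like (0.9, 0.6) stays representable. Ranking uses the score
g = μ³ − ν³ as primary key and the accuracy H = μ³ + ν³ as tie-break; the
hesitation degree π = (1 − μ³ − ν³)^⅓ completes the partition
μ³ + ν³ + π³ = 1.

Two orders coexist and are deliberately kept apart in the API:

* `compare` — the total score-then-accuracy order used for ranking;
* `dominance_leq` — the componentwise partial order (μ no larger, ν no
  smaller) under which the aggregation operators are monotone and bounded.
  A pair can be strictly score-ordered yet dominance-incomparable.

## Aggregation

All operators are instances of one exponent-q kernel
(`fermadm.kernel`): the averaging family maps (μₖ, νₖ) to
((1 − ∏(1 − μₖ^q)^wₖ)^(1/q), ∏νₖ^wₖ) and the geometric family is its De
Morgan dual. q = 3 gives the Fermatean operators — dynamic (time weights ε:
FFDyWA/FFDyWG) and static (attribute weights ω: FFWA/FFWG power forms) are
the same computation with relabelled weights — and q = 1 gives the
intuitionistic baselines (IFDWA/IFDWG). The kernel surfaces only q ∈ {1, 3};
q = 2 (Pythagorean) would work but has no exercised consumer here.

The literature also defines a componentwise-arithmetic operator under the
FFWA name (Σwμ, Σwν). It is a different operator from the power form (it
commutes with neither closed form above), so it is exposed separately as
`ffwa_arithmetic` and never used by the pipeline: the pipeline's published
overall values are reproducible only with the power form. Its closure needs
no proof beyond convexity of the constraint region.

## Numerical choices

* Products are weighted log sums: ∏xₖ^wₖ = exp(Σwₖ log xₖ), with exact
  short-circuits for factors 0 and 1 and the conventions 0⁰ = 1 (a zero
  weight drops a period) and 0^w = 0 for w > 0. This cannot underflow for
  long series.
* The complement side 1 − ∏(1 − x)^w is evaluated as −expm1(Σw·log1p(−x)).
  A naive `1 - prod` loses all precision when every x is below machine
  epsilon (e.g. aggregating pairs with μ ≈ 1e−7 returns 0 instead of
  ≈ μ); the expm1/log1p form keeps full relative precision at both
  boundaries, which is what lets idempotency, boundedness and the
  50-digit-oracle agreement hold to 1e−12 in the test suite.
* Validation tolerance 1e−9 on the cube-sum constraint (absorbs
  decimal-literal rounding); comparison tolerance 1e−12 for score/accuracy
  ties; weight-sum tolerance 1e−6 with an opt-in `normalize` flag, since
  user files carry rounded weights.
* Degenerate inputs: a single period with weight 1 reproduces its input; a
  1×1×1 tensor echoes its cell; strict validation raises naming the
  offending cell (matrix, row, column), permissive validation flags it and
  proceeds.

## Pipeline

`run_method` = stage 1 (collapse periods per cell, FFDyWA or FFDyWG under
ε) → stage 2 (collapse attributes per row, matching power form under ω) →
score → rank. Ties after score and accuracy are reported as explicit groups
in input order rather than broken arbitrarily, since a decision problem can
legitimately have plural optima.

`collective_decimals` optionally truncates the stage-1 matrix to a fixed
number of decimals before stage 2. Published results tables in this field
tabulate the collective matrix at three decimals and compute the overall
values from the printed table, so reproducing such tables end-to-end
requires truncating at the same point; the package default is full
precision. The shipped case study illustrates the size of the effect: the
top score is 0.3988 with 3-decimal tabulation and 0.3997 without — the
ranking is unaffected.

All attributes are treated as benefit-type. The shipped case study includes
a side-effects attribute that a cost-aware analysis would complement or
rescale first; the packaged data applies no such reversal, and the package
performs none, leaving cost handling to the caller.

The intuitionistic baselines default to permissive validation because
Fermatean-elicited data routinely violate μ + ν ≤ 1; every violating cell
(54 of the 60 in the shipped case) is listed in the report rather than
silently accepted or refused.

## Synthetic generator

`generate_tensor` draws μ uniform on [0, 1] and ν uniform on
[0, (1 − μ^q)^(1/q)] conditional on it, so every cell is valid by
construction and the μ-marginal is exactly uniform. All randomness flows
through one seeded numpy generator; identical configs give identical
tensors. The generator emulates only the structural features of real
elicitation (valid orthopairs on a labelled m×n×p grid) — not
inter-attribute correlation, expert bias toward round tenths, or temporal
trends — so property tests on generated tensors certify the algebra and
pipeline mechanics, not behaviour on any particular elicitation style.

## Known limitations

* Single decision maker; no group aggregation or consensus step.
* No cost-attribute normalisation (see above) and no sensitivity analysis
  over ε or ω.
* Only q ∈ {1, 3} constraint families; interval-valued, picture, spherical
  and general q-rung variants are out of scope.
* Printed-value regression tests use an absolute band of ±0.002 because the
  reference results are typeset at three (inconsistently truncated)
  decimals; quantities the package computes itself are checked to 1e−12
  against an independent high-precision oracle.
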