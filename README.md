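# fermadm

Fermatean fuzzy dynamic multi-attribute decision making: rank a set of
alternatives evaluated against several attributes *over several time
periods*, when each judgement is a membership / non-membership pair rather
than a crisp number.

## The problem and the model

A decision maker scores alternative Ξᵢ on attribute ∅ⱼ at period tₖ with a
**Fermatean fuzzy number** (FFN) — a pair (μ, ν) of support and opposition
degrees in [0, 1] constrained by

    μ³ + ν³ ≤ 1.

The cubic constraint admits judgements such as (0.9, 0.5) that the
intuitionistic condition μ + ν ≤ 1 would reject, so experts can express
simultaneous strong support and strong doubt. FFNs are ranked by the score
g(F) = μ³ − ν³, with the accuracy H(F) = μ³ + ν³ breaking ties; the
residual hesitation is π = (1 − μ³ − ν³)^⅓.

Time-stamped judgements are collapsed with the **dynamic weighted
averaging** and **geometric** operators under a time-weight vector ε
(εₖ ∈ [0, 1], Σεₖ = 1):

    FFDyWA(F₁…F_p) = ( (1 − ∏ₖ (1 − μₖ³)^εₖ)^⅓ ,  ∏ₖ νₖ^εₖ )
    FFDyWG(F₁…F_p) = ( ∏ₖ μₖ^εₖ ,  (1 − ∏ₖ (1 − νₖ³)^εₖ)^⅓ )

Both are idempotent, bounded by the componentwise extremes, monotone, and
closed on valid FFNs. The full ranking procedure is two-staged: FFDyWA (or
FFDyWG) collapses the period axis cell by cell into a collective m×n
matrix, the matching attribute-weighted operator (FFWA/FFWG, weights ω)
collapses each row into one overall FFN per alternative, and alternatives
are ordered by score then accuracy. Intuitionistic dynamic baselines
(IFDWA/IFDWG — the same closed forms with exponent 1 and score μ − ν) run
through the same pipeline for comparison; a single exponent-q kernel backs
both families.

The package ships a worked clinical case: four leukemia (ALL) treatment
alternatives — chemotherapy, stem-cell transplantation (HSCT), radiation,
and CAR T-cell therapy — judged on survival rate, remission, side effects,
efficiency and reliability over three two-year periods, with
ε = (0.2, 0.3, 0.5) and ω = (0.3, 0.25, 0.1, 0.2, 0.15).

## Worked example

```sh
python - <<'EOF'
from fermadm import all_treatment, write_tensor
t, eps, omega = all_treatment()
write_tensor(t, eps, omega, "case.json")
EOF
fermadm rank case.json --variant both --collective-decimals 3
```

prints

```
variant: averaging
alternative  overall (mu, nu)   score    accuracy
Chemotherapy (0.749, 0.503)      0.293   0.548
HSCT         (0.737, 0.625)      0.157   0.644
Radiation    (0.622, 0.531)      0.091   0.390
CAR-T        (0.805, 0.497)      0.399   0.644
ranking: CAR-T ≻ Chemotherapy ≻ HSCT ≻ Radiation

variant: geometric
alternative  overall (mu, nu)   score    accuracy
Chemotherapy (0.726, 0.540)      0.225   0.540
HSCT         (0.720, 0.678)      0.062   0.686
Radiation    (0.600, 0.579)      0.022   0.411
CAR-T        (0.732, 0.520)      0.251   0.533
ranking: CAR-T ≻ Chemotherapy ≻ HSCT ≻ Radiation
```

Each row shows an alternative's overall FFN after both aggregation stages,
its score μ³ − ν³ (the ranking key) and accuracy μ³ + ν³ (the tie-break).
CAR T-cell therapy leads under both operator families — the averaging
family rewards strong isolated judgements, the geometric family penalises
weak ones, and a ranking that survives both is robust to that modelling
choice. `--compare all` appends the intuitionistic baseline rankings;
`--collective-decimals 3` tabulates the intermediate collective matrix at
three decimals, matching how such tables are conventionally published
(omit it for full precision).

The same pipeline is available as a library (`run_method`,
`run_baseline`), and `fermadm generate --seed N --output t.json` writes a
seeded synthetic tensor for experimentation.

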