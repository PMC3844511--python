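# Methods

## The probability model

A family enters the sample because its child is affected (`D`). At a
di-allelic autosomal locus with risk allele `A` (frequency `p`, `q = 1 − p`)
and penetrances `f₂, f₁, f₀` for genotypes `AA, Aa, aa`, the penetrances are
not identifiable from case-ascertained families — only the relative risks
`ψ₂ = f₂/f₀` and `ψ₁ = f₁/f₀` are, and they are the model's risk parameters.
Assuming Hardy–Weinberg equilibrium and random mating in the parental
generation, Bayes' rule gives, for each combination of parental mating type
`MT` and child genotype `C`,

    P(MT, C | D) = P(MT) · P(C | MT) · ψ_C / R,
    R = p²ψ₂ + 2pq·ψ₁ + q²,

where `ψ_C` is the relative risk of the child's genotype and `R` is
proportional to the marginal disease probability. This yields 10 triad cells.
Dyad cells are obtained by summing the **ordered** triad configurations over
the unobserved parent (halving unordered mixed mating types, since exactly one
ordering matches the observed parent); each of the 7 sums collapses to a
monomial, e.g. parent `Aa` with child `AA` gives `p²q·ψ₂/R`. The classical
unordered version of this probability (which does not say *which* parent is
observed) exceeds the ordered one by `p³q·ψ₂/R`; it is retained in the code
only as a documented cross-check (`schaid_sommer_unordered_probability`),
because applying it to real dyad records — which always identify the genotyped
parent — would misweight the likelihood. Monads contribute the case-genotype
probabilities `(p²ψ₂, 2pq·ψ₁, q²)/R`.

Every cell probability is `k · p^a q^b ψ₁^c ψ₂^d / R` with small integer
exponents, so the log-likelihood of counted data collapses to

    ap·log p + aq·log q + a₁·log ψ₁ + a₂·log ψ₂ + const − N·log R,

where `(ap, aq, a₁, a₂)` are exponent-weighted count sums, `N` is the total
number of families and `const = Σ count·log k` is parameter-free. These four
sufficient statistics are the whole interface between data and inference,
which is what the estimation and simulation machinery exploits. The
multinomial coefficient is omitted (it cancels from every likelihood ratio);
`0·log 0 := 0`, and a positive count on a zero-probability cell evaluates to
`−∞` rather than raising, so optimisers can reject the point.

## Estimation

Under `H₀: ψ₁ = ψ₂ = 1` the normaliser is identically 1 and the likelihood is
binomial in the allele-count coefficients, so `p̂ = ap/(ap + aq)` in closed
form. Data carrying only one allele are degenerate (`p̂` would be 0 or 1) and
raise a dedicated error.

Each alternative model is fitted by damped Newton ascent on a transformed
scale that absorbs the domain constraints:

* `a = logit p`, and `t = log ψ` for the free risk parameter(s);
* the additive model's admissibility bound `ψ₁ ≥ ½` (needed for
  `ψ₂ = 2ψ₁ − 1 ≥ 0`) is enforced by `ψ₁ = ½ + e^θ`.

Writing `u = (q², 2pq·ψ₁, p²ψ₂)/R` — the case-genotype distribution — the
derivatives of `log R` take multinomial-logistic form (`u` is a softmax of the
log cell weights), giving compact analytic gradients and Hessians. The ascent
starts at the null point `(p̂, 1, 1)`, so the attained log-likelihood can never
fall below the null's and likelihood-ratio statistics are nonnegative by
construction; steps use a tiny-ridge Newton solve with a halving line search
and a scaled-gradient fallback. Convergence is declared when an accepted step
improves the log-likelihood by less than `1e−10` (relative); the scalar API
additionally restarts from deterministic over-/under-dispersed points
(`ψ ≈ e^±0.7`) and keeps the best optimum. Constraint relations
(`ψ₂ = ψ₁`, `ψ₁²`, `2ψ₁ − 1`) are recomputed from the free parameter in the
returned estimates, so they hold exactly rather than up to rounding.

**Boundary solutions.** When a risk-bearing cell class is entirely unobserved
(e.g. no `AA` case and no `AA`-producing mating, so `a₂ = 0`), the likelihood
increases monotonically as `ψ₂ → 0`: the supremum sits on the boundary and no
interior stationary point exists — a classical Newton–Raphson ascent diverges
there. The optimiser detects this (a transformed parameter beyond `|θ| = 12`,
far outside any interior optimum attainable at realistic sample sizes) and
sets a `boundary` flag. A rarer variant is the ridge `ψ₁, ψ₂ → ∞` jointly when
no family of the baseline (`aa`-type) class is observed. The same
vectorised routine fits whole arrays of datasets at once: all per-iteration
quantities are elementwise array operations plus a stacked 2×2/3×3 solve.

## Tests

LRTs are referred to chi-square with 2 df (Unr) or 1 df (Dom, Rec, Mult, Add).
A negative statistic within `1e−8` of zero is clamped to zero; anything more
negative indicates optimiser failure and raises. The TDT uses
`b = n₂ + 2n₅ + n₆ + n₈` transmitted vs `c = n₃ + n₆ + 2n₇ + n₉` untransmitted
risk alleles; it is undefined (error, not zero) when `b + c = 0`. The combined
score test adds dyad terms `b₁ = m₂ + m₅`, `c₁ = m₃ + m₆` and is referred
**two-sided** to the standard normal: with no dyads `z_com² = TDT` exactly,
so the two-sided rule is the unique choice consistent with the TDT's
chi-square decision. No multiple-testing adjustment is applied across the five
models (each answers a different scientific question); the CLI offers an
optional Bonferroni column.

## The simulation engine

`run_study` draws, per replicate, independent multinomials
`Triads ~ Mult(n, ·)`, `Dyads ~ Mult(m, ·)`, `Monads ~ Mult(s, ·)` from the
generating parameters, evaluates the requested statistics, and reports the
proportion of replicates exceeding the reference-distribution critical value
at each nominal level, with Monte-Carlo standard errors. Default study
configurations mirror the published design: `s = 50` monads with
`n ∈ {100, 200, 500}` triads and `m ∈ {0, n/4}` dyads for type-I error;
`n = 100` or `500` with `m ∈ {0, n/4}` and `s ∈ {0, 50}` for power; 100,000
replicates at full scale (the CI suite uses 10,000 — Monte-Carlo tolerances in
the tests combine both error sources). All replicates for a study come from
one seeded NumPy generator and are drawn as stacked arrays; identical
configuration (including seed) always reproduces the identical result. A
per-replicate substream scheme was considered and dropped: with sufficient
statistics the whole study is a handful of array operations, so there is
nothing to parallelise across processes.

**Failure accounting.** A replicate whose fit is degenerate, non-converged or
on a `ψ → 0/∞` boundary is counted as *failed* for that statistic: it enters
neither the numerator nor the denominator of the rejection proportion, and the
failure count is reported alongside (a rate above 1% warns, or errors under
`strict=True`). Silent inclusion either way would bias size and power.  This
policy is not cosmetic: under the null at `p = 0.05` with `n = 100`, `m = 0`,
`s = 50`, about 69% of replicates have no `AA`-bearing observation at all, the
ψ₂ estimate exists only in the limit `ψ₂ → 0`, and the chi-square reference
does not apply. The published type-I-error tables for the Unr and Rec models
at small `p` are reproduced by this package *only* as proportions over the
estimable replicates — including the two famously elevated entries at
`p = 0.05` (≈ 0.059 and 0.065 at nominal 0.05) — which identifies the
published values as conditional proportions of the same kind. Two caveats are
documented rather than hidden: the printed `p = 0.2` Unr/Rec entries are
~20% below what both the conditional and unconditional exact-MLE rejection
rates give (an unexplained artefact of the original optimiser), and in the
far tail (nominal 0.01, `p = 0.5`) the exact-MLE Unr rate is stably ≈ 0.0102
against a printed 0.00907.

## What the generator does and does not emulate

The generator reproduces exactly the stochastic mechanism the tests assume:
multinomial counts from the closed-form conditional probabilities, i.e.
perfect HWE, random mating, homogeneous ancestry, error-free genotypes and
exchangeable families. Passing simulation checks therefore validates the
inferential machinery, not robustness to genotyping error, population
stratification, Mendelian inconsistencies (the tabulator excludes and counts
those but the generator never produces them) or informative missingness of
parents (missingness here is by design, not genotype-dependent).

## Numerical choices and degenerate inputs

* logit/log transforms clamped at `|logit p| ≤ 16`, `|log ψ| ≤ 25`; boundary
  detection threshold `|θ| ≥ 12`.
* Newton: max 200 iterations, 40 halvings per line search, ridge
  `1e−9·(1 + max |diag H|)`.
* LRT negative-clamp tolerance `1e−8`; nesting violations beyond it raise.
* All-zero count vectors are legal everywhere (log-likelihood 0); tests on
  them are undefined and raise typed errors with guidance.
* Tie-breaking: rejection uses `statistic ≥ critical value`, so nominal level
  1.0 (critical value 0) rejects every evaluable replicate.

## Known limitations

Single marker, autosomal, two alleles; no covariates, no parent-of-origin or
maternal-effect terms, no stratification adjustment; no standard errors or
confidence intervals for `ψ` (the tests are likelihood-ratio based); dyad
parent sex is read but deliberately unused. Designed for candidate-marker
analysis — fitting five models per marker is orders of magnitude slower than
a TDT scan, though still ~milliseconds per marker.
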