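# Methods

## Scope and model

The package analyses quantitative carrier tests of laundry disinfection
run as an interlaboratory ring trial. One *run* of one laboratory under
one test condition yields nine log₁₀-scale endpoints: five log reductions
(LR, one per test strain: *P. aeruginosa*, *E. coli*, *S. aureus*,
*E. hirae*, *C. albicans*), cross-contamination of initially sterile
carriers on two growth media (RI-TSA, RI-MEA), and the microbial load of
the wash water on the same media (WW-TSA, WW-MEA).

Each endpoint × condition panel is treated as a one-way random-effects
design, Y_ij = μ + B_i + ε_ij, with independent normal laboratory effects
B_i (sd σ_B) and residuals ε_ij (sd σ_r). Reproducibility variance is the
sum σ_R² = σ_B² + σ_r², an identity the code maintains exactly. The model
is deliberately minimal: no device, operator or day factors — a ring trial
of this size cannot separate them from the laboratory effect.

## Quantification rules

* Countable window: a plate contributes only if 14 ≤ cfu ≤ 330
  (inclusive). The same window is applied to the 2-ml wash-water plates;
  the protocol does not state otherwise and a wider window would make the
  two sample types inconsistent.
* Carrier eluates: N = c / (0.4·(n₁ + 0.1·n₂)·d) over at most two
  consecutive ten-fold dilutions, d being the less dilute factor. When a
  full ladder is supplied, the least dilute level with a countable plate
  is chosen, plus its ten-fold neighbour when countable. If only the more
  dilute of two levels is countable it is treated as the sole dilution —
  the 0.1·n₂ weight only makes sense relative to a countable lower level.
* Censoring: if no plate is countable and the direct-dilution counts are
  below 14, the survivor count is set to 14 cfu/plate and the log₁₀ value
  is recorded at the detection limit: 1.54 (carrier eluates) or 1.15
  (wash water), as bit-exact constants. Fully overgrown samples (> 330
  everywhere) are an *error*, not a censoring — no substitute value
  exists on the high side. Control carriers (N₀) are never censored; a
  control below the countable range is a protocol failure.
* The limits are configuration values (`DetectionLimits`) so other plated
  volumes remain usable; the defaults reproduce the standard method
  (1.54 = log₁₀ 35 from 14 cfu in duplicate 0.4-ml direct plating,
  1.15 = log₁₀ 14 per wash-water plate).
* Replicate carriers of the same strain and role within a run are
  quantified separately and pooled by the arithmetic mean of their log₁₀
  counts before LR = N₀ − Na is taken. The collection-spreadsheet dialect
  therefore carries a `carrier` replicate column.
* Inoculum validity: N₀ must lie in [6.15, 8.15] log₁₀ for bacteria and
  [5.15, 7.15] for yeast (inclusive).

## Estimation

* `anova_mom`: σ̂_r² = MS_within; σ̂_B² = max(0, (MS_between −
  MS_within)/n₀), with n₀ the common replication when balanced and the
  effective replication n₀ = (N − Σnᵢ²/N)/(p−1) otherwise (needed e.g.
  when one laboratory misses a cycle). Negative between-lab estimates are
  truncated at zero unconditionally; the ANOVA F-test p-value for
  H₀: σ_B² = 0 is reported alongside rather than used as a gate.
* `reml`: the one-way restricted likelihood is profiled on the variance
  ratio λ = σ_B²/σ_r² ∈ [0, ∞); for fixed λ the residual variance has the
  closed form Q(λ)/(N−1), so a bounded scalar search (Brent, xatol 1e-12
  after a log-spaced grid bracket) suffices. On balanced data with an
  interior moment estimate the two estimators coincide (verified to 1e-6
  in tests, and against an independent REML implementation on unbalanced
  data).
* Exactly constant panels (every value pinned at a detection limit) are
  detected by the value range, not the sums of squares, so rounding dust
  cannot turn an all-censored row into a spurious nonzero component.
* Mean and CI: pooled-observation t interval, mean ± t₀.₉₇₅,ₙ₋₁·s/√n.
  The original report does not state its CI construction; nothing
  downstream depends on the interval except its collapse for constant
  panels.
* RSD = 100·S_R/mean requires a positive mean — given on the log₁₀ scale
  and the detection-limit floors, every reportable mean is positive.
* S_R/S_r classes: minor (< 2), clear (2–4), considerable (> 4). Ties at
  exactly 2 or 4 go to the middle class (the conventional footnotes write
  strict inequalities on both sides, leaving ties undefined). A degenerate
  S_r = 0 with S_R > 0 is classed considerable; S_R = S_r = 0 is minor.

## Outlier screening

Cochran's C = max(s²ᵢ)/Σs²ᵢ over the per-laboratory within-lab variances,
with the exact critical value C = 1/(1 + (p−1)/F₁₋α/p(n−1, (p−1)(n−1)))
(reproduces the classical printed tables to 4 decimals; cross-checked by
Monte-Carlo in the tests). Unequal replication uses the critical value at
the largest n, which is slightly liberal and is noted in the report.
Grubbs' two-sided single-outlier test uses the standard critical value
((n−1)/√n)·√(t²/(n−2+t²)) with t the α/(2n) quantile on n−2 df.

Screening runs per endpoint × condition: Cochran first (removing the
flagged laboratory's runs for that endpoint), then Grubbs (removing one
observation), for at most two passes, never removing past the point where
fewer than two laboratories would remain. α defaults to 0.05 for both
tests. Power characteristic: with 3 runs per laboratory a 5× inflated
within-lab sd is flagged in roughly three quarters of trials; from 4
replicates power exceeds 80% (measured by simulation in the tests).

## Synthetic ring trials

The generator emulates the study design: 7 laboratories (6 for the rinse
cycle) × 3 conditions × 3 runs, endpoint means preset from the published
precision report (shipped as package data; presets, not ground truth),
σ_B = 0.45 and σ_r = 0.40 by default (central tendency of the published
S_R/S_r panel). Censoring is applied on the survivor level: for LR
endpoints through the implied Na = N₀ − LR against the carrier limit, for
RI/WW directly — so effective-disinfectant conditions reproduce the
pile-up of identical censored values (S_R = S_r = 0) seen in real reports.
Laboratory effects are drawn independently per endpoint; a
`shared_lab_effect` switch makes them common per laboratory for
sensitivity analyses (real cross-endpoint correlation is unknowable
without raw data).

The optional plate-count layer forward-simulates colonies: λ = 10^y·0.4·d
per carrier plate across a ten-fold ladder (default to 10⁻⁶ so control
carriers at the top of the inoculum window remain countable), λ = 10^y per
wash-water plate, Poisson-drawn or deterministically rounded. Control
carriers are laid down at the midpoint of the inoculum validity window
(7.15 log₁₀ bacteria, 6.15 yeast), since the raw N₀ compilation was never
published.

What the generator does **not** emulate: wash-chemistry dose–response
(condition effects enter only through the mean presets), device effects,
operator drift, non-normal lab effects, and overdispersed (non-Poisson)
counting error. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness of the
laboratory method itself.

Two structural facts about the forward model are worth knowing:

* Wash-water endpoints above ≈ 2.5 log₁₀/plate cannot be regenerated
  through the plate layer: direct five-plate counting saturates at 330
  cfu/plate. Real trials evidently report such values anyway (their
  collection spreadsheets are not printed); in this package those
  simulated panels come back as missing rows, which the reports mark and
  the summary skips. Round-trip identity tests use loads inside the
  countable window.
* Near the detection limit the count quantization is coarse: at 17
  cfu/plate a rounding of ±0.5 colonies is ±0.015 log₁₀. The noiseless
  round-trip tolerance of 0.01 log₁₀ holds for loads whose selected
  dilution yields ≳ 35 cfu/plate, which the identity tests use.

## Problem sizes in the test suite

Property checks use the smallest designs that make the statistics
meaningful: 200 replicates of the 7 × 3 study design for parameter
recovery, 500 replicates for false-positive rates and power, 20 000 null
draws for the Cochran critical-value regeneration, and one 50-lab ×
50-run dataset whose 27 endpoint × condition cells are pooled for the
variance-decomposition check (a single cell's between-lab estimate has a
~20% sampling sd at 50 laboratories, so only the pooled comparison
supports a 5% tolerance). The whole suite runs in a few seconds.

## Known limitations

* The CI construction and the original study's exact outlier-removal
  policy (α, sidedness, lab-versus-run removal) are not documented in the
  source material; the defaults here are the conventional choices and are
  configurable.
* Published ratio classes were computed from unrounded statistics; the
  packaged reference table carries the printed classes verbatim, which
  occasionally disagree with the class implied by the rounded S_R/S_r
  columns beside them. The table is treated as authoritative.
* Uncensored quantification of very high wash-water loads would require a
  dilution series for wash water, which the standard's formula does not
  define; the package declines to invent one.
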