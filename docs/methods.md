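# Methods

## Model and assumptions

`hfrisk` treats the departments of a healthcare facility as nodes of a
weighted influence graph. Experts judge direct cross-infection influence
pairwise on an ordinal 0–4 scale; the method then assumes these judgments
can be averaged cardinally, propagated through indirect paths, and compared
across departments. Three further assumptions are inherited from the
underlying techniques:

- **Rank-weighted consensus.** An expert of rank r counts exactly r times
  as much as a rank-1 expert. The divisor of the weighted mean is the sum
  of ranks, which keeps the consensus on the original 0–4 (or 0–100) scale
  and makes the aggregation invariant to rescaling all ranks by a common
  factor. The downstream influence analysis is additionally invariant to
  the divisor choice altogether, because any uniform scaling of Z cancels
  in the normalization Z/S; only the weighted-sum side would notice.
  Infection-cluster and managerial-cluster panels are aggregated
  independently; their rank scales are never compared.
- **Geometric influence propagation.** Total relation is the series
  T = D + D² + … = D(I−D)⁻¹, i.e. influence attenuates multiplicatively
  along paths. Convergence requires spectral radius ρ(D) < 1; with
  D = Z/(max row sum) this holds for every input whose row sums are not
  all concentrated on one department, and is checked explicitly (a
  `ConvergenceError` names the condition otherwise).
- **Single-direction criteria.** All weighted-sum criteria point the same
  way: a higher value is a stronger case for elimination. No benefit/cost
  flipping exists in this application.

## Parameters that matter

| parameter | units / range | default | rationale |
|---|---|---|---|
| influence scale | integers 0–4 | fixed | ordinal anchors: none/low/moderate/high/very high |
| expert ranks | positive integers | 1–3 in practice | assigned by the facility's leadership |
| criterion weights | 0–100 | — | elicited from the managerial panel |
| risk criterion weight | 0–100 | 100 | infection risk is the study's primary concern, so it gets the maximal weight before joint re-normalization |
| risk mapping mode | `abs_minmax`, `rank_based`, `manual` | `abs_minmax` | see below |
| `top_k` shortlist size | 1–n | 4 | matches the case study's proposal; no claim it is a general rule |
| normalization constant | — | max row sum | a variant using max(max row sum, max column sum) is available via `include_columns=True` |

**Risk mapping.** The conversion of the net relation R−C into a 0–100 risk
criterion is genuinely open: both strong causes and strong receivers are
risky, so the default maps |R−C| linearly onto [0, 100] (`abs_minmax`).
When every |R−C| is equal the spread is degenerate and all departments
score 50, with a warning. `rank_based` spaces departments evenly on
[0, 100] by |R−C| rank, which is robust to outliers but discards
magnitudes. `manual` passes expert-curated scores through verbatim — the
case-study fixture uses this, since its published risk row is an expert
judgment informed by, but not a deterministic function of, the influence
analysis (it is not perfectly monotone in |R−C|).

## Numerical choices

- (I−D)T = D is solved with a dense LU solve rather than forming the
  inverse, for conditioning.
- Comparisons with zero (group membership, tie detection) use an absolute
  tolerance of 1e-9. A department with |R−C| ≤ 1e-9 is reported as
  `neutral` — membership is defined only for strictly signed values.
- Ties at the R−C extremes and in weighted-sum rankings resolve to the
  first department in canonical (input) order, via stable sorts; ties are
  logged.
- Weighted sums are reported at 2 decimals; full precision is kept
  internally.
- Aggregated consensus entries need not be integers.

## What the synthetic generator emulates — and what it does not

`hfrisk.synth` reproduces the *structure* the pipeline assumes: a
two-cluster panel (defaults: 7 infection + 7 managerial experts, ranks
drawn from {1, 2, 3}), 20 departments, 12 managerial criteria, influence
entries drawn categorically on {0..4} with configurable sparsity, and
managerial weights/values uniform on [0, 100]. The field data fix only the
scales, not the distributions, so uniform/categorical draws are used.

It does **not** model epidemiology: no transmission dynamics, no
correlation between a department's clinical function and its influence
profile, no inter-expert correlation beyond the planted structure. Passing
tests on synthetic data therefore demonstrate the *algorithmic* contracts
(aggregation, propagation, classification, ranking) — not that the method
recovers true infection risk in a real facility.

`generate_planted_structure` plants known ground truth for recovery tests:
a planted dispatcher rates 3–4 on every outgoing influence and receives
nothing; a planted receiver mirrors this; other entries are low noise
(exactly zero at `noise_level=0`). At zero noise the planted departments
are provably the R−C extremes, making recovery an exact oracle for the
cause/effect classification; recovery is checked over 50 seeds.

## Verification against the published case study

The packaged fixtures transcribe the case study's printed total-relation
and WSM tables exactly, preserving their mixed cell precision and known
defects (values are never corrected). Checks against printed values are
never tighter than the print precision itself; where whole columns are
printed at 2 decimals, per-cell comparisons are avoided in favor of the
4-decimal marginals. Two transcription-level anomalies are preserved and
documented in the fixture notes:

- the printed normalized-weight column sums to ≈1.368; MR10's 0.40865 is a
  suspected decimal-shift misprint of 0.04086 (the weighted cells and
  totals are internally consistent regardless, so the engine ingests the
  already-weighted cells directly);
- the ED16 column's printed cells sum to 35.63 against a printed total of
  36.05 — a 0.42 gap that no rounding of the printed cells can produce.
  The corresponding reproduction test asserts the printed total and
  therefore fails, deliberately: the fixture is not silently repaired.

The series-oracle check compares the solve-based T against the truncated
series Σ_{k=1..200} D^k at 1e-9. The truncation tail is of order
ρ^201/(1−ρ), which stays below 1e-9 only for ρ ≲ 0.89, so the sampled
spectral radii span (0.2, 0.88) — inside the convergent region ρ < 0.95 the
check is defined over.

Problem sizes throughout the test and acceptance runs (matrices up to
20×20, 100 random draws, 50 recovery seeds) match the case-study scale and
complete in seconds.

## Known limitations

- The raw per-expert matrices behind the case study were never published,
  so the fixture path replays the printed *outputs* (total-relation
  marginals, weighted cells); the end-to-end path from raw matrices is
  exercised on synthetic data only.
- The ordinal 0–4 scale is averaged as if cardinal — standard practice for
  this family of methods, but an assumption.
- `abs_minmax` risk scores are relative within one facility; they are not
  comparable across facilities.
- The final managerial decision (which shortlisted departments to actually
  eliminate) is outside the package's scope.
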