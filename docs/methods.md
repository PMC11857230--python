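# Methods

## The problem

Dispersive liquid–liquid microextraction (DLLME) concentrates trace
volatiles from an aqueous sample (here, wine) into a small organic phase by
injecting a mixture of a water-immiscible extraction solvent and a
water-miscible disperser solvent, forming a cloudy emulsion. Extraction
efficiency depends jointly on the identities and volumes of both solvents,
so tuning the method is a four-factor design-of-experiments problem with two
categorical and two quantitative variables, observed through GC-MS peak
areas for a panel of 36 aroma compounds.

## Design construction

The candidate set is the full factor grid: 5 extraction solvents
(chloroform, dichloromethane, hexane, pentane, chloroform:pentane 2:1) × 5
extraction volumes (500, 750, 1000, 1500, 2000 µL) × 3 dispersers (acetone,
acetonitrile, methanol) × 3 disperser volumes (500, 1000, 1500 µL) = 225
conditions. An exact n-run design is chosen to maximize det(XᵀX) of the
model matrix of the full response-surface model (25 columns) via Fedorov
exchange: starting from a random nonsingular n-run subset (with repetition
allowed — standard for exact designs), each run in turn is exchanged for the
candidate maximizing the determinant-ratio delta

    Δ(x_i → x_j) = d(x_j) − d(x_i) − [d(x_i)d(x_j) − d(x_i, x_j)²],

with d(u, v) = uᵀ(XᵀX)⁻¹v, until no exchange improves the criterion. The
procedure is monotone, so the returned design's criterion dominates every
intermediate design. Twenty random starts (one top-level seed) guard
against local optima; ties break first-found. On small candidate sets the
result matches exhaustive search (tested), and on the full grid the 60-run
design beats 1000 random designs (tested) — global optimality of an exact
design is NP-hard and not claimed.

## Model coding

Categorical factors are treatment-coded against chloroform (X₁) and acetone
(X₃); quantitative volumes enter in raw µL, quadratics as squared µL,
interactions as products of constituent columns. Raw-µL coding (rather than
the orthogonal ±1 coding common in RSM) is deliberate: the packaged
reference surface for ethyl octanoate has per-µL slopes (e.g. 36 area units
per µL of extraction solvent) that are only meaningful in raw units, and
treatment coding is what makes its solvent dummies (no chloroform or acetone
column) well defined. Column labels are deterministic (`X1[pentane]`,
`X2^2`, `X1[pentane]:X2`, …), so fitted coefficients are stable keys across
the pipeline.

## Fitting and backward elimination

Per analyte, ordinary least squares on the model matrix via scaled QR; rank
deficiency is a hard error naming the collinear columns, not silent
pivoting. Non-detect rows are excluded from the fit, never imputed as zero:
a failed phase formation is missing information about the response, not a
zero response. Term significance uses the partial F-test of the nested
model omitting the whole term — for single-column quantitative terms this
reduces to the square of the t-statistic (tested), and for categorical
terms it treats all dummies as one unit, which is the only coherent reading
of removing a "term". Elimination removes the single eligible term with the
largest p ≥ α (default 0.05) and refits, iterating to a fixed point;
intercept-only is a valid terminal state. Weak heredity (default on)
protects a main effect while any retained interaction contains it, matching
the hierarchical shape of the reference reduced model (X₁ and X₂ retained
alongside X₁:X₂). Quadratic terms are not treated as protecting their main
effect; they are removable independently.

Replicates enter as raw observations rather than replicate means (a config
choice); with triplicates this weights all runs equally and leaves the
F-tests their full residual degrees of freedom. The response defaults to
raw peak area; internal-standard area ratio is a switch.

## Grid prediction, ranking, consensus

Each reduced model is evaluated at all 225 conditions; negative predictions
are clamped to zero and flagged (aggregation uses the clamped values).
Ranking criterion 1 sums predicted areas over analytes; criterion 2 counts,
per condition, the analytes that place it in their top m = 3 predicted
responses. Ties are handled deterministically: sorts are stable on the
grid's enumeration order, and the top-m set uses competition ranking —
every condition tied with the m-th value is included, so an analyte with
all-equal predictions contributes to every condition. The consensus
optimum minimizes the sum of its two rank positions; among equals the
smaller total solvent volume (X₂ + X₄) wins — a practical preference for
limiting solvent waste — and a totally disjoint pair of top lists is an
error, since no automatic choice is defensible there. Analytes never
detected in any run have no fittable model and are excluded from both
rankings rather than contributing all-zero rows.

## Validation mathematics

Calibration is a least-squares line of area ratio on spiked concentration
(≥ 3 distinct levels required); σ is the residual standard deviation on
n − 2 degrees of freedom, r² the squared Pearson correlation (identical to
the coefficient of determination for a simple line). LOD = 3.3 σ/S and
LOQ = 10 σ/S, so LOQ/LOD = 10/3.3 exactly before rounding. Quantification
inverts the line and attaches a qualifier (`ok`, `below_LOQ`, `below_LOD`,
`above_range`) instead of censoring, leaving exclusion decisions to report
consumers. Recovery is R = (C_o − C_b)/C_s × 100 from the means of paired
spiked/unspiked measurements. RSD uses the sample (n − 1) standard
deviation, appropriate at the small n of replicate extraction studies;
intra-day RSD averages per-day RSDs and inter-day RSD pools all
measurements across days (the more conservative pooling choice).

## Synthetic data generator

The generator stands in for the wet-lab study with the structure the
analysis assumes:

- **Design responses**: mean response = ground-truth linear predictor at the
  run's condition; observed = mean × (1 + ε), ε ~ N(0, CV²), truncated at
  zero. Noise is multiplicative (constant CV, default 5%) because precision
  in this field is quoted as RSD%, a CV-scale statement; replicate RSD
  converges to CV × 100 (tested at n = 1000). Non-detects are deterministic
  per failing solvent — phase-formation failure is categorical, not
  probabilistic — and three analytes of the default 36-compound roster
  (β-citronellol, trans-2-hexen-1-ol, geraniol) are never detected at all,
  exercising the exclusion path.
- **Ground truths**: the reduced ethyl octanoate surface is packaged
  verbatim as a fixture; the other 35 analytes get seeded random surfaces
  whose qualitative structure matches the study system (chloroform-family
  solvents and acetonitrile dispersers favored, response increasing in
  extraction volume, disperser volume nearly inert). At zero noise the
  generator is an exact evaluator of the linear predictor (oracle equality
  on all 225 conditions, tested).
- **Calibration / matrix studies**: six-level duplicate series with known
  slope and σ for closed-form LOD/LOQ checks; paired spiked/unspiked tables
  whose true recovery is the matrix-effect factor × 100 by construction
  (drawn in 0.8–1.2 per matrix). The pipeline spikes at 1×/3×/10× each
  analyte's baseline so the spike dominates baseline noise, as a real
  validation protocol would.

What passing tests on this generator do **not** show: robustness to
integration artifacts, co-elution, heteroscedasticity beyond constant CV,
between-day drift (a single CV only; no day effect is simulated by
default), or model misspecification — real response surfaces need not be
polynomial in volume.

## Problem sizes and numerics

Defaults: 60-run design from 20 exchange starts; 36 analytes × 3
replicates; 1000-dataset Monte Carlo for the elimination-calibration check
(on a 40-observation toy model, where the per-term null retention rate is
within binomial 99% bounds of α); 1000-replicate noise-convergence checks.
These sizes keep the full suite and the acceptance script in the
seconds-to-minutes range while leaving Monte Carlo error well inside the
asserted tolerances. Exchange uses rank-one delta updates with a fresh
inverse after each accepted swap (a 25 × 25 solve, cheap and drift-free);
QR rank checks use column-normalized matrices with tolerance 1e−9 so µL²
columns cannot mask deficiency; det(XᵀX) is computed via slogdet and
reported as 0 for singular matrices rather than a spurious negative.

One root seed expands into per-stage child seeds via
`numpy.random.SeedSequence.spawn` (order: design, responses, calibration,
matrix), so stages rerun in isolation reproduce the pipeline's streams;
rerunning a config yields byte-identical CSVs (tested).

## Known limitations

- Exact D-optimality is heuristic (multi-start exchange), as in all
  practical exact-design software.
- The three "never detected" analytes are excluded rather than modeled by a
  detection-probability mechanism.
- Quantification assumes the calibration line extends to the measured
  ratio; no weighted regression for heteroscedastic calibration.
- The ranking reports point predictions only; no uncertainty propagation
  onto the rankings.
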