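# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Similarity screen (stand-in)

The original campaign used a proprietary attention-based multi-level
molecular representation. That model is not reproducible from public
information, so this package's screen is a *declared stand-in* that keeps
the published contract — three descriptor levels fused into one similarity
in [0, 1], thresholded at 0.65 strictly — while making the levels explicit:

* **Level 1 (1D)**: scalar physicochemical descriptors (MolWt, MolLogP,
  TPSA, H-bond donors/acceptors, rotatable bonds, ring count, Fsp³), each
  divided by a fixed typical-range constant so no single descriptor
  dominates the cosine.
* **Level 2 (2D)**: Morgan fingerprint (radius 2, 1024 bits), compared by
  Tanimoto.
* **Level 3 (3D proxy)**: topological shape/complexity descriptors (Kier
  κ₁–κ₃, valence χ, Labute ASA, Balaban J, Bertz CT), again range-scaled.
  True conformer-derived features would require an embedding step; the
  proxy keeps the level structure without one.

Cosine similarities are mapped to [0, 1] by (1 + cos θ)/2; the fused score
is the equal-weight mean of the three levels (weights configurable).
Retention uses strict inequality; the degenerate threshold 1.0 keeps only
exact-profile duplicates. Ties for the best reference break
lexicographically for reproducibility. The stand-in makes *no claim* of
reproducing the original 1745-compound candidate set; what is preserved is
the operating behaviour (planted reference-like ligands score high, random
chemistry scores ≈ 0.35–0.55 fused) and the thresholding semantics.

## Receptor triage

Triage is pure bookkeeping and is implemented exactly as published:
missing-structure records first (1028 → 1006 in the study-scale fixture),
then the *pooled* pocketless-or-anti-target exclusion (→ 908). The pooled
count is what the source workflow reports; the split is also emitted for
verbose diagnostics but never validated, since no published split exists.
Anti-target membership is an explicit flag/blocklist, not name matching.
Structure preparation (repair, protonation) is out of scope; a manifest
either has a structure path or it does not. The top-ranked pocket centers
a cubic box, default edge 25 Å.

## Mock docking backend

Real docking is behind an adapter contract (structure path + box + ligand
→ best-pose affinity, failures surface both ids). The mock backend maps a
BLAKE2b hash of `(ligand_id, receptor_id, seed)` through the inverse CDF
of a normal(−6.0, 1.0) truncated above at 0 kcal/mol, quantized to 0.001.
Consequences that the pipeline relies on:

* cells are independent of assembly order (parallel-safe by construction);
* a matrix is reproducible from ids + seed alone;
* fixture sidecars can plant specific pair scores without touching the
  background.

The background location/scale are arbitrary but declared; only orderings
matter downstream. With 908 columns, the expected top-20 background mean
magnitude is ≈ 8.3–8.9, so plants at ≈ 10–11 dominate rankings and plants
at ≥ 9 on anti-target columns trip the 8.5 filter with margin.

## Prioritization

Scores are stored engine-convention (negative favorable); all ranking uses
magnitudes A = −s. The final binding score is the mean of the k = 20
largest magnitudes per ligand row; contributing receptors are reported in
descending magnitude with receptor-id tie-breaks. Rows shorter than k
average what is available (logged), rather than erroring.

The anti-target rule as literally published ("scores less than 8.5 were
excluded") contradicts the workflow's stated goal of removing strong mTOR
binders. The default here excludes a ligand when its *maximum anti-target
affinity magnitude ≥ 8.5*; the literal direction is available via
`literal_antitarget_rule=True`. Anti-target receptors are dropped from the
ranked panel by triage but still docked as extra matrix columns so the
filter has data; by default those columns do not contribute to the top-k
mean (`antitarget_in_topk=False`), which makes filter-then-rank and
rank-then-filter equivalent. Survivors are ranked score-descending with
ligand-id tie-breaks; the top n = 20 are selected.

## Melt-curve fitting and ΔTm calling

The melt model is the plateau sigmoid used for thermal proteome profiling
data, parameterized in reciprocal temperature:

    f(T) = (1 − p) / (1 + exp(b − a/T)) + p,   T in kelvin,

with slope a (K), offset b, plateau p ∈ [0, 0.5). The melting point has
the closed form Tm = a / (b − ln(0.5/(0.5 − p))) and the fit is flagged
unconverged when the optimizer fails on all starts, p pins near ½, Tm
falls outside [min T − 10, max T + 10] °C, or the data are flat (R²
undefined). Fitting is multi-start nonlinear least squares (a data-driven
start from the half-height crossing plus seeded jitters, 5 starts,
bounds a ∈ [10³, 5·10⁵], b ∈ (0, 5·10³], p ∈ [0, 0.499]).

Fold changes are anchored to 1 at the lowest temperature (the reference
spectrum is acquired at 37 °C). This anchoring divides the curve by
f(37 °C), which is only ≈ 1 when the transition sits well inside the
grid; for Tm ≲ 45 °C on the 37–67 °C grid it biases the refit Tm by
~0.1–0.2 °C. The generator draws Tm in 46–56 °C, where the bias is
negligible; ΔTm is additionally robust because the bias largely cancels
between conditions.

ΔTm = Tm(treated) − Tm(vehicle) is only computed when both fits converge
with R² ≥ 0.8 (standard QC for this model family; prevents noise-driven
calls). A protein is called stabilized when ΔTm > 2 °C, strictly. The
10-point 37–67 °C grid and the 7-point 37–61 °C grid run through the same
code path. Shared targets are the set intersection of stabilized ids with
a user-supplied predicted-target id list.

## ITC one-site model and fit

Heats follow the Wiseman single-site isotherm with *displacement-mode*
volume bookkeeping: the cell volume V₀ is constant and each injection of
volume v dilutes current cell contents by (1 − v/V₀) while delivering
titrant at the syringe concentration. Bound ligand comes from the one-site
quadratic with site concentration N·[M]; the heat of injection i is
ΔH·V₀·(B_i − B_{i−1}(1 − v/V₀)) plus a constant dilution offset. Protocol
defaults: 300 μM syringe, 15 μM cell, 300 μL cell, one discardable 0.2 μL
injection then 19 × 2 μL, 25 °C. The dilution offset default in the
generator is 0.5 μcal/injection — small against plant-scale binding heats
(≈ 5–6 μcal) but large enough that a fitter ignoring the baseline fails.

Noise is additive with per-injection SD = (noise level) × that injection's
binding-heat magnitude, plus a baseline floor of 10% of the largest
binding heat — instrument noise does not vanish at saturation. The fitter
matches this model: residuals are inverse-variance weighted using
SDs estimated from the data *before* fitting (weights must not depend on
the current model; model-based weights are degenerate because inflating
K_D shrinks the predicted heats and hence the weighted residuals).
Optimization is multi-start least squares over (log₁₀ K_D, N, ΔH, offset)
with K_D starts spanning 0.1–100 μM. A fit is flagged unidentifiable when
the isotherm does not beat a constant-offset model on AICc (the
buffer-only control case); K_D is then meaningless and callers must not
use it. At zero noise the round trip is exact to < 10⁻⁴ relative.

## Inhibition-mode classification

The three rate laws (v as a function of substrate S and inhibitor I, with
α = 1 + I/K_i):

* competitive: v = V_max·S / (K_m·α + S)
* noncompetitive: v = V_max·S / ((K_m + S)·α)
* uncompetitive: v = V_max·S / (K_m + S·α)

are each fitted to *untransformed* rates (multi-start in K_i) and compared
by small-sample AIC (AICc, k = 3). The mode is the argmin. Double-
reciprocal (Lineweaver–Burk) per-[I] straight lines are fitted to
replicate-mean rates and their 1/v-axis intercepts reported as a
diagnostic only: an ATP-competitive inhibitor leaves V_max — hence the
1/v-axis intercept — unchanged across inhibitor levels, which is the
published qualitative signature. Reciprocal-space *fitting* is avoided
because the transform distorts the error structure. The default design is
ATP at 25/50/100 μM with inhibitor at 0/10/15 μM (the uninhibited control
plus the two published doses) and 3 replicates; the generator's default
inhibitor grid is the two published doses. On this design at 3% noise,
single-experiment intercepts scatter with ≈ 5% SE (V_max at the highest
inhibitor level is an extrapolation from S ≤ 1.5·K_m,app), so the
common-intercept check is asserted on seed-averaged intercepts; mode
calls themselves are per-experiment.

Generator defaults K_m = 25 μM, V_max = 100 (arbitrary luminescence
units), K_i = 8.5 μM; K_i was set via Cheng–Prusoff from the published
potency at [S] = K_m, making the kinetic and dose–response fixtures
mutually consistent.

## Dose–response and Cheng–Prusoff

The IC50 fit is a four-parameter logistic in dose space,
resp = bottom + (top − bottom)/(1 + (d/IC50)^h), evaluated exactly at
`top` for d = 0 so the zero dose anchors the top plateau and the 1000 μM
dose the bottom; bottom is bounded at ≥ 0. The generator uses the
published 10-dose grid with 5 replicates and 5% multiplicative noise.
K_i = IC50/(1 + [S]/K_m) is provided as the competitive-consistency check.

## What the synthetic data does and does not emulate

The generators reproduce the *structure* of the study's inputs — counts,
grids, protocols, planted signal sizes — with declared noise models and
seeded randomness (every generator draws from its own seed-derived
substream; identical spec + seed ⇒ identical outputs). They do not emulate
real chemistry (descriptor profiles are numeric stand-ins, not molecules),
force-field energetics (the mock backend is a hash), mass-spectrometric
artifacts (no missing values, no abundance-dependent noise in melt
curves), or instrument-specific ITC baselines beyond a constant offset.
Passing tests therefore demonstrate that the *statistical machinery* —
triage accounting, top-k aggregation, exclusion logic, the fitters and
their operating characteristics — behaves correctly at the stated noise
levels; they say nothing about upstream data generation in a real
campaign.

## Problem sizes

Desk-scale fixtures use 120 ligands × 80 receptors (analysis scripts) or
60 × 60 (unit tests); the full-funnel runs use the study-scale counts
(1745 ligands, 1028-receptor manifest) with the mock backend, which
assembles the ≈ 1.65 M-cell matrix in a few seconds. Deconvolution runs
use 50 proteins × 2 conditions × 10 temperatures; mechanism checks use 20
seeds per inhibition mode. These sizes were chosen so every analysis
completes in seconds while keeping enough replication for the operating-
characteristic checks (sensitivity/false-call rates, classification
accuracy) to be meaningful.

## Known limitations

* The similarity stand-in is not the original representation model; its
  retained set on real chemistry will differ.
* The pooled 98-exclusion count is validated, not its split.
* Single-titration ITC K_D at 3% noise carries ≈ 5–10% statistical error;
  replicate titrations would be needed for tighter estimates.
* The melt-curve anchor normalization slightly biases Tm for transitions
  near the grid edge (see above).
* The pipeline's NA policy is strict completeness; the opt-in row-drop
  policy for failed backend cells is logged but no partial-row top-k
  variant is offered.
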