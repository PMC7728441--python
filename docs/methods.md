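# Methods

This note documents the models, estimators, numerical choices and known
limitations of `bmpdiversity`, in the spirit of a statistical software
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spatial profile pipeline

Raw input is a per-embryo column-average intensity trace along the
dorsal–ventral axis in % embryo length (ventral = 0, dorsal = 100).

1. **Binning.** Intensities are averaged into half-open bins
   `(k·0.5, (k+1)·0.5]` of 0.5% embryo length; a column at exactly 0 joins
   the first bin. Bins with no contributing column carry NaN — missing
   values propagate and are excluded from every subsequent sum, never
   imputed. Binning is idempotent on already-binned data.
2. **Background.** Three conventions, reflecting how FISH and
   immunofluorescence data are corrected: a position-wise control-embryo
   average (`profile` mode), a scalar image-corner value (`scalar`), or
   the mean of the dorsal-most 5% at the earliest timepoint
   (`dorsal_reference`). Subtraction may produce negative intensities;
   they are kept.
3. **Trimming.** Bins whose centers fall in the outer 5% on each side are
   dropped (the outermost columns average few pixels and are unreliable).
   The trim fraction is a parameter; centers exactly on the boundary are
   kept.
4. **Affine normalization.** Each embryo is modeled as
   `I_n(x) = A_n·c̄(x) + b_n` against the across-embryo arithmetic mean
   shape `c̄(x)`. The objective `Σ_i (I_n(x_i) − A_n·c̄(x_i) − b_n)²` is
   exactly quadratic in `(A_n, b_n)`, so the minimizer is computed in
   closed form (simple linear regression of `I_n` on `c̄`) rather than by
   an iterative simplex search — identical minimum, no tolerance
   ambiguity. `c̄` is estimated in a single pass; it is not re-estimated
   after normalization. Normalized profiles are `(I_n − b_n)/A_n`; `A_n = 0`
   is rejected as degenerate. Per-gene mean profiles divided by their
   maximum are a display-layer convention only; statistics use the
   un-max-scaled normalized profiles.
5. **Gaussian fit and range.** `A·exp(−(x−μ)²/ς)` is fitted by bounded
   Nelder–Mead from the initial guess (300, 20, 10000) inside the boxes
   A ∈ [300, 1e5] a.u., μ ∈ [−50, 50] %, ς ∈ [100, 1e5] %², with at most
   10000 function evaluations and 5000 iterations. Note ς is the
   "2σ²-style" width: ς = 2σ² of the standard parameterization. The
   expression range is `r = μ + √(ς/2)` — the position where the curve has
   fallen to e^(−1/2) of its peak, i.e. μ + σ. Per-embryo ranges are
   averaged per gene (mean ± SEM). Margin expression is the mean
   normalized intensity over bin centers in [5, 10]% embryo length.

### Bounded Nelder–Mead

The simplex method is unconstrained, so boxes are enforced with a smooth
sine transform of each coordinate onto its interval (the `fminsearchbnd`
construction); parameters whose boxes span several decades (amplitudes,
width parameters, rate constants) are transformed in log10 space so simplex
steps are geometrically sensible. A start exactly on a bound is legal; the
initial simplex steps 0.25 rad in transformed coordinates, wide enough to
leave the bound. Convergence tolerances are tight (xatol 1e−10,
fatol 1e−12) so the iteration caps, not the tolerances, are the binding
limits.

## Temporal onset fitting

Counts on the half-hourly 2.75–7.25 hpf grid are fitted with
`(A/2)(1 + erf((t−ν)/(τ√2))) + b` by the same bounded Nelder–Mead, from
(1000, 5 h, 1 h, 100) inside A ∈ [100, 10000], ν ∈ [3, 7] hpf,
τ ∈ [0.05, 3] hpf, b ∈ [0, 1000], with the same iteration caps. The
activation time is `t_act = ν − 1.5·τ`, on the *early* side of the
inflection: the curves are increasing, so they cross the activation level
before ν. The constant is exactly 1.5 as conventionally printed, although
two mean average deviations of a normal are ≈ 1.596·σ. Activation times
are computed per repeat and then averaged; maternally contributed genes
(e.g. id2a, smad6a) are excluded from summaries via an argument, not
hard-coded. A flat series cannot be represented exactly (A ≥ 100): the fit
degenerates gracefully by pinning A low and/or τ high.

## Pulse kinetics

Time is handled in seconds internally, with t = 0 at light onset and the
pulse occupying [0, t_L] (t_L = 1800 s). CSV timestamps are "minutes
post-exposure" (clock starts at light OFF): `t = 60·minutes + t_L`.
Sibling subtraction (injected − uninjected) isolates the optogenetically
induced components; repeats are kept separate, and negative values after
noise or subtraction are retained without clipping.

### Method 1

`dTo/dt = σ·Po(t) − λ·To` with `Po` a degree-5 least-squares polynomial
through the measured pSmad pulse. The polynomial is fitted to the
across-repeat average of the subtracted pSmad series — one input curve
reused for all gene fits, mirroring how a single measured signaling time
course drives all gene models — and is clamped to its endpoint values
outside the fitted window, because a quintic diverges immediately outside
its data support. The original analysis simulated this model in a one-cell
(10 μm) spatially homogeneous no-flux domain; that PDE reduces exactly to
the scalar ODE implemented here.

Per repeat, `(To(0), σ, λ)` is fitted by bounded Nelder–Mead
(σ, λ ∈ [1e−5, 0.1]/s log-spaced, To(0) ∈ [−100, 100] a.u.) from zero
initial guesses clipped onto the boxes, at most 500 iterations.
`R² = 1 − SSD_min/Σ(L − L̄)²`; zero-variance data yield a missing R².
Across-repeat summaries report mean and n−1 sample SD per gene.

Two forward models exist for this ODE and a test pins them together at
1e−8: `simulate_induction` (adaptive LSODA, rtol 1e−10) is the reference
contract, while the fitting objective uses an exact piecewise
exponential-integrator solution — for a polynomial input the update
integral `∫ e^{−λ(h−u)}·u^k du` has a closed form (upward recurrence,
switching to a beta-function series below |λh| = 0.5 where the recurrence
cancels) — which is machine-precision for this input class and ~100×
faster per objective evaluation.

### Method 2

The linear system

    dPe/dt = k1 − k2·Pe
    dPo/dt = k3·[θ(t) − θ(t − t_L)] − k2·Po
    dTe/dt = k4·Pe − k5·Te
    dTo/dt = σ·Po − λ·To

is solved in closed form branch-wise (before, during, after the pulse);
each component is a sum of exponentials, continuous across the branch
points, with initial conditions `Pe(0) = δPe + k1/k2`, `Po(0) = δPo`,
`Te(0) = δTe + k1·k4/(k2·k5)`, `To(0) = δTo`. θ(0) = 1 (light on at t = 0);
the measure-zero boundary convention is covered by a continuity test, and
comparison grids avoid exact t = 0 and t = t_L. The forms have removable
singularities at k2 = λ, k2 = k5, λ = 0, k5 = 0, which are rejected as
degenerate; exponent arguments are clipped at ±700 purely as an overflow
guard far outside plausible rates.

Fitting is two-stage unconstrained least squares (scipy `trf`,
Jacobian-based scaling, tolerances clamped at machine epsilon, caps 20000 /
10000 evaluations): stage 1 fits (δPe, δPo, k1, k2, k3) simultaneously to
the two pSmad arms from (0, 0, 0, 0.00167, 0); stage 2 holds those fixed
and fits (δTe, δTo, k4, k5, σ, λ) to the two transcript arms from
(0, 0, 0, 0.00167, 0, 0.00167). No sign constraints: negative fitted decay
constants are admissible and must survive reporting. Because the
six-parameter stage-2 surface has local minima — the prescribed start
reproducibly converges to an inferior optimum on noisy data — the default
start is supplemented by a deterministic 4-point grid of alternative
(k5, λ) starts (0.0005 and 0.005 each) and the lowest-SSD solution is
returned. R² is computed over the concatenated two-arm residuals,
analogous to the Method-1 formula.

## Diversity statistics and normalization

`cv(x) = σ(x)/μ(x)` with across-gene mean and n−1 SD at each position;
positions with non-positive mean are reported missing rather than signed or
infinite. cv is invariant under common positive rescaling of all profiles.
Significance testing uses the unpaired two-tailed equal-variance t-test
(pooled variance, df = n_a + n_b − 2) with α = 0.05 on raw p-values; no
multiplicity correction is applied by default, matching per-gene/timepoint
reporting practice. Degenerate zero-variance comparisons return p = 1
(equal means) or a flagged p = 0.

Housekeeping normalization scales each lane of a lane × gene count table by
(grand geometric mean / lane geometric mean) of a reference gene set,
applied sequentially for positive spike-in controls and then housekeeping
genes. The composition is order-insensitive up to a global scale; the
control-first order is the documented convention. The operation is
idempotent.

## Synthetic data

The generator emulates three dataset families at the study's designs:
bell-shaped spatial profiles `A_n·G(x) + b_n` on the 0.5% grid, erf-CDF
temporal onsets on the half-hourly 2.75–7.25 hpf grid (10 points), and
sibling-paired pulse responses from the closed-form 4-ODE model on the
10-point post-exposure grid {−30 … 110} min with t_L = 1800 s. Three
repeats and 10 embryos are the default replication levels.

Defaults anchored to the study conditions: the pSmad pulse parameters are
the published best-fit values (k1 = 0.1429 a.u./s, k2 = 0.000900/s,
k3 = 0.954 a.u./s, δPe = −76.19, δPo = 264.1 a.u.); the reference gene's
(σ, λ, δTe, δTo) follow the published bambia closed-form fit. k4 and k5
are not published anywhere; they are set once to 0.001/s and 0.0005/s,
plausible transcript activation/decay rates that put endogenous counts on
the NanoString scale of hundreds of a.u. Embryo scales A_n are log-normal
around 1 (SD 0.2 in log space) and offsets b_n are N(0, 10 a.u.), drawn
once per design seed.

Noise is additive Gaussian on intensities and counts — consistent with
arithmetic mean ± SEM reporting — with SD a design parameter (default
20 a.u., about 2% of a typical ~1000 a.u. peak). This is a stand-in, not a
claim about nCounter chemistry or imaging shot noise: real NanoString
counts are heteroscedastic and non-negative, real profiles have spatially
correlated errors. Passing recovery tests therefore demonstrates estimator
correctness under the assumed error model, not robustness to every failure
mode of real data. One root seed streams per-embryo/per-repeat substreams,
so identical (truth, design, seed) triples are bit-identical; counts may go
negative after noise or subtraction (no clipping).

Recovery studies use noise SD = 2% of the relevant noiseless peak
(pSmad arms ≈ 1050 a.u. → SD 21; transcript arms ≈ 850 a.u. → SD 17;
spatial profiles → SD 0.02·A per gene). Problem sizes — 100 Method-1 fits,
200 temporal fits, 3 genes × 10 embryos for the spatial route, 20 random
parameter sets for the closed-form/ODE comparison — are chosen so the full
validation runs in about a minute on one core while keeping Monte-Carlo
error well below the tolerances being checked.

## Known limitations

* No image processing: the pipeline starts from extracted 1D column
  profiles; mask drawing, rotation and projections are upstream.
* The pulse model is a single well-mixed compartment; no spatially
  resolved signaling.
* Uncertainty is across-repeat SD only; no likelihood-profile or Bayesian
  intervals.
* The affine normalization's mean shape is estimated once, not
  iteratively re-fitted.
* Maternal transcript decay is not modeled; maternally contributed genes
  are simply excluded from activation-time summaries.
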