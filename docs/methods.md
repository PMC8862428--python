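# Methods

## Model

The nonessential activator scheme treats the two ATPase sites of the
transporter homodimer as independent and assumes rapid-equilibrium binding
of MgATP (T) and the activator/transported substrate GSSG (S):

    E + T  <->  ET      (K_T)
    E + S  <->  ES      (K_S)
    ET + S <->  ETS     (α·K_S)     ES + T <-> ETS  (α·K_T)
    ET  -> E + products   rate k
    ETS -> ES + products  rate β·k

giving the specific velocity

    v/E_T = k (T/K_T + β S T/(α K_S K_T)) / (1 + T/K_T + S/K_S + S T/(α K_S K_T)).

Only binding and hydrolysis are modeled; ADP-bound and product-release
states are not. At every fixed S the law is exactly hyperbolic in T with
apparent constants k_obs(S) = k(1+βS/αK_S)/(1+S/αK_S) and
K_T_app(S) = K_T(1+S/K_S)/(1+S/αK_S); the identity
v = E_T·k_obs(S)·T/(K_T_app(S)+T) holds algebraically and is enforced in the
test suite to 1e-10 relative over randomized parameter sweeps. Limits:
k_obs → βk and K_T_app → αK_T as S → ∞; α = β = 1 collapses the model to
plain Michaelis–Menten, independent of S.

Parameter units: k and all turnover numbers are min⁻¹ *per transporter
homodimer* (MW 135 kDa — the same mass used in the mass→molar conversion, so
rates and molarity stay on one basis); K_T, K_S in mM; α, β dimensionless.
All five parameters are validated strictly positive (floor 1e-12, since the
expressions divide by α·K_S). Output headers state the per-homodimer basis.

## Synthetic assay generator

The generator emulates the molybdate/phosphate colorimetric protocol that
produced the real data:

- design: MgATP ∈ {0, 0.1, 0.2, 0.5, 1, 2, 5, 10} mM × GSSG ∈ {0, 1, 2.5,
  5, 10, 20} mM (48 cells), sampled at 0, 5, 10, 15 min;
- replicates: 6 per cell in detergent and proteoliposomes, 3 in nanodiscs;
- loading: 0.05 mg/ml protein; in nanodiscs the transporter is
  135/(135 + 2·25) = 0.73 of that mass (two 25 kDa scaffold proteins per
  transporter), giving 0.27 µM instead of 0.37 µM transporter;
- phosphate accumulates linearly, Pi(t) = (v/E_T)·E_T·t — steady state is
  assumed to hold over the whole 15-min window;
- each reading is perturbed by independent Gaussian noise with
  sd = cv·reading + additive_floor. Defaults cv = 0.05 and floor = 0.5 µM
  phosphate: cv = 0.05 keeps global R² of refits in the 0.90–1.00 band that
  real fits of this assay report, and 0.5 µM is a plausible blank-level
  scatter for an 850 nm colorimetric readout. The t = 0 reading carries the
  same noise (a nonzero blank is possible); a flag switches to an assumed
  exact zero.

Rates are then *extracted*, not copied, from each time course: the OLS slope
of Pi versus time with free intercept, divided by transporter molarity.
Because a 4-point slope averages reading noise, the rate-level CV is about
0.55× the reading-level cv (≈2.7% at cv = 0.05); the replicate-CV test
asserts this proportionality band rather than equality.

What the generator does **not** emulate: absorbance calibration (it works in
phosphate concentration directly), substrate depletion or product inhibition
(accumulation is strictly linear), background hydrolysis (no transporter-free
blank), detergent/liposome physics, or orientation mixtures beyond a scalar
factor. Passing recovery tests therefore demonstrate estimator correctness
and design identifiability under this noise model — not robustness to
curvature in real time courses or to correlated plate effects.

The orientation correction is a separate, explicit operation: measured
proteoliposome rates are doubled (factor 2.0 by default: roughly half the
reconstituted transporters face away from the added MgATP), with a flag
guarding against double application. The simulator always produces
*measured*-scale rates, so recovery experiments compare like with like.

## Fitting

All fits minimize unweighted sums of squared residuals, matching how the
original analysis was done, even though high-rate cells have larger absolute
scatter. The global activator fit targets the 48 replicate-*mean* rates
(replicate-level fitting is available behind a flag). Per-GSSG hyperbolic
fits use the same machinery with (kcat, Km).

Numerical choices:

- parameters are optimized as logs, making positivity structural and the
  α–K_S/β ridge better conditioned; scipy's Levenberg–Marquardt with
  ftol = xtol = 1e-12, gtol = 1e-10, ≤10,000 evaluations per restart;
- multi-start: a data-driven start (k₀ = max basal mean rate, K_T₀ = MgATP
  concentration nearest half of k₀, K_S₀ = median positive GSSG, α₀ = 1,
  β₀ = max-rate ratio) plus 15 Latin-hypercube points log-uniform in a
  [p₀/4, 4p₀] box, 16 starts total (configurable). Winner = lowest SSR,
  ties broken by fewest function evaluations — deterministic given the seed;
- standard errors: Gauss–Newton covariance s²(JᵀJ)⁻¹ in log space at the
  optimum, mapped to the linear scale by the delta method (SE_p = p·SE_log p)
  so they are comparable to conventionally reported asymptotic errors. A
  case-resampling bootstrap (within-cell resampling of replicates, ≥100
  resamples, refit per resample, percentile intervals) is provided as a
  cross-check; refit failures are counted and >20% flags the fit unstable.
  No claim is made that either reproduces the error model behind any
  particular published SE;
- R² = 1 − SSR/SStot with SStot about the mean of the observed rates
  entering the fit, reported globally and per GSSG curve;
- degenerate inputs fail loudly: <2 distinct time points, <3 MgATP levels,
  all-zero rates, and — for the global fit — a design without a GSSG = 0
  series (the basal k is unidentifiable without it).

The recovery harness repeats simulate→fit and reports per-parameter bias,
RMSE, median relative error, and the fraction of runs within tolerance
(default 15% relative).

## Design identifiability and known limitations

On the standard design the noise-free global fit recovers all fifteen
parameters (three conditions × five) to two decimals from every restart —
the optimum is unique and reachable. Under realistic noise, identifiability
is condition-dependent: the detergent and proteoliposome parameter sets have
α·K_S ≈ 13.7 and 33.8 mM, inside or near the 0–20 mM GSSG range, so k_obs(S)
curvature separates α from β and all five parameters are recovered within a
few percent. The nanodisc set has α·K_S ≈ 97 mM: 20 mM GSSG reaches only
~20% of saturation, the initial slope (β−1)·k/(α·K_S) is essentially the
only well-determined α,β-combination, and simulate→refit estimates of α and
β scatter several-fold along the ridge (sampling SDs ≈ 5.6 and 34 at
reading cv = 0.05 with triplicates) even while k, K_T, K_S and the derived
k_obs(S) curve over the observed range stay tight. Asymptotic SEs at a
converged optimum understate this dispersion. Practical implication: to pin
down nanodisc-scale α and β, the assay needs GSSG well above 20 mM or many
more replicates; the bootstrap intervals, not the asymptotic SEs, give the
honest picture.

Per-GSSG Michaelis–Menten Km trends can disagree in sign with
K_T_app(S) at α near 1 (a ~2% predicted increase is smaller than Km's
sampling error), so small printed Km changes between GSSG levels should not
be over-interpreted; the package reports both the per-level fits and the
model curve and leaves reconciliation to the reader.

Problem sizes used by the shipped checks: the standard 48-cell design with
its sextuplicate/triplicate replicates (288 or 144 time courses per
dataset), 16 restarts per fit, 100–200 bootstrap resamples, and ≤20
simulate→refit repetitions — the full pipeline runs in seconds.

## Scope decisions

- No Hill/MWC two-state machinery, no ADP-bound states, and no modeling of
  the apparent cooperativity hinted at the lowest MgATP concentrations:
  the five-parameter scheme above is the entire model surface.
- No weighted or robust regression variants; unweighted least squares is the
  single fitting mode (replicate-level vs mean-level is the only choice).
- Plotting is deliberately out of the tested surface; all outputs are CSV
  tables with provenance comment headers (version, config hash, seed).
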