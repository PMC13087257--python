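# Methods

## Forward model of the dipolar signal

Two unpaired electron spins at distance `r` couple with the point-dipole
frequency `ν(r) = D / r³`, `D = 52.04 MHz nm³` for free-electron g-values;
exchange coupling is neglected, which is appropriate for nitroxide pairs
beyond ~1.5 nm and is why the distance axis never starts below 1 nm. For an
isotropic (powder) orientation distribution the background-free dipolar
signal of a distance distribution `P(r)` is

    F(t) = ∫ K(t, r) P(r) dr,
    K(t, r) = ∫₀¹ cos[2π ν(r) (1 − 3u²) t] du ,   u = cos θ.

`K` is evaluated by a Fresnel-integral closed form; an independent
Gauss–Legendre quadrature route (default 5001 nodes) is provided and the
two agree to better than 1e−6 over `t ∈ [0, 8] µs`, `r ∈ [1.5, 8] nm`. The
discretised kernel matrix folds trapezoidal quadrature weights in `r`, so a
distribution is always handled as a density per nm, never as bin masses.

The detected echo amplitude adds a modulation depth `λ` (the fraction of
detected spins whose partner is inverted by the pump pulse), an overall
scale `V0`, and an intermolecular background modelled as a stretched
exponential `B(t) = exp(−k t^(d/3))`:

    V(t) = V0 [(1 − λ) + λ F(t)] B(t).

`d = 3` (homogeneous three-dimensional excess spins) is the default;
membrane-confined samples can show `d < 3`, so `d` is exposed in the
configuration but held fixed during fitting — letting `d` float alongside
`k`, `λ` and a non-parametric `P` is badly conditioned at realistic noise.

## Global regularised inversion

One distribution is fitted jointly to all evolution windows of a sample:

    min_{P ≥ 0, θ}  Σᵢ ‖Vᵢ − modelᵢ(P, θᵢ)‖² / σᵢ²  +  α² ‖L P‖²

with per-trace nuisance parameters `θᵢ = (λᵢ, kᵢ, V0ᵢ)`, per-trace noise
levels `σᵢ` estimated from the high-frequency residual of a Savitzky–Golay
fit (floored at 1e−5 so clean synthetic data cannot produce infinite
weights), and `L` the second-difference operator with zero boundary
conditions — the distribution is treated as vanishing outside the axis,
which penalises edge mass and removes the degeneracy between a flat
far-distance contribution and the background parameters. A strongly
weighted row pinning the trapezoidal integral of `P` to 1 is appended to
the linear system; it removes the exact redundancy between the modulation
depths and the scale of `P` and conditions the optimisation. Residuals are
noise-normalised, so the objective is in units of noise variance.

The optimisation is separable. The inner problem at fixed nuisance is a
convex non-negative Tikhonov solve, handled by active-set NNLS (with a
BVLS fallback when the active set cycles on ill-conditioned systems); on
20-point problems it matches an independent bounded-variable least-squares
oracle to 1e−6. The outer problem alternates that solve with independent
bounded 3-parameter least-squares refinements of each trace's nuisance at
fixed `P` (block-coordinate descent; both blocks decrease the joint
objective, so the sweep objective is monotone). Because the joint landscape
has local optima in the modulation depths — approaching from below is safe,
from above is not — the first round is multi-started from the tail-fit
depth estimate and from half that value, keeping the lower-objective
solution. Refinement stops when the per-sweep relative decrease falls below
1e−7 (30-sweep cap; a run that is still decreasing faster than 1e−4 per
sweep at the cap is flagged as non-converged). Two rounds of α selection
and refinement are performed; reported per-trace depths are the effective
values after renormalising `P`.

### Regularisation-parameter selection

`α` is chosen on a log-spaced grid (default 33 points over 1e−4…1e4) by
generalised cross-validation,

    GCV(α) = m ‖residual‖² / (m − tr H(α))²,
    H(α) = A (AᵀA + α² LᵀL)⁻¹ Aᵀ,

with the residual taken from the non-negative solution and the trace from
the unconstrained smoother. The strong robust variant (the default)
multiplies GCV by `(γ + (1 − γ) tr(H²)/m)` with `γ = 0.8`, which penalises
under-smoothing. Grid points where the influence system is numerically
singular are excluded. Two tie-breaking rules, both toward stronger
smoothing, stabilise flat GCV valleys: near-ties within 2% of the minimum,
and an absolute floor of 1e−3 — criterion values that small mean the fit is
orders of magnitude below the noise floor, where distinctions between α
values are statistically meaningless and the non-negative solution can be
arbitrarily ragged. Note that because residuals are noise-normalised, the
selected α itself scales like 1/σ; the scale-free smoothing strength is
α·σ, which is the quantity that grows with the noise level.

### Reliability and robustness

Each trace's evolution window limits how far in distance its information
reaches; the usual colour-bar convention is implemented as
`r_X = c_X (t_max / 2 µs)^(1/3)` with defaults `c = (5, 6, 7) nm` for
shape / mean-and-width / mean reliability (configurable — the exact
constants of the original analysis tools are not published). A fit is
flagged "low modulation depth" when the effective depth is below 0.02 or
when less than half of the recovered mass lies inside the mean-and-width
reliability limit: mass beyond that limit has a nearly flat kernel over the
window and is observationally degenerate with the background and the
depth, so the apparent modulation is not interpretable. Leave-one-trace-out
jackknifing (≥ 3 traces) re-fits every subset and reports the maximum
pairwise L1 distance between the recovered distributions.

## Two-state quantification

The recovered `P(r)` is fitted with a mixture of two area-normalised
Gaussians by multi-start least squares (≥ 8 starts seeded from the two
largest well-separated local maxima of a lightly smoothed copy of `P`,
plus seeded jitter; strict component ordering via a non-negative
separation parameter). Because the components are normalised, the mixture
weight `p1` equals the first component's area, so the state populations
are read off directly: the shorter-distance component is assigned to the
non-swapped state, the longer to the swapped state, with a warning if a
mean deviates more than 0.7 nm from the 3.3 / 5.0 nm references.

Component widths are capped at 1 nm. The cap is interpreted on the
standard deviation — the width parameterisation of the Gaussian distance
models in current DEER fitting software — with the older FWHM convention
selectable. The choice is consequential: read as FWHM, a 1 nm cap clips
any component broader than SD 0.42 nm (the ~3.3 nm state, predicted at
SD 0.5 nm, is broader than that) and inflates the opposite population by
2–3 percentage points on exact input.

An optional cross-check mode fits the two-Gaussian model directly to the
time-domain traces (mixture parameters optimised jointly with the per-trace
nuisance parameters, seeded from the standard route); it is free of
regularisation bias and agrees with the distribution-domain route to within
a few tenths of a percentage point on the packaged fixtures.

Uncertainty is reported at two levels: the 2σ (95%) interval of `p1` from
the fit covariance, and a combined uncertainty `max(ci95, p1/10, axis
spread)` where the axis spread is the max−min of the swapped population
across processing with 8, 9 and 10 nm distance axes. The pure covariance
interval is systematically optimistic — in the packaged round-trip studies
it covers the ground truth in only a minority of replicates, while the
combined uncertainty covers it in essentially all — which is precisely why
the processing-spread heuristic exists.

## Synthetic data: what it emulates and what it does not

The generators produce: Gaussian-mixture ground truths on a distance axis;
seeded multi-window trace sets through the full forward model with white
Gaussian noise on the real channel; idealised poly-alanine helix dimers
(φ = −57°, ψ = −47°, backbone + Cβ) for labelling tests; and AR(1) energy
series with prescribed mean, marginal SD and lag-1 autocorrelation
`exp(−1/τ)`. The packaged fixtures `exp19C` / `exp40C` fix the component
means and SDs at the in-silico predictions for the two cap states
(3.3 / 0.5 nm and 5.0 / 0.3 nm) and set the weights to the fitted state
populations at the two temperatures (0.43/0.57 and 0.34/0.66). Default
trace conditions: four windows of 2 / 4 / 6 / 7.5 µs at dt = 16 ns,
modulation depth 0.3, background `k = 0.05, d = 3`, and noise SD 0.005·V0 —
the depth and noise level are conventions chosen to match visually strong
oscillations, as the experimental values are not published, and are
exposed in the fixture configuration.

Passing round trips on these fixtures demonstrate that the inversion and
quantification are unbiased and correctly calibrated *under the stated
model*: white noise, exactly stretched-exponential background, orientation-
isotropic kernel. Real spectrometer data additionally contain nuclear
modulation, phase noise and "2+1" end artefacts (the last handled by the
end-truncation utility); performance on such data is bounded below by
these results, not established by them.

## Rotamer-based distance prediction

The R1 (MTSSL) side chain is grafted from an internal-coordinate template:
bond lengths/angles of the Cβ–S–S–C–ring chain with the nitroxide ring held
rigid, five rotatable dihedrals χ1–χ5 sampled uniformly, label point at the
N–O bond midpoint. A candidate is accepted when at most `max_clashes`
protein heavy atoms (hydrogens ignored; the labelled residue itself
excluded, since its contacts with the grafted chain are bonded geometry)
lie closer than the clash cutoff: "loose" = 2.5 Å / ≤ 5 contacts,
"tight" = 3.4 Å / 0 contacts; "thorough" searches 30 000 candidates,
"quick" 3 000; the ensemble caps at 200 accepted rotamers. Sites are
validated for backbone completeness (Cβ synthesised for glycine) and
disulfide-bonded cysteines (SG–SG < 2.5 Å) are rejected as not labellable.
Pair predictions histogram all |A|×|B| midpoint distances (default bin
0.05 nm). The template geometry is idealised (ring closure is approximate),
which is adequate for the ~0.1 nm scale of accessible-volume predictions
but not for rotamer energetics, which are out of scope.

## Energy post-processing

The association free energy relative to the ideal-gas (non-interacting)
reference is the exponential average `ΔG = −kT ln⟨exp(−U/kT)⟩`
(`k_B = 0.0019872041 kcal mol⁻¹ K⁻¹`), evaluated with a log-sum-exp shift
so arbitrarily large |U| cannot overflow. Because interaction energies
drift on long time scales, the estimator is applied per contiguous block —
five equal blocks of the last half of the series by default — and the
block mean ± block SD is reported; applying the estimator per block (rather
than averaging U per block first) is the implemented reading of the
block-averaging scheme, chosen because it keeps each block a valid
free-energy estimate. Temperature differences subtract estimates of
identical system composition with errors added in quadrature. pV work uses
1 bar·nm³ = 0.0602214076 kJ/mol. The radial-distribution utility bins the
minimum distance from each point to a reference set and normalises by the
bulk density times the annular area (2D) or shell volume (3D); it warns
when `r_max` exceeds half the box extent.

## Numerical choices and limitations

- Time is µs and distance nm everywhere inside the package; ns inputs are
  detected by magnitude on read. Default axis 1.5 nm → `r_max` (8–10 nm
  supported) at 0.05 nm steps.
- All generators and fits are pure functions of their inputs and seeds;
  pipeline reports are byte-identical on re-run with the same config.
- Round-trip studies use 20 seeded replicates per condition, four traces
  each; a full study takes a few minutes on one CPU.
- The imaginary channel of complex traces is phase-rotated to minimal RMS
  and discarded.
- Known limitations: no orientation selection, no multi-spin (> 2)
  combination frequencies, no Bayesian/neural inversion, no rotamer
  energetics, no parsing of MD trajectories (scalar series only). The
  bare covariance CI on populations is optimistic; use the combined
  uncertainty.
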