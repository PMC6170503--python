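# Methods

## Models

`phostime` analyses the initiation of receptor-tyrosine-kinase
signalling by a bivalent ligand (VEGF-A binding VEGFR2 on a patch of an
endothelial cell surface, by default) as a continuous-time Markov chain
(CTMC) over molecule counts. A free bivalent ligand binds a free
receptor monomer to form a bound monomer `M`; the ligand's second site
recruits another free receptor, cross-linking the pair into a bound
dimer. Two variants differ in how phosphorylation is treated:

* **IP (instantaneous phosphorylation)** — a dimer is phosphorylated
  (`P`) the moment it forms. States are `(n1, n2)` = (`M`, `P`) counts.
* **DP (delayed phosphorylation)** — cross-linking first gives a
  non-phosphorylated dimer `D`, which phosphorylates at rate `gamma+`
  and de-phosphorylates at `gamma-`; phosphorylated dimers must
  de-phosphorylate before dissociating. States are `(n1, n2, n3)` =
  (`M`, `D`, `P`).

Both chains are closed: free receptors and ligands are implicit via
`R = n_R - M - 2*(D+P)` and `L = n_L - M - D - P`. Mass-action rates
carry a factor of 2 wherever either of the ligand's two equivalent
sites can react (monomer formation, dimer dissociation). The three
admissibility regimes (`2 n_L <= n_R`, intermediate, `n_R <= n_L`) are
all enumerable; the matrix analytics are exercised mainly in the
ligand-limited regime `2 n_L <= n_R`, which is where the physiological
copy numbers fall.

Grouping states by the phosphorylated-dimer count (`n2` for IP, `n3`
for DP) — the QBD *level* — makes the generator block-tridiagonal: no
single reaction changes the level by more than one. The level choice
is deliberate: the signalling threshold "at least `N` phosphorylated
dimers" then removes whole levels at once.

## Descriptors

**Threshold-hitting time.** `T_n(N)`, the first time the chain started
at `n` holds `N` phosphorylated dimers, is the absorption time of the
auxiliary chain restricted to levels `< N`. Raw moments solve the
nested linear systems `(-Qt) m^(1) = 1`, `(-Qt) m^(k) = k m^(k-1)`;
the Laplace–Stieltjes transform solves `(s I - Qt) phi(s) = a` with `a`
the absorption-rate vector. Moments are obtained from repeated linear
solves rather than transform differentiation — numerically the stabler
route. Each system is solved two independent ways: a block-Thomas
sweep over levels (forward elimination ascending, back-substitution
descending; no cross-level pivoting, safe because the negated
sub-generator Schur complements are M-matrices) and a generic sparse
LU. The suite checks agreement to 1e-8 relative; observed agreement is
~1e-15.

**Stationary distribution.** The base chains are irreducible on their
finite state space, so `pi` is the unique normalized left null vector
of `Q`. The QBD route censors the *lowest* level first (linear level
reduction): `T_0 = A_0`, `T_l = A_l + D_l (-T_{l-1})^{-1} U_{l-1}`, top
level solved for its null vector, lower levels recovered downward.
The direction matters: at picomolar ligand the stationary mass sits
almost entirely in the top levels, so a top-down sweep manipulates
censored sojourn times of order 1e17 s and loses all precision, while
the bottom-up sweep keeps every intermediate bounded. The sparse
cross-check replaces one (redundant) balance equation with the
normalization row; the two routes agree to ~1e-14 in total variation.

**Elasticities.** Sensitivity of a descriptor `y` to a rate `theta` is
reported as the elasticity `(theta/y) dy/dtheta`. The generator is
linear in each rate, `Q = sum_theta theta B_theta` with integer pattern
matrices `B_theta`, so derivatives satisfy exact linear systems:
`(-Qt) dm = Bt m` for the mean hitting time, and
`{dpi Q = -pi B_theta, sum dpi = 0}` for the stationary mean. Both are
implemented as direct solves (reusing the LU factor of the unperturbed
system); a central finite-difference oracle (relative step 1e-4) backs
them in the tests at 1e-3 relative agreement. Because the stationary
mean depends on the rates only through the ratios `alpha+/alpha-`,
`beta+/beta-`, `gamma+/gamma-`, paired elasticities are antisymmetric;
the direct solves reproduce this cancellation below 1e-6 without it
being imposed.

The tabulated threshold for the elasticity summaries is
`N = round(0.25 * n_L)` with round-half-up (23 → 6, 58 → 15, 116 → 29).
The headline monomer-association elasticities (~ -1) are insensitive to
this rounding convention; third-digit changes in the smaller entries
are possible under a different convention, which is why the policy is a
configurable parameter.

## Rate estimation

The six CTMC rates come from measured constants through the standard
two-step (diffusion transport + intrinsic reaction) trap model; all
lengths in mm, times in s, amounts in mol. On a patch of area
`f * s_c` (radius `r = sqrt(f s_c / pi)`):

* ligand transport `k_dL = 4 pi D_L r`; the observed per-receptor pair
  `q_on = k_on/N_A` (with `k_on = k_off/K_d`) and `q_off = k_off`
  decompose as `1/q_on = 1/k+3D + n_R/k_dL` and
  `q_off = k- k_dL / (k_dL + n_R k+3D)`, yielding the intrinsic rates
  `k+3D` and `k-`;
* the membrane analogue `k+2D = k+3D / delta` composes with receptor
  transport `k_dR = 2 pi (D_R + D_M) / log(w/b)` into the cross-linking
  pair `k_c = k_dR k+2D/(k_dR + k+2D)`, `k_u = k- k_dR/(k_dR + k+2D)`.
  `w` is taken as the radius of the per-receptor area disc,
  `sqrt(f s_c / (pi n_R))` — the reading of "one-half the mean distance
  between receptors" under a uniform receptor distribution;
* per-event rates: `alpha+ = q_on/(f s_c h)`, `alpha- = q_off`,
  `beta+ = k_c/(f s_c)`, `beta- = k_u`.

With the default parameter set (HUVEC surface 1e-3 mm^2, f = 0.04,
5800 receptors per cell hence `n_R = 232`, `K_d = 150 pM`,
`k_off = 1.32e-3 /s`) this gives `alpha+ = 3.653e-7`,
`alpha- = 1.320e-3`, `beta+ = 4.483e-4`, `beta- = 1.620e-4` (all 1/s).
The phosphorylation defaults are stored as `0.22/min` and `0.055/min`
(`gamma+ = 3.667e-3`, `gamma- = 9.167e-4` 1/s), which reconciles the
slightly different roundings in circulation for these constants.
Derivation failure modes are explicit errors: a transport-limited
parameter set (`1/q_on <= n_R/k_dL`) and receptor overcrowding
(`w <= b`) both raise rather than returning unphysical rates.

Ligand counts follow `n_L = round(c_L N_A f s_c h)`; the canonical
study pairs 1 pM → 23, 2.5 pM → 58, 5 pM → 116 (10/25/50 % of `n_R`,
not the rounded formula values — 1 pM rounds to 24) are built in as a
lookup that takes precedence at the default parameters.

## Single-molecule fate

For one bound monomer in isolation (partner pool `n_R - 1`, other
ligands ignored), the signalling-vs-loss race is a 1- or 2-state
absorbing chain. With `b = beta+ (n_R - 1)`, `a = alpha- + k_int`,
`A = b + a` and `G = 2 beta- + gamma+ + k_int`:

* IP: `p_signal = b/A`, `tau_signal = 1/A`;
* DP: `p_signal = b gamma+ / (A G - 2 b beta-)`,
  `tau_signal = (A + G) / (A G - 2 b beta-)`.

`tau_signal` is the mean absorption time *conditioned on signalling*
(Doob h-transform; the conditioned chain keeps the original holding
rates, so `tau = [(-Q)^{-1} p]_M / p_M`). The closed forms are checked
against a generic conditioned-absorption oracle to 1e-10 across random
rate draws. The non-phosphorylated dimer internalizes at the plain
`k_int`: the faster-internalization multiplier `q` applies to
phosphorylated dimers, and the race ends at the phosphorylation event.

## Stochastic simulation

The direct-method SSA covers the base models and their open extension
with receptor synthesis (constant rate `k_syn`; basal balance requires
`k_syn = n_R k_int`) and internalization (`k_int` for free receptors,
monomers and non-phosphorylated dimers; `q k_int` for phosphorylated
dimers). An internalized complex removes its ligand from the surface
pool permanently by default; a `recycle_ligand` switch returns it
instead (endosomal compartments themselves are out of scope, matching
the surface-only focus of the models). Because synthesis opens the
system, the extended variants have no finite conservation-bounded state
space and are analysed by simulation only. Ensembles use one master
`SeedSequence` with per-replicate spawned substreams, so results are
reproducible for a fixed seed and replicates are independent; grid
summaries use piecewise-constant interpolation of each trajectory.

## What the defaults emulate, and what they do not

The default configuration reproduces the published VEGF-A/VEGFR2 study
conditions: a well-mixed 4 % patch of a HUVEC surface with 232
receptors, picomolar-to-nanomolar ligand, no receptor pre-dimerization,
no spatial structure, no receptor clustering, no convective transport,
and no endosomal recycling. Passing tests therefore certify the
mathematics of these idealized chains, not biology the chains omit:
real membranes cluster receptors upon stimulation, ligand depletion in
a dish differs from the fixed-`n_L` closed system, and phosphorylation
is in reality multi-site and sequential.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study-scale instances
(IP: 300 states; DP: 2600 states at 1 pM; IP up to 6903 states at
5 pM). DP at 5 pM (~274k states) is supported by the same code paths
but not exercised in the default suite. Simulation cross-checks use
toy instances (`n_L <= 10`) with a uniform x200-x2000 time rescaling —
a pure change of time unit that leaves hitting-time distributions (up
to scale) and the stationary law untouched while keeping runs at desk
scale; agreement is asserted at 3 Monte-Carlo standard errors with
2000 replicates for hitting times and 40 long replicates for late-time
occupancy. The late-time window corresponds to ~4–9 days of physical
time because the final ligand-binding events at low copy number are
extremely slow.

Tolerances: generator row sums are required to vanish within
1e-12 of the diagonal scale; dual-route solver agreement at 1e-8;
stationary residual `||pi Q||_inf` at 1e-10 — all far below the
precision of any quantity reported.

## Known limitations

* The single-molecule module reproduces the published fate table's four
  probabilities (and the zero-internalization IP time) to print
  precision, but three published conditioned times differ from the
  exact Doob-conditioned values by 0.008 %, 0.10 % and 0.70 %. No
  parameterization of the stated fate chains reproduces those three
  prints together with the probabilities (the IP times alone pin the
  internalization rate to ~2.88e-4/s, inconsistent with the stated
  2.8e-4/s); the package reports the exact conditioned values.
* Elasticities are local (first-order); no variance-based global
  sensitivity analysis is provided.
* The LST is evaluated pointwise; no numerical inversion to the full
  hitting-time distribution is provided (means and SDs cover the
  reported use).
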