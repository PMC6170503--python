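# phostime

Exact stochastic analysis of the time it takes receptor–ligand systems
to start signalling.

Receptor tyrosine kinases such as VEGFR2 signal when a bivalent ligand
(VEGF-A) cross-links two receptor monomers into a dimer whose
intracellular tails trans-autophosphorylate. At picomolar ligand and a
few hundred receptors per membrane patch, copy numbers are small enough
that deterministic rate equations mislead; `phostime` instead treats
the counts of bound monomers `M`, non-phosphorylated dimers `D` and
phosphorylated dimers `P` as a continuous-time Markov chain with
quasi-birth-and-death (QBD) structure and answers, *exactly*:

* **How long until the cell signals?** The first-passage time
  `T_n(N) = inf{t : P(t) = N}` to a threshold of `N` phosphorylated
  dimers, via moments of the absorption time of an auxiliary chain:
  `(-Qt) m^(1) = 1`, `(-Qt) m^(k) = k m^(k-1)`, solved by
  block-tridiagonal level elimination (LST evaluations included).
* **Where does the system settle?** The stationary distribution
  `pi Q = 0` by QBD level censoring, with dimer marginals and mean
  occupancies.
* **Which rate matters?** Elasticities
  `(theta/y) dy/dtheta` of both descriptors with respect to each
  kinetic rate, from exact derivative linear systems (the generator is
  linear in every rate).
* **Where do the rates come from?** A two-step diffusion-limited
  derivation maps measured biophysics (surface area, diffusivities,
  `K_d`, `k_off`, membrane thickness) to the six per-event rates
  `alpha±, beta±, gamma±`.
* **What is one molecule's fate?** Closed forms for the probability
  that a single bound monomer signals before dissociating or
  internalizing, and the conditioned mean time to do so.
* **What if the membrane is open?** Gillespie simulation of the base
  models and of extensions with receptor synthesis and internalization.

Two model variants are supported everywhere: **IP** (dimers
phosphorylate instantly on formation) and **DP** (phosphorylation and
de-phosphorylation are explicit reactions). See `docs/methods.md` for
the full model description and numerical choices.

## Worked example

```python
from phostime import (PhysiologicalParameters, ModelSpec, FirstPassageQuery,
                      derive_rates, build_generator, fpt_moments,
                      stationary_distribution, signal_fate)

phys = PhysiologicalParameters()          # HUVEC defaults, f = 4 % patch
deriv, rates = derive_rates(phys)
print(f"n_R = {phys.n_R}, alpha+ = {rates.alpha_plus:.4g} /s, "
      f"beta+ = {rates.beta_plus:.4g} /s")

spec = ModelSpec(kind="DP", n_R=phys.n_R, n_L=23)     # 1 pM VEGF-A
gen = build_generator(spec, rates)
res = fpt_moments(FirstPassageQuery(spec=spec, rates=rates, threshold=5),
                  gen=gen)
t = res.at((0, 0, 0))
print(f"T(empty -> 5 phosphorylated dimers): "
      f"{t['mean_s']/60:.1f} +/- {t['sd_s']/60:.1f} min")

pi = stationary_distribution(gen)
print(f"stationary means: {pi.means()}")

fate = signal_fate(rates, n_R=phys.n_R, model_kind="DP", k_int=0.0)
print(f"single-monomer p_signal = {fate.p_signal:.4f}, "
      f"tau = {fate.tau_signal:.1f} s")
```

prints

```
n_R = 232, alpha+ = 3.653e-07 /s, beta+ = 0.0004483 /s
T(empty -> 5 phosphorylated dimers): 31.1 +/- 11.6 min
stationary means: {'M': 0.01760082136496659, 'D': 4.562711580019509, 'P': 18.250846320078043}
single-monomer p_signal = 0.9863, tau = 282.8 s
```

Reading: starting from 232 free receptors and 23 free ligands, the
delayed-phosphorylation chain needs about 31 minutes (mean, +/- one SD)
to accumulate five phosphorylated dimers; at steady state essentially
every ligand sits in a dimer (about 18 phosphorylated, 4.6 not yet
phosphorylated, P:D tracking `gamma+/gamma-` = 4); and a single bound
monomer, left alone, phosphorylates before dissociating with
probability 0.986.

The same analyses are available from the shell:

```sh
phostime rates                                  # derived kinetic rates
phostime fpt --model dp --n-ligands 23 -N 5 --minutes --empty-only
phostime steady --model ip --concentration-pm 1
phostime elasticity --model ip
phostime fate --model dp --k-int 0 --k-int 2.8e-4
phostime simulate --model dp --n-ligands 23 --t-max-min 60 --out tc.csv
phostime report --out-dir report/               # all headline tables
```

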