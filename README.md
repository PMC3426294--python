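# epichaos

Stochastic-Galerkin Legendre polynomial chaos for compartmental epidemic
ODE models with uniform random parameters.

## The problem

Transmission parameters of epidemiological ODE models are rarely known
exactly; often all the data support is a point estimate. `epichaos` treats
such parameters as independent uniform random variables and propagates the
resulting uncertainty *spectrally* instead of by brute-force sampling.
Every random parameter and every state is expanded in a truncated
tensor-Legendre chaos over a germ vector ξ = (ξ₁,…,ξₙ) of independent
Uniform[−1,1] variables,

    X(t; ω) = Σ_{i=0}^{P−1} x_i(t) Ψ_i(ξ(ω)),     P = (n+p)!/(n!p!),

where the Ψ_i are products of univariate Legendre polynomials with total
degree ≤ p. Projecting the governing equations onto each Ψ_L (the intrusive
Galerkin step) turns one random ODE system into one coupled deterministic
system for the coefficients x_i(t), solved once with an adaptive explicit
Runge–Kutta 4(5) scheme. Orthogonality then gives the statistics for free:

* mean:      E[X(t)] = x₀(t)
* variance:  Var X(t) = Σ_{i≥1} x_i(t)² ⟨Ψ_i, Ψ_i⟩
* first-order Sobol index of the parameter on germ d:
  S_d(t) = Σ_{i : Ψ_i depends only on ξ_d} x_i(t)² ⟨Ψ_i, Ψ_i⟩ / Var X(t)

A batched Monte Carlo propagator (`epichaos.mc_oracle`) provides the
independent cross-check: moments by streaming accumulation over vectorized
ensemble ODE solves, Sobol indices by the pick-and-freeze two-matrix
estimator with bootstrap errors.

The right-hand sides may contain constant sources, linear transits and
bilinear contact terms — the structure of classical compartmental models.
The bundled worked example is a three-compartment obesity model (normal
weight N, overweight S, obese O by body-mass index, proportions, time in
weeks) with four Uniform(0, 2θ̂) transmission parameters, reduced to the
(S, O) pair through the conservation law N + S + O = 1.

## Worked example

```python
import epichaos as ec

basis = ec.generate_multi_indices(4, 2)          # 15 basis functions
tensors = ec.build_inner_product_tensors(basis)
params = ec.obesity_parameter_set(random=True).bind_chaos(basis)
model = ec.build_obesity_model("reduced", params)

system = ec.assemble_galerkin(model, params, basis, tensors)   # 30 unknowns
solution = ec.integrate_chaos(system, 800.0, [520.0, 780.0])

moments = ec.compute_moments(solution, basis)
mean, var = moments.at_time("O", 520.0)
print(f"obese at t=520: {mean:.2%} +/- {var**0.5:.2%}")

sobol = ec.compute_sobol(solution, basis, params)
print({n: round(float(sobol.series('O', n)[0]), 3)
       for n in ("beta", "gamma", "epsilon", "rho")})
```

prints

```
obese at t=520: 15.08% +/- 2.80%
{'beta': 0.019, 'gamma': 0.974, 'epsilon': 0.0, 'rho': 0.0}
```

— the obese prevalence ten years in is 15.08 % with a one-standard-
deviation band of ±2.80 percentage points, and about 97 % of that variance
is driven by the overweight→obese transit rate γ alone: prevention aimed at
the overweight population is the leverage point.

The same pipeline is available from the shell:

```bash
epichaos run $(python -c "import epichaos.cli as c; print(c.bundled_config_path())") -o out
epichaos report out/chaos_moments.csv
```

which writes tidy CSVs (`time, state, quantity, method, value`) plus a run
manifest, and renders year-by-year prevalence tables with mean and
one-standard-deviation interval per state.

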