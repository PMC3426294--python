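# Methods

## Model class

`epichaos` handles compartmental ODE systems whose right-hand sides are
polynomial of degree ≤ 2 in the states: constant sources, linear transits
and bilinear contact terms. Each term is a signed product
`coefficient × state-monomial`, where the coefficient is a literal constant
times a product of named parameters (e.g. μ·N⁰). Composite coefficients
keep their parameter references rather than being pre-multiplied, so any
factor can later be declared random without restructuring the model. A
coefficient may contain at most one *random* parameter: products of
independent random parameters would need joint chaos terms that the
truncation cannot carry, and no classical compartmental model requires
them.

The bundled obesity model tracks adults (24–65) by body-mass index class —
normal weight N, overweight S, obese O, as population proportions with time
in weeks:

    N′ = μN⁰ − μN − βN(S+O) + ρS
    S′ = μS⁰ + βN(S+O) − (μ+γ+ρ)S + εO
    O′ = μO⁰ + γS − (μ+ε)O

β is the social-pressure transmission rate, γ the overweight→obese rate,
ε the obese→overweight recovery rate, ρ the overweight→normal-weight rate,
μ the demographic turnover of the age band, and N⁰, S⁰, O⁰ the inflow
proportions from the 23-year-old cohort (they sum to 1, so N+S+O = 1 is
conserved). Point estimates (per week): β = 0.00085, μ = 0.000469,
γ = 0.0003, ε = 0.000004, ρ = 0.000035, N⁰ = 0.704, S⁰ = 0.25, O⁰ = 0.046;
initial proportions 0.522/0.362/0.116. The default *reduced* variant
substitutes N = 1 − S − O into the S equation (expanding
β(1−S−O)(S+O) into linear and bilinear terms) and integrates only (S, O),
recording N as a closure state; the full 3-state form is also assemblable
and is tested to agree with the reduced one.

## Random parameters

Each uncertain parameter is uniform on [a, b] and owns one germ dimension
(mutual independence). Its Legendre chaos expansion is exact at degree 1:
constant coefficient (a+b)/2, linear coefficient (b−a)/2 on its germ,
everything else — including the degree-2 slot — exactly 0. The degree-2
slot is stored anyway so variance gathers over "all basis functions of one
germ" stay well-defined. When only a point estimate θ̂ is available, the
convenience constructor uses the noninformative Uniform(0, 2θ̂), whose mean
is θ̂. Deterministic parameters are zero-width uniforms without a germ, so
the chaos dimension equals the number of genuinely random parameters (4 in
the obesity example). Correlated or non-uniform parameters are out of
scope.

## Chaos basis and inner products

The basis is the total-degree truncation: all products of univariate
(unnormalized) Legendre polynomials with total degree ≤ p over n germs,
(n+p)!/(n!p!) functions. Canonical ordering: grouped by total degree;
within a group, functions of fewer germ dimensions first, ties broken by
germ order. For p = 2 this is: constant; linear terms ξ₁…ξₙ; pure
quadratics P₂(ξ₁)…P₂(ξₙ); cross products ξᵢξⱼ (i<j, lexicographic) — so
with four germs, coefficient 5 is the first germ's quadratic mode. Norms
are carried separately (⟨Ψᵢ,Ψᵢ⟩ = ∏ 1/(2l+1)), not absorbed into the basis.

Inner products factorize over dimensions under the uniform product density,
so the 2-/3-/4-way tensors are assembled from univariate moment tables
E[P_a P_b], E[P_a P_b P_c], E[P_a P_b P_c P_d] computed by Gauss–Legendre
quadrature with ⌈(4p+1)/2⌉+1 nodes (exact for the 4-way products with
margin; the suite verifies the tables against exact symbolic integration to
1e−12). Table entries are canonicalized over sorted indices so permutation
symmetry holds exactly, entries below 1e−14 are zeroed, and the 4-way
tensor is stored dense (15⁴ doubles at the default size is negligible;
memory for dense storage is the practical ceiling on p).

## Galerkin assembly and integration

Projection onto each test function Ψ_L yields, per modeled state, one ODE
per basis function. At assembly time the parameter chaos vector of every
term is contracted into the 3-way (linear terms) or 4-way (bilinear terms)
tensor once, leaving a per-step cost that is a matrix–vector or small
bilinear form in the state coefficients; constant sources project to their
own coefficient vector. Initial conditions are treated as deterministic:
mode 0 carries the initial value, all higher modes start at zero.

Integration uses `scipy.integrate.solve_ivp` RK45 with rtol 1e−8 and
atol 1e−10 — tight enough that reported prevalences are
integrator-independent at two printed decimals. Degenerate (all-widths-
zero) inputs reduce the system to the deterministic model exactly; the
suite asserts mode-0 agreement to 1e−8 and dormant higher modes below
1e−10. For closure models the derived coefficients satisfy
N₀+S₀+O₀ = 1 and Nᵢ+Sᵢ+Oᵢ = 0 to 1e−12 at all times.

Truncation order defaults to p = 2: the obesity system is weakly nonlinear
and order-2 and order-3 means at t = 520 agree to well under 0.1 percentage
points (asserted in the suite), while order 1 already matches to a similar
level for this model.

## Moments, bands, Sobol indices

Mean and variance come from orthogonality (variance is the norm-weighted
sum of squared higher modes; negative values beyond −1e−14 from
cancellation would warn before clamping to zero). The reported uncertainty
bands are mean ± one standard deviation of the output process — *not*
calibrated Gaussian confidence intervals; no quantile multiplier is
applied.

First-order Sobol indices gather the squared coefficients of basis
functions depending on a single germ dimension (at p = 2: the linear and
pure-quadratic modes of that germ, with weights Var P₁ = 1/3 and
Var P₂ = 1/5) and divide by the total variance. The pooled multi-germ
contribution is exposed as an extra "interactions" series so the
decomposition visibly sums to one (to 1e−10 wherever variance is positive);
where total variance is zero (t = 0) indices are reported as NaN.

## Monte Carlo oracle

`mc_propagate` draws parameter tables, integrates the deterministic model
for the whole ensemble at once (the polynomial RHS evaluates elementwise
over sample arrays, so one adaptive solve advances every draw), and
combines batch moments with the pairwise (Chan et al.) update — a
single-pass, flat-memory accumulation. Ensemble tolerances are rtol 1e−6 /
atol 1e−9; sampling error dominates far above that. `mc_sobol` implements
the pick-and-freeze first-order estimator
S_i = mean(f(B)·(f(AB_i) − f(A)))/Var(f) with the variance taken over the
pooled A and B evaluations and bootstrap (default 200 resamples) standard
errors; the A/B/bootstrap streams take three child seeds derived from the
user seed. Default oracle sizes are 50 000 draws for moments and 20 000 for
Sobol indices, which keep the cross-checks at a few seconds while leaving
Monte Carlo standard errors well above spectral truncation error.

## What the fixtures do and do not show

The obesity configuration is a real historical calibration (regional
health-survey point estimates), and the uniform distributions encode
point-estimate uncertainty only. Passing tests demonstrate that the
spectral propagation is internally correct (exact tensor identities,
deterministic limits, closure conservation) and agrees with brute-force
Monte Carlo on this weakly nonlinear system; they do not validate the
epidemiological model itself, the uniform distribution choice, or behavior
under strong nonlinearity, where order-2 truncation can bias both mean and
variance and higher p (with dense-tensor memory growth) would be needed.

## Numerical and design choices

- Time unit is weeks; the calendar labeling of the obesity reports
  (year = 2000 + t/52, so 2010/2011/2015 ↔ t = 520/572/780) is applied only
  when rendering tables. Report percentages round half-even to two
  decimals.
- Output CSVs are tidy (`time, state, quantity, method, value`) for
  downstream plotting; the CLI pipeline is deterministic, so reruns are
  byte-identical.
- Configuration is one YAML file; validation errors name the dotted field
  path. Partial outputs are removed if a run fails.
- Test and cross-check problem sizes (20-week output stride, 50k/20k
  oracle draws) were chosen so the full suite completes in well under a
  minute at desk scale while keeping every assertion statistically sharp.
- Implicit/stiff integrators, non-intrusive collocation, adaptive/sparse
  truncations and non-uniform input families are deliberately out of
  scope.
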