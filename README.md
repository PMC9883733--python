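# hieropt

Hierarchical maximum-likelihood parameter estimation for ODE models that are
observed through **relative measurements**.

## The problem

Mechanistic ODE models in systems biology are calibrated against data that
are usually not absolute concentrations: plate-reader viabilities normalized
to a control, reverse-phase protein arrays median-centered per antibody, and
so on.  Each datapoint is then related to the model output by

    ybar_i = s_i * h_i(theta) + b_i + eps_i,     eps_i ~ N(0, sigma_i^2)

where `h_i` is the (possibly log-transformed) unscaled model observable,
`theta` the *dynamic* parameters (rate constants, initial concentrations),
and `s`, `b`, `sigma` are *static* observation parameters — scalings,
offsets and noise standard deviations — shared across groups of datapoints.
Estimating the statics jointly with `theta` inflates the optimization
problem and conditions it badly: the objective is typically far more
sensitive to the scalings than to the dynamics.

## The method

All parameters are estimated by minimizing the Gaussian negative
log-likelihood

    J(theta, s, b, sigma) = 1/2 * sum_i [ log(2 pi sigma_i^2)
                                          + (ybar_i - (s_i h_i + b_i))^2 / sigma_i^2 ].

hieropt splits this into an **outer** problem over `theta` and an **inner**
problem over the statics, which — under checkable sharing assumptions on the
datapoint groups — has closed-form solutions per group:

    s_alpha   = ( sum h_i^2 / sigma_i^2 )^-1 * sum (ybar_i - b_i) h_i / sigma_i^2
    b_beta    = ( sum 1 / sigma_i^2 )^-1     * sum (ybar_i - s_i h_i) / sigma_i^2
    sigma_g^2 = mean_i (ybar_i - (s_i h_i + b_i))^2

(scaling and offset shared by the same datapoints are solved jointly as a
weighted least-squares line fit; a perfect fit is caught by a lower bound on
sigma).  Because the inner solution is exactly stationary, the gradient of
the reduced objective `Jhat(theta) = J(theta, s(theta), b(theta),
sigma(theta))` equals the partial `theta`-gradient at fixed optimal statics
(envelope property).  That gradient is computed either by forward
sensitivity analysis or — crucially for large models — by an **adjoint**
backward pass whose state dimension is the number of model states,
independent of the number of parameters.  A multi-start harness runs
gradient-based local optimization in this hierarchical mode and in the
standard joint mode for comparison.

## Worked example

```python
import hieropt as hp

bench = hp.make_benchmark("exp_decay")          # xdot = -k x, y = s*x + noise
truth = hp.generate_data(bench.problem, bench.theta_true,
                         bench.statics_true, seed=1)

starts = hp.sample_startpoints(truth.problem, n_starts=5, global_seed=0)
result = hp.optimize(truth.problem, "hierarchical", starts,
                     hp.OptimizerConfig(max_iter=100))
print(result.best.final_parameters)
```

Running `python examples/01_fit_relative_data.py` prints

```
true decay rate      k = 0.8
recovered            k = 0.8113
true scaling         s = 2.0
inner-solver scaling s = 2.0874
final objective      J = 7.3709 (5/5 starts converged)
```

the recovered decay rate and scaling sit near the generating values (the
residual discrepancy is the finite-sample noise), and `J` is the negative
log-likelihood at the optimum.  `examples/04_standard_vs_hierarchical.py`
runs the paired mode comparison on a three-state signaling cascade (8
dynamic parameters, 3 scalings, 2 offsets, 2 noise parameters):

```
median standard         4.132
median hierarchical   -52.292
```

the hierarchical runs reach much better likelihoods within the same
iteration budget because the optimizer never sees the 7 static coordinates.
The other examples demonstrate the closed-form inner solutions, the
agreement of forward/adjoint/finite-difference gradients, and the
information lost by fitting relative instead of absolute data.

## Command line

```
hieropt benchmark cascade3 --seed 0 --out problem_dir   # write a synthetic problem
hieropt validate problem_dir                            # group-structure report
hieropt fit problem_dir --mode hierarchical --n-starts 20 --seed 1 --out fit_dir
hieropt compare problem_dir --n-starts 10 --seed 1 --out report.json
```

A problem directory holds a YAML model file and TSV tables for
measurements, static-parameter groups and experimental conditions (see
`docs/methods.md`).

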