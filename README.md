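# hydrovigor

Hydrotime-model analysis of seed vigor from germination time courses across
water potentials.

## The problem

Seed lots of the same cultivar can share near-identical germination
percentages under ideal laboratory conditions yet establish very differently
in the field, because lots differ in *vigor* — the sum of seed properties
governing performance under stress. A germination assay run across a range
of water potentials (imposed osmotically with PEG-6000) exposes those
differences, and the hydrotime model turns the resulting time courses into
three biologically interpretable parameters per lot:

- **θ_H** — the hydrotime constant (MPa·h): the amount of
  (water potential excess) × time a seed must accumulate to germinate;
- **Ψ_b(50)** — the median base water potential (MPa): the threshold below
  which the median seed cannot germinate;
- **σ_φb** — the standard deviation of the base water potential across
  seeds (MPa): germination uniformity.

The model says fraction *g* germinates at time *t_g* satisfying
θ_H = (Ψ − Ψ_b(g))·t_g, with Ψ_b normally distributed over seeds, so the
cumulative germinated fraction is

```
g(t; Ψ) = Φ( (Ψ − θ_H/t − Ψ_b(50)) / σ_φb )
```

Estimation is by *repeated probit analysis*: for a trial θ_H every usable
observation becomes a point (x, probit g) with x = Ψ − θ_H/t, which the model
makes collinear; θ_H is profiled to maximize the r² of that line (coarse
log-spaced grid, then golden-section refinement), and the winning line's
slope and intercept give σ_φb = 1/slope and Ψ_b(50) = −intercept/slope.

Ψ_b(50) is the vigor indicator of interest: lots with more negative
Ψ_b(50) germinate and emerge better across control, water-stress,
salinity, deep-sowing, cold and field conditions. The package quantifies
this with Pearson correlation / OLS regression matrices between the three
fitted parameters and lot-level vigor variables (germination percentage and
rate/index, emergence percentage, seedling dry weight, and the simplified
vigor index SVI = emergence % × dry weight).

Intended users: seed scientists and forage-legume breeders ranking
commercial seed lots, and anyone fitting population-threshold germination
models to censored count data.

## Worked example

Generate a noiseless panel from a known truth (θ_H = 8.799 MPa·h,
Ψ_b(50) = −0.522 MPa, σ_φb = 0.299 — the package's highest-vigor reference
lot), refit it, and interrogate the fitted model:

```python
from hydrovigor import (default_lot_params, simulate_time_course,
                        fit_hydrotime, time_to_fraction,
                        predicted_max_germination)

truth = default_lot_params()["12"]
courses = [simulate_time_course(truth, psi, 90, noise_mode="noiseless",
                                fractional=True)
           for psi in (0.0, -0.2, -0.4, -0.6, -0.8)]
fit = fit_hydrotime(courses)
print(f"theta_H  = {fit.theta_H:.3f} MPa*h")
print(f"psi_b50  = {fit.psi_b50:.3f} MPa")
print(f"sigma    = {fit.sigma_phib:.3f} MPa")
print(f"r2       = {fit.r2:.3f}")
print(f"t50(0.0 MPa) = {time_to_fraction(fit, 0.0, 0.5):.1f} h")
print(f"Gmax(-0.6 MPa) = {predicted_max_germination(fit, -0.6):.3f}")
```

prints

```
theta_H  = 8.799 MPa*h
psi_b50  = -0.522 MPa
sigma    = 0.299 MPa
r2       = 1.000
t50(0.0 MPa) = 16.9 h
Gmax(-0.6 MPa) = 0.397
```

i.e. the fit recovers the generating parameters exactly, the median seed
germinates after 16.9 h in pure water, and at −0.6 MPa only 39.7% of seeds
lie above their threshold and can ever germinate.

The same workflow from a shell:

```
hydrovigor simulate --out panel.csv --seed 7        # 12 lots x 5 psi x 3 reps
hydrovigor fit --input panel.csv --output params.csv
hydrovigor correlate --params params.csv --germ germ_summary.csv --out table4.csv
hydrovigor reproduce-paper                          # fixture-based screening report
```

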