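# bfckinetics

Single-filament kinetics of the actin barbed-end / formin / capping-protein
ternary complex: a stochastic simulator of individual filaments under
microfluidic flow protocols, and the inference chain that recovers the
underlying rate constants from per-filament switching times.

## The problem

An actin filament's fast-growing (barbed) end can be occupied by a
processive formin (state **BF**, fast elongation from profilin–actin), by
heterodimeric capping protein (**BC**, growth arrested), or — contrary to
the classical mutually-exclusive picture — by **both at once** in a ternary
complex (**BFC**, arrested).  With concentrations in µM and time in
seconds, the kinetic scheme is a four-state cycle:

```
        k+F [F]                k'+C [C]
   B  <--------->  BF   <--------------->  BFC
        k-F                    k'-C
        k+C [C]                k'+F [F]
   B  <--------->  BC   <--------------->  BFC
        k-C                    k'-F
```

Primed constants refer to a barbed end already occupied by the other
protein.  Mutual binding weakens both partners by roughly three orders of
magnitude, so each protein can rapidly displace the other — the mechanism
that lets capping protein limit the dwell time of formins in structures
like filopodia.  The ternary complex decays with overall rate
k′₋C + k′₋F and resolves to BF with branch fraction
f_BF = k′₋C / (k′₋C + k′₋F).

In single-filament microfluidics experiments these transitions show up only
as changes of elongation regime (fast / slow / paused) or as filament
detachment, so the measurable quantities are per-filament *switching times*.
The package simulates exactly that kind of data (continuous-time Markov
chain per filament, state-dependent elongation, camera-limited observation,
right-censoring) and implements the estimators used on it:

* empirical switching-time CDFs with explicit censoring,
* single-exponential fits `A·(1 − e^(−k_obs t))`,
* pseudo-first-order regression of k_obs versus concentration (→ k_on),
* branch-rate splitting k′₋C = f_BF·k_obs with delta-method errors,
* the exposure-titration plateau equation
  `p = (1 − e^(−k'+F·[F]·T_expo)) · f_BF`,
* filament-level bootstrap standard errors.

## Worked example

Recover the association rate constant of CP to formin-bound barbed ends
from a simulated capping titration (50/100/200 nM CP, true value
0.21 µM⁻¹·s⁻¹):

```python
>>> from bfckinetics import get_design, run_design
>>> design = get_design("setup1_capping",
...                     n_per_condition={0.05: 10_000, 0.1: 10_000, 0.2: 10_000})
>>> report = run_design(design, master_seed=31)
>>> for row in report["per_condition"]:
...     print(row["condition"], round(row["k_obs"], 5))
cp_50nM 0.01034
cp_100nM 0.02088
cp_200nM 0.0409
>>> est = report["estimates"]["k_prime_plus_C"]
>>> round(est["value"], 4), round(est["rel_dev"], 4)
(0.2069, -0.0147)
```

The three pseudo-first-order rates are, as expected, proportional to [CP]
(0.0103…0.041 s⁻¹), and the origin-constrained slope recovers the injected
association constant to within about 1.5%.

The same machinery is available from the shell:

```sh
bfckin simulate --design setup2_partition --seed 7 --out-dir results/
bfckin fit --design bcf_titration_mdia1 --seed 7
bfckin reproduce-table --seed 7 --out-dir results/
bfckin filopodia --n0 30 --cp 0.1 --kon 0.08 --t 300
```

`reproduce-table` prints the analytic identities implied by the measured
rate constants (equilibrium affinities in nM, fold changes, branch
fractions, the detailed-balance ratio K_C·K′_F / (K_F·K′_C) ≈ 0.75) next
to full simulation-and-refit recoveries of each directly fitted constant.

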