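# Methods

## Scope and assumptions

`milkpk` predicts *steady-state, AUC-style* milk-to-plasma (M/P)
concentration ratios by passive-diffusion equilibrium. The central
assumptions, shared by every model variant implemented:

- only the unbound, unionised species crosses the mammary epithelium, and at
  steady state its water-phase concentration is equal in plasma and milk
  (pH-partition theory);
- milk is a two-phase matrix — an aqueous "skim" phase with protein binding
  (fraction unbound `fu_m`) and a lipid phase occupying the creamatocrit
  volume fraction Crt — and only unbound skim drug partitions into the lipid,
  with apparent coefficient `Papp_milk`;
- active transport is absent. Transporter substrates violate this and are
  filterable (`filter_transporter_substrates`, default roster BCRP, MDR1,
  MRP2, OCTN1, OCTN2, OCT1, OCT3, OATP1A2, OATP2B1);
- no time dependence: secretion/reuptake kinetics and milk maturation are out
  of scope.

## Equations

Fraction unionised from Henderson–Hasselbalch: acids
`1/(1+10^(pH−pKa))`, bases `1/(1+10^(pKa−pH))`, neutrals exactly 1.
Multiprotic drugs use the single pKa nearest physiological pH; zwitterions
additionally need a declared acid/base branch (default acid) because a
one-pKa treatment cannot represent both groups. `LogD(pH) = LogP +
log10(f_un)`.

Phase engine:

    M/P = fu_p·f_un,p / (fu_m·f_un,m) / (S/W),
    S/W = 1 / (1 + Crt·(fu_m·Papp_milk − 1))

The division by S/W (rather than multiplication) is fixed by the mass
balance `C_whole = (1−Crt)·C_skim + Crt·fu_m·Papp·C_skim`, which the test
suite verifies against the closed form to machine precision, and by the
worked labetalol/zolpidem behaviour (M/P of lipophilic drugs must *rise*
with creamatocrit).

`fu_m` predictors (all clamped into (0, 1] — a fraction unbound cannot
exceed 1, though the Ito and Yang regressions can mathematically):

- Atkinson/Begg (default): `fu_p^0.448 / ((6.94e−4)^0.448 + fu_p^0.448)`
- Ito: `0.4956·fu_p + 0.5335`
- Yang: `1.033·fu_p/(0.988+fu_p) + 0.1017·ln(PSA)` (requires PSA > 1 Å²)

`Papp_milk` formulae (published fits, coefficients config-exposed):

| name               | formula                                              |
|--------------------|------------------------------------------------------|
| phase_distribution | `10^(−0.88 + 1.29·LogD_milk)`                        |
| logpow             | `LogP` (literal; can be negative — warned, preserved)|
| abi                | `10^(0.4017·LogD_milk + 0.1548)`                     |
| mcdb               | `10^(7.489 − 5.327·e^(−0.1153·LogP))`                |
| bartels_logp/logd  | `10^(−4.653 + 7.972/(1+10^(0.1175−0.2849·X)))`, X = LogP or LogD_milk |

The Bartels sigmoid saturates at `LogPapp = 3.319`; the MCDB exponent
grouping (the whole expression as the power of 10) is the reading consistent
with its systematic overprediction, and is overridable via the coefficient
dictionary.

Log-transformed engine (acids/bases only; neutral drugs raise an explicit
unsupported-class error):

    acids: ln M/P = −0.405 + 9.36·ln(f_un,p/f_un,m) − 0.69·ln fu_p − 1.54·ln K
    bases: ln M/P = 0.02477 + 2.28·ln(f_un,p/f_un,m) + 0.886·ln fu_p + 0.505·ln K

with `K = (1−Crt)·fu_m + Crt·Papp` (a whole-milk capacity term mirroring the
S/W mass balance; the literal alternative `1 − Crt·fu_m + Crt·Papp` is
available as `k_literal` — the two differ by < 1% over the physiological
range because `Crt ≤ 0.12`). "ln" is natural log throughout. `fu_m` and
`Papp` come from the Atkinson/Begg and phase-distribution formulae
respectively.

### Ionisation correction of fu_p

Increased ionisation reduces plasma protein binding, so a milk-pH-adjusted
`fu_p` can be fed to the `fu_m` predictors (`*_ion` registry variants). The
exact published regression behind this idea is not available to us in a form
we could transcribe, so the package implements the *mechanism* as a
configurable per-charge-class shift of the bound:free ratio:

    log10 K' = log10((1−fu_p)/fu_p) + c_class·(f_ion(pH_milk) − f_ion(pH_plasma))

with defaults `c_acid = c_base = −1.0`, `c_zwitterion = −0.5`, `c_neutral =
0` (an order of magnitude of binding lost on full ionisation — the scale of
published binding-vs-ionisation effects). It is the identity when disabled,
stays in (0, 1], is monotone in `fu_p`, and is applied at milk pH, only to
the `fu_m`-predictor input — never to the plasma-side `fu_p` of the M/P
equation. Treat the defaults as a sensitivity knob, not a validated fit.

### Observed milk binding

`use_observed_fum` (registry variant `bartels_logd_obsfum`) substitutes a
measured milk fraction unbound for the predicted one. It is an explicit
per-run switch: predicted and measured binding are never mixed silently.

## Heterogeneity sweep

The default grid spans milk pH mean ± 1 SD (7.12 ± 0.24 → 6.88–7.37, 21
evenly spaced points = "twenty identical increments") by creamatocrit
3%–12% in 0.1% steps (91 points): 1911 compositions per drug/model. Wider pH
presets at ±2 and ±3 SD use the literature bounds 6.63–7.62 and 6.38–7.87
verbatim; these differ slightly from naive mean±k·SD arithmetic (7.12±0.48 =
6.64–7.60) and are therefore stored as named presets rather than recomputed.
Plasma pH is fixed at 7.4 (configurable on the grid/composition objects).

`predict_range` reports min/max over all grid points, the arithmetic grid
mean, and a **central** prediction at the midpoint composition (centre of
the pH window, mid-range Crt ≈ pH 7.125, Crt 7.5% on the default grid). The
central value — not the grid mean — is the default location summary and the
basis of AFE and R², because the grid is a uniform design, not a sample from
the physiological distribution; the grid mean remains available.

## Evaluation

- **Fold coverage**: a drug is within k-fold if `[mp_min, mp_max]` intersects
  `[observed/k, observed·k]` (closed intervals — touching counts). This
  "any-in-range" rule credits a model whose physiological envelope reaches
  the observation; 5-fold coverage therefore always dominates 2-fold.
- **AFE**: per-drug symmetric fold error `max(P/O, O/P)` of the central
  prediction, averaged arithmetically ± SD. No standard definition is
  universal here, so a geometric-mean alternative is exposed (`afe=
  "geometric"`); the arithmetic default is the more conservative of the two.
- **R²**: squared Pearson correlation of central predicted vs observed M/P,
  raw scale by default (`r2_on_log` toggles log scale).
- Drugs a model cannot predict (neutrals under the log-transformed engine)
  are excluded from that model's denominator and reported by name.
- Transporter stratification is descriptive only (n, median P/O, IQR, with
  an under-powered flag below n = 5); inferential testing is left to
  standard statistical tools on the exported per-drug table.
- Property correlations (P/O vs fu_p, LogD, MW, PSA, HBD, HBA) report an OLS
  fit plus a Spearman rank correlation, since the fu_p relationship is known
  to be non-linear; a constant property is reported as degenerate rather
  than fitted.

## Synthetic data generator

`generate_synthetic_drugs` emulates a curated drug table: charge class
drawn acid/base/neutral (0.35/0.45/0.20; neutrals omitted when the truth
model is log-transformed), pKa uniform in class-appropriate windows (acids
3–9, bases 5–11), LogP uniform on [−2, 5], fu_p log-uniform on [0.005, 1],
PSA uniform on [20, 150] Å². The "observed" M/P is the truth model's
prediction at the reference composition (pH 7.12, Crt 7.5% — the centres of
the physiological windows) times lognormal noise (default log-SD ln 1.5,
i.e. a typical 1.5-fold observation error). Everything is a deterministic
function of the seed.

What this emulates — and what it does not: real observed M/P ratios carry
study-level aggregation error, assay-era bias, transporter effects and
unrecorded milk composition; the generator has none of these, so synthetic
recovery results demonstrate that the *pipeline* identifies its own
generating mechanism under calibrated noise, not that any model is accurate
on real drugs. Dataset-level accuracy claims require a real observed table
(see `tests/test_acceptance.py::TestDatasetBenchmark` for the expected
schema and location).

## Bundled example drugs

`milkpk/data/example_drugs.csv` holds eight drugs whose constants (pKa,
LogP, fu_p, PSA, observed M/P) were re-transcribed from public
physicochemical databases and the clinical lactation literature. They are
demonstration/test records: different public sources disagree on LogP and
pKa for several of these compounds (labetalol's published LogP spans roughly
1.3–3.1), and per-drug agreement with any published analysis is accordingly
limited by constant provenance, which is why worked-example tests use a 15%
relative band rather than printed precision.

## Numerical notes and edge cases

- All partitioning math is scalar double precision; no iteration, fitting or
  tolerance choices are involved beyond the published coefficients.
- `fu_m` clamping and negative literal-LogP `Papp` values emit warnings; a
  non-positive S/W denominator (possible only with negative `Papp`) raises a
  domain error naming the responsible model.
- Grid evaluation is order-independent and exactly reproducible; grid Crt
  values are rounded to 12 decimals to keep step arithmetic stable.
- `fu_p = 1` is a fixed point of the ionisation correction (no bound drug to
  release); `fu_p ≤ 0` is rejected everywhere.

## Known limitations

- Single-pKa treatment of multiprotic drugs and zwitterions.
- No transporter mechanism — substrates can only be excluded or stratified.
- The interplay between protein binding, lipid partitioning and ionisation
  inside milk is essentially unverified experimentally; the compensating
  structure of the equations (higher binding ⇒ proportionally higher lipid
  uptake) means predicted M/P is often insensitive to the `fu_m` model, and
  that insensitivity is a property of the model family, not evidence of
  correctness.
- The ionisation-correction coefficients are order-of-magnitude defaults,
  not a transcribed published fit.
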