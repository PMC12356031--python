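# Methods

`letrbe` couples a mechanistic Monte-Carlo model of DNA double-strand-break
(DSB) induction, repair and misrepair with the standard clonogenic and
focus-kinetics statistics used to quantify radiosensitivity across radiation
qualities. This note documents the model, its parameters and their defaults,
the synthetic-data generator, and the numerical and design choices a user
should know before trusting or changing anything.

## The mechanistic model

### DSB induction

The nucleus is a sphere (radius 4.0 um, density 1 g/cm^3 by default; the
order of magnitude of an RPE-1 nucleus). The total number of DSBs per
nucleus is Poisson with mean `dose * dsb_yield`, identical for every
radiation quality; the default yield of 35 DSB/Gy per diploid nucleus is
the standard radiobiological value, configurable in `InductionParams`.

What distinguishes qualities is spatial structure:

* **Photons** place breaks uniformly in the sphere.
* **Charged particles** deposit breaks along straight track chords. The
  expected number of traversals follows from the fluence-dose relation
  `D[Gy] = 0.1602 * LET[keV/um] * Phi[um^-2] / rho[g/cm^3]`, so tracks per
  unit dose scale as 1/LET and breaks per track scale as LET. Chords have
  uniform random orientation and impact point; breaks are allotted to
  chords in proportion to chord length and placed uniformly along them.
  Length-proportional allotment matters: it reflects that energy deposition
  scales with path length, and it makes the *marginal* break distribution
  exactly uniform in the sphere, so the photon and particle geometries
  differ only through intra-track clustering. (Uniform-over-tracks
  allotment overweights short peripheral chords and spuriously *reduces*
  break proximity below the photon case at low LET.)

Break complexity is an independent Bernoulli flag with probability 0.25,
deliberately independent of LET: in this model the spectrum of individual
lesions does not change with radiation quality; only their spatial packing
does. This is the central mechanistic assumption the package exists to
exercise.

A microscope does not resolve breaks closer than ~0.5 um: the observable
focus count is the number of single-linkage clusters of break positions at
that threshold (equivalently, connected components of the 0.5-um
neighbourhood graph). At 2 Gy an alpha-particle nucleus carries the same
~70 breaks as an X-ray nucleus but in ~5 tracks, merging into far fewer
visible foci — the model's explanation for induced focus counts *falling*
with LET while damage rises.

### Pathway routing

Each break is routed by cycle phase and phenotype:

* G1: canonical NHEJ for every break.
* S/G2: complex breaks route to HR with probability 0.8, the rest to NHEJ.
* A break whose primary pathway is defective falls through to the alt-EJ
  backup; the *complex-only* defect class fails only for complex breaks
  (how Artemis- and DNA-PKcs-deficient cells are represented).
* Functional pathways can also fail stochastically per break
  (`nhej_failure_prob`, `hr_failure_prob`), modelling partial loss of a
  pathway component; alt-EJ itself fails permanently with the phenotype's
  `alt_ej_failure_prob`, leaving the break unrepaired.

### Misrepair

Misrepair is a competition between correct rejoining (fixed weight
`w_self = 9.5`) and pairing with another break at Gaussian proximity weight
`exp(-d^2 / (2 sigma^2))`, `sigma = 0.35 um`. Breaks are visited in index
order; break `i` misrepairs with probability `S_i / (w_self + S_i)` where
`S_i` sums its weights to still-available partners, chooses the partner
proportionally to weight, and both ends commit (greedy sequential matching,
deterministic under a fixed seed). Breaks handled by alt-EJ carry a
misrepair-weight multiplier of 1.5 (pairwise geometric mean), encoding the
pathway's error-proneness. Misrepair events are labelled inter- or
intra-chromosomal from the partners' chromosome ids (46 equal-content
chromosomes; spatial chromosome territories are not modelled, so the
inter fraction is ~45/46).

`sigma` and `w_self` were calibrated jointly, before any acceptance run was
scored, against three closed-form anchors: wild-type X-ray misrepair of a
few percent of breaks at 2 Gy, a wild-type X-ray SF2 near 0.55, and a
wild-type RBE_MID span of roughly 1 to 6 across LET 0.45-129.3 keV/um.
With uniform break positions the per-break misrepair odds scale as
`n * (2 pi sigma^2)^{3/2} / (V w_self)` and grow linearly with dose
(quadratic, beta-like killing); within a track the odds are
dose-independent (`~(breaks per track / chord length) * sigma * sqrt(2 pi)
/ w_self`, linear alpha-like killing). High-LET curves therefore come out
steeper and more linear without any LET-dependent parameter — the model's
account of the LQ-shape change and of RBE itself.

### Cell fate

Survival multiplies three factors:

```
P = (1-p_inter)^n_inter * (1-p_intra)^n_intra     # lethal aberrations
  * (1-p_unrep)^n_unrepaired                      # unrepaired breaks
  * exp(-g * mu * (n_misrepaired + n_unrepaired)) # G1-checkpoint loss
```

Defaults: `p_inter = 0.5`, `p_intra = 0.1`, `p_unrep = 0.8`, `mu = 0.1`
per lesion; `g` is the phenotype's continuous G1-checkpoint activity in
[0, 1] (1 = fully functional, 0 = checkpoint-null). All are free model
parameters chosen to reproduce the qualitative knockout phenotypes; none
is a measured constant.

### Repair kinetics and residual foci

Correctly rejoining breaks clear with exponential waiting times: 2.0 h^-1
for simple NHEJ breaks, 0.2 h^-1 for complex and HR-routed breaks,
0.1 h^-1 for alt-EJ. Phenotype rate scales slow clearance (DNA-PKcs-null
halves the NHEJ rate; FANCD2-null halves the HR rate) without changing
fidelity. Unrepaired breaks persist. Misrepaired breaks also persist as
foci: a misrejoined junction remains a marked damage site on the
simulation's 24 h horizon. This choice is what makes the wild-type 24 h
residual fraction rise with LET — residual damage tracks the misrepair
fraction, which is the model's only LET-dependent quantity. Without it the
wild-type residual would be near zero at every LET, contradicting the
behaviour of real high-LET data.

### Phenotype presets

| preset | mechanism | rationale |
|---|---|---|
| `wild_type` | all pathways functional, g = 1 | reference |
| `p53` | g = 0 only | checkpoint-null; repair intact; emerges slightly *more* resistant than wild-type (SER < 1) without being forced |
| `fancd2` | HR functional but 60% of HR-routed breaks fail to the backup; HR clearance halved | mild phenotype, just below wild-type |
| `brca1` | HR defective | complex S/G2 breaks lose their preferred pathway |
| `artemis` | NHEJ complex-only-defective | end-processing nuclease needed only for complex ends |
| `dnapk` | NHEJ complex-only-defective + 8% simple-break NHEJ failure + halved NHEJ rate | sensing/synapsis role beyond end processing; slower clearance |
| `lig4` | NHEJ defective | all breaks to the backup |
| `atm` | NHEJ defective + backup failure raised to 0.15 + g = 0 | the sensor/signalling kinase feeds every end-joining route; most sensitive preset |

Knockout lethality is deliberately dominated by *LET-independent*
failure-to-repair channels (alt-EJ fall-through and failure), with the
default backup failure probability at 0.06. Two consequences were design
goals: the X-ray sensitivity ranking ATM < LIG4 < DNA-PK < Artemis <
BRCA1 < FANCD2 < WT <= p53 (by MID) is reproduced, and SER compresses
toward 1 for every knockout as LET rises, because the knockout-specific
added killing is flat in LET while the wild-type baseline grows. An
earlier design that expressed pathway slowdown as a misrepair-weight
multiplier was rejected: multiplicative defects amplify the intra-track
misrepair gain *faster* for knockouts than for wild-type and push SER
*up* at low particle LETs, contrary to the SER compression the model is
required to show. The ATM preset likewise could not be expressed as
"slow NHEJ + complex-break failure": slow-repair multipliers produce
dose-quadratic killing, and the low-dose region that dominates the MID
would always rank LIG4 (whose failure channel is linear in dose) as more
sensitive than ATM; raising ATM's backup-failure probability instead makes
it the most sensitive preset through the same linear channel.

Modelled SER magnitudes are exaggerated relative to typical experimental
values (the mechanistic wild-type has almost no linear killing component at
X-rays, so its MID is high); the package treats model SER/RBE *orderings*,
not magnitudes, as meaningful. This is a known limitation.

### Monte-Carlo design

`predict_survival_curve` averages the survival probability over `n_cells`
nuclei per dose (default 1000; at least 100 enforced). Two variance-
reduction devices sharpen comparisons without changing expectations:

* **Common random numbers.** Each nucleus is seeded per (dose, cell) but
  not per quality or phenotype, and every repair stage consumes a fixed
  number of draws regardless of outcomes. Curves computed at the same seed
  therefore share break-count, complexity, routing and pairing randomness,
  so MID ratios (RBE, SER) isolate physical differences. This matters: at
  LET 1 keV/um the intra-track effect on the MID is only ~2-4%.
* **Repair replicates.** The stochastic repair stage is replayed
  `n_repair_reps = 8` times per sampled geometry (reusing the proximity
  kernel) and the survival probability averaged, Rao-Blackwellising the
  pairing noise.

Even so, two SER comparisons sit at the edge of Monte-Carlo resolution at
10^3 nuclei per dose: the mildest knockouts (FANCD2, and to a lesser
degree BRCA1) have true SER drops of only ~0.3-0.5% between X-rays and the
1 keV/um proton quality, against residual noise of a similar order. The
expected direction is correct; individual seeds can tie.

Model MIDs are computed from the predicted curves on fixed per-quality
dose grids (X-rays and 58 MeV protons to 6 Gy, alpha particles to 2 Gy),
chosen so the log-linear tail beyond the last dose stays a small fraction
of the integral for every preset.

## Clonogenic statistics

* **LQ fit** (`fit_lq`): constrained least squares on `ln SF` with
  `alpha, beta >= 0`. When per-replicate colony counts are available the
  fit runs at replicate level with counting-statistics sigmas
  (`var(ln SF) ~ 1/colonies + 1/colonies_at_0Gy`, absolute); simulation
  shows ~95% two-sigma coverage for alpha under binomial colony noise,
  whereas empirical replicate-variance weights from triplicates gave
  ~62-73% coverage and are used only as a fallback.
* **MID** (`compute_mid`): piecewise exponential (log-linear)
  interpolation between measured points, flat-segment limit `S * dD` when
  `|lambda| < 1e-12`, and a log-linear tail from the final segment's rate;
  the tail fraction is reported and a warning raised above 20%. On dense
  LQ samplings the result agrees with the closed form
  `sqrt(pi/(4 beta)) * exp(alpha^2/(4 beta)) * erfc(alpha/(2 sqrt(beta)))`
  (evaluated via `erfcx` for stability) to well under 1%; on the
  generator's sparse study grids the interpolation bias is at most ~1.3%
  (X-ray grids, where lnSF curvature between 4-8 Gy is largest).
* **RBE_MID / SER** (`compute_rbe`, `compute_ser`): plain MID ratios with
  first-order (delta-method) SE propagation when input SEs exist.
* **Mylar correction** (`apply_mylar_correction`): plate doses are
  multiplied by 1.22 to land on the Mylar dose axis before an X-ray
  reference MID enters an alpha-particle RBE; the factor is configurable
  and `1/factor` inverts the direction, which is exposed because the
  correction's orientation is an assay-level convention.
* **Line fits** (`fit_linear`): OLS with slope SE and R^2; a constant
  response returns slope 0 with R^2 = 0 rather than erroring.

Surviving fractions are normalised per replicate against that replicate's
0 Gy plating efficiency before averaging. Trailing doses with zero pooled
colonies carry no information on a log scale; they are dropped with a
logged warning (never silently).

## Focus-kinetics analysis

One-phase decay `y(t) = plateau + (y0 - plateau) e^{-kt}` with
`k, plateau >= 0`, weighted by per-timepoint SEM when available
(`absolute_sigma`, for honest parameter SEs under count noise). A flat
course is returned with the rate flagged unidentifiable instead of
raising. Model-free summaries: induction = the earliest timepoint's mean
(nominally 1 h; a later first timepoint is flagged), percent residual =
100 x (24 h mean)/(1 h mean), percent repaired its complement. Residual
percentages above 100 are possible under noise and flagged. The
residual-vs-LET regression is a thin wrapper over `fit_linear`.

## Synthetic-data generator

The generator emulates an eight-line (wild-type + seven knockout), six
quality clonogenic and 53BP1 study with exported ground truth; it is the
test bed for every analysis stage, since the study it emulates published
no raw data.

* **Clonogenic**: colonies ~ Binomial(cells_seeded, PE x SF), PE = 0.5,
  LQ survival from the truth table, triplicate. The truth table is
  hand-set and non-canonical: X-ray alphas (0.22-0.90 Gy^-1 across lines,
  shared beta 0.045 Gy^-2) encode the sensitivity ranking, and per-quality
  alpha multipliers (1.36 -> 9.29) with shrinking beta multipliers
  (0.95 -> 0.05) were solved so the wild-type RBE_MID envelope is
  1.16/1.49/2.18/2.92/5.56 across the five particle qualities, with beta
  -> 0 (curve linearisation) at high LET. With shared multipliers, MID
  ordering is preserved at every quality and truth RBE rises strictly with
  LET for every line, by construction.
* **Dose grids** mirror the study design (X-rays 0-8 Gy in seven steps,
  alphas 0-2 Gy in six). Cells seeded per dose rise from 10^4 (0 Gy) to
  4 x 10^5 (interpreted as pooled wells): the 0 Gy reference is kept large
  because plating-efficiency noise multiplies into every normalised SF,
  and MID recovery within a few percent requires sub-2% counting noise.
  With these settings the worst-case MID recovery error over all 48 cells
  stayed <= 2.7% across ten generator seeds.
* **Foci**: per-cell counts ~ Poisson(mu(t)) over 50 cells at t = 1, 2, 4,
  8, 24 h, `mu(t) = N1 (res + (1-res) e^{-k(t-1)})`. Wild-type truths:
  induction 24.3 -> 14.6 foci/cell and 24 h residual 5.7% -> 49.9% from
  X-rays to alphas, decay rate 0.40 -> 0.22 h^-1; knockouts scale residual
  up (to x3.2 for ATM-null) and rates down (to x0.30).

What the generator does *not* emulate: plating/pipetting variance beyond
binomial counting noise, per-cell focus-count distributions (only
means/SEMs are emitted), cell-cycle-resolved foci, background (0 Gy) foci,
and any microscope-level artefact. Passing recovery tests therefore show
the estimators are correct under idealised counting noise, not that they
are robust to every failure mode of real assays.

## Determinism

All randomness flows from explicit `numpy.random.Generator` seeds; the
pipeline requires a seed in its config and has no hidden entropy. A fixed
seed reproduces break sets, repair outcomes and output tables
byte-identically. Seeds derived internally use `SeedSequence` lists and
stay within 32-bit range.

## Known limitations

* Chromosome territories, non-spherical nuclei, amorphous radial track
  dose profiles and secondary-electron transport are not modelled; nuclear
  geometry in particular is a recognised driver of high-LET response that
  this model omits.
* Sub-lethal damage repair, dose-rate effects, fractionation and an
  explicit aberration taxonomy (dicentric vs ring vs translocation) are
  out of scope.
* The mechanistic wild-type underestimates the linear (alpha) component of
  low-LET killing, which exaggerates SER magnitudes; orderings, not
  magnitudes, are the model's reliable output.
* The complex-only failure class is modelled as total failure for complex
  breaks; a rate-limited variant would also be plausible.
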