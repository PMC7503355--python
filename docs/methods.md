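# Methods

## Scope and model

The package operationalises a chain of analyses around a missense
variant of an enzyme: (i) pedigree-based candidate filtering, (ii)
structural/energetic descriptors of MD trajectories of the
enzyme–cofactor–ligand ternary complex, (iii) persistence of sidechain
interactions, and (iv) linear QSAR models predicting Michaelis–Menten
parameters from those descriptors. The package consumes trajectories;
it does not run molecular dynamics, build force-field topologies, or
place mutant rotamers. Consequently it makes no attempt to reproduce
any published *absolute* SASA/energy/persistence value that depends on
particular simulations — those operations are validated against
analytic closed forms, brute-force oracles and synthetic ground truth
instead, while the QSAR stage is validated against the bundled
descriptor/kinetics panel, which is in-repo data.

## Segregation filtering

A dominant, fully penetrant (within the expressing sex) model is
assumed: a surviving variant is heterozygous in every affected and
absent in every control. The five criteria are independent predicates;
the survivor set is order-invariant, while per-stage removal counts
charge each variant to the first failing stage in the documented order.
Policy choices the data cannot decide:

* *Missing genotypes.* In an affected individual: hard error
  (segregation cannot be asserted). In a control: treated as absent by
  default (lenient), switchable to strict. A sequencing gap in a control
  is far more often a no-call than a hidden carrier.
* *Frequency threshold.* Variants **more** frequent than the threshold
  (default 1%) are removed, so AF exactly at the threshold survives.
* *Hom-alt in an affected* fails the heterozygosity criterion — under a
  dominant model with a rare allele, a homozygote is implausible and
  more likely a genotyping artifact.
* All variants are treated autosomally; no sex-specific genotype logic.

## Trajectory descriptors

**SASA** uses the Shrake–Rupley construction: each atom inflated by the
probe radius (default 1.4 Å, water), sampled with a golden-spiral
lattice (default 960 points/atom), points occluded by any other atom of
the *whole system* removed, surviving fraction × sphere area summed
over the target group. Reported in nm². Quadrature error scales as
~n⁻¹ᐟ²; at 960 points, 3-atom clusters agree with a dense Monte-Carlo
surface integration to better than 2%. Translation invariance is exact;
rotation invariance holds to quadrature error because the lattice is
space-fixed.

**Interaction energy** between two disjoint atom groups is the sum over
inter-group pairs of ke·qᵢqⱼ/r (ke = 138.935485 kJ·mol⁻¹·nm·e⁻²) and
4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot combination (arithmetic σ,
geometric ε). No cutoff by default and no mesh-Ewald or long-range
dispersion correction: the toy systems the package evaluates are small
and non-periodic, and the QSAR stage consumes *differences between
variants* of in-paper descriptor values, never absolute energies
recomputed here.

**RMSF** is the per-atom root mean square displacement about the
trajectory-average structure over Cα atoms. Superposition (default on,
matching the common MD-tool convention) performs one round of
mean → Kabsch fit of every frame → recomputed mean before measuring
displacements. For isotropic per-axis jitter of SD σ the expected RMSF
is σ√3 (root of a scaled χ² mean), which the implementation reproduces
within 3% at 10⁴ frames.

**Summary statistics** over frames use the population SD (divisor n):
the frames are the complete sampled population of the trajectory, and
at MD frame counts the n vs n−1 distinction is far below reporting
precision. Distributional comparisons between variants use the
one-tailed Welch t-test (unequal variances); two degenerate equal-mean
zero-variance samples sit on the null boundary and return p = 0.5 by
convention.

## Interaction persistence

Persistence = 100 × (frames satisfying the geometric criteria)/(total
frames). Hydrophobic contacts: mass-weighted sidechain centres of mass
within 5.0 Å, over the residue set {ALA, VAL, LEU, ILE, PHE, MET, PRO,
TRP}; hydrogen bonds: donor–acceptor distance ≤ 3.5 Å **and** D–H···A
angle (vertex at the hydrogen) ≥ 120°. These defaults follow the
sidechain interaction-network convention used by PyInteraph-style
analyses; all are configurable. Glycine (no sidechain atoms) is skipped
with a warning; a donor without an attached hydrogen is a hard error.
Persistence equals brute-force per-frame enumeration exactly — no
tolerance — and is invariant under frame reordering and rigid-body
motion.

A reference table of published persistence percentages for the
wild-type vs L213Q hydrophobic network and the variant's novel hydrogen
bonds ships as `data/persistence_reference.tsv` for documentation; the
underlying trajectories are not available, so these values are context,
not test targets.

## QSAR protocol

All responses (kcat in min⁻¹, Km in µM, kcat/Km in min⁻¹µM⁻¹) are
modelled as log₁₀; all fits are unweighted OLS via a least-squares
solve (equal to the normal-equation solution to 1e-10 relative
tolerance, property-tested). Descriptor SDs are carried for reporting,
never as weights. The selection protocol per response:

1. every descriptor as a single predictor; accept the best single model
   if its fit R² ≥ `min_single_r2` (default 0.65 — the panel's accepted
   single model sits at 0.72 and its rejected competitors at ≤ 0.48, so
   any bar in between behaves identically; 0.65 leaves margin on both
   sides);
2. otherwise all descriptor pairs, subject to (a) *independence*:
   predictor–predictor R² ≤ `independence_max_r2` (default 0.5, the
   midpoint of the observed gap between accepted pairs at R² ≤ 0.32 and
   a rejected pair at 0.63); (b) *redundancy*: the double fit must gain
   ≥ `redundancy_min_gain` (default 0.05) R² units over the better of
   its two single fits — on the bundled panel this reproduces the
   rejection of the turnover double model (gain 0.045) while keeping
   the efficiency double model (gain 0.24); (c) the same 0.65 bar;
3. a response with no surviving model is reported "unmodelled" (Km on
   the bundled panel).

The efficiency response uses the *tabulated* kcat/Km column rather than
recomputing kcat ÷ Km: the published one-decimal ratios are the values
the original analysis fitted (they reproduce R² = 0.73 where the
recomputed ratio gives 0.72 and different coefficients); a config
switch (`recompute_ratio`) exposes the other convention.

**Leave-one-out.** Each variant is held out in turn; the refit's
training R² feeds the mean ± SD summary (the only reading that yields a
dispersion for a deterministic procedure), and the held-out log₁₀
prediction feeds MSE = (1/n) Σ (obs − pred)². A fold whose reduced
design is degenerate is excluded with a warning. A two-point fold that
fits its data exactly takes R² = 1 by convention (0/0 limit of the
variance ratio).

**Prediction.** kcat and kcat/Km come from exponentiating the two
models at the new variant's descriptors; Km = kcat ÷ (kcat/Km), which
makes the triple internally consistent by construction. By default the
models are evaluated at tabulation-precision coefficients (slopes 4
decimals, intercept 3), reproducing what the printed equations yield;
full precision is a flag away. Descriptors outside the training range
flag the result as an extrapolation (informational).

On the bundled panel the full-precision turnover intercept is −3.52175,
which prints as −3.522 where the published equation shows −3.521 (a
single unit in the last printed digit, consistent with truncation or
with unprinted digits in the source kinetics); the downstream predicted
kcat is 38.1 vs the tabulated 38.2 min⁻¹ (0.3%). Likewise the held-out
LOO MSE computes to 0.128 (model A) and 0.403 (model B) against
published 0.125 and 0.394 — a uniform ~2% consistent with the 1–3
printed digits of the tabulated kinetics. These are the only deviations
from the published statistics; all fitted coefficients and R² values
reproduce exactly at printed precision.

## Synthetic data

The generators define the conditions all recovery tests run under:

* **Trajectories** place one-atom residues on a 20 Å grid (no
  accidental contacts); a scheduled pair sits just inside the 5 Å
  contact cutoff for the first ⌊fraction·n⌋ frames and just outside for
  the rest, with the in/out separations offset from the cutoff by more
  than the maximum jitter excursion (Gaussian jitter clipped at 3σ per
  axis), so scheduled fractions are exact by construction. This
  emulates the binary formed/broken character of a native contact, not
  the continuous distance distributions of real MD.
* **QSAR panels** draw descriptors uniformly from the observed
  descriptor ranges of the real panel (energies −130…−95 and −35…−5
  kJ/mol; distractor surface areas 0.8…1.6 nm²) and apply planted
  log-linear laws shaped like the accepted models, plus Gaussian
  residual noise in log₁₀ units; Km is derived from kcat and kcat/Km
  so the kinetic triple is consistent. The default panel size is 8
  variants, the size of the real training set; recovery experiments use
  50. Real descriptor panels have correlated, non-uniform descriptors —
  the generator demonstrates recoverability, not robustness to
  collinearity.
* **Families** mirror the study design: 12 members across three
  generations, 3 affected females, a 22-individual unrelated cohort,
  one causal variant heterozygous in exactly the affected members, and
  background variants each planted to violate exactly one filter
  criterion (uniformly chosen), which makes per-stage removal counts
  predictable. Real WES data violate criteria jointly and contain
  missingness patterns the generator does not model.

Determinism: every generator draws from a single `numpy` Generator
seeded from its spec; identical specs give byte-identical outputs
(asserted down to written files).

## Problem sizes and known limitations

Test and acceptance workloads are deliberately small — trajectories of
≤ 100 frames and ≤ 10 atoms, 10⁴-frame jitter runs only where a
distributional limit is asserted, selection-recovery experiments of 40
replicates at n = 50 — sizes at which every oracle (dense-grid surface
integration, double-loop energy sums, per-frame enumeration,
permutation tests) is itself cheap and trustworthy.

Limitations: no periodic boundary conditions or long-range
electrostatics; no weighted or regularised regression and no models
with more than two predictors (the protocol under study is strictly
1–2 predictor OLS on a small panel, where regularisation would change
the question, not answer it); the variant filter performs no annotation
— population frequency and consequence must be pre-annotated in the
input; and predictions for descriptors far outside the training range
are extrapolations of a two-parameter line and should be treated as
such.
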