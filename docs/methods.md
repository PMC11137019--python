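# Methods

## Operational model and transduction coefficients

The response model is the Black–Leff operational model

E = basal + (Em − basal)·τⁿAⁿ / ((A + K_A)ⁿ + τⁿAⁿ)

with A the agonist concentration (molar), Em the system maximum and
basal the constitutive level on the normalized response scale (% of the
reference agonist's maximum), K_A the functional dissociation constant
(molar), τ the efficacy and n the transducer slope. Closed forms used
throughout for validation: observed plateau
Emax_obs = basal + (Em − basal)·τⁿ/(1 + τⁿ) and half-plateau
concentration EC50 = K_A/((2 + τⁿ)^{1/n} − 1).

Fits are parameterized directly in logR = log10(τ/K_A), so the quantity
of record and its standard error come straight from the fit covariance.
Two constraint modes:

* **full-agonist** (fitted logistic plateau ≥ 90% of the reference Em):
  τ and K_A are not separately identifiable, so logKA is fixed — at the
  ligand's binding pKi when supplied as metadata, else at −6 (1 µM, a
  typical mid-panel affinity) — and logR and Em are fitted. logR is
  insensitive to the choice (verified to < 1e-3 across fixed logKA from
  −5.5 to −7), and any residual offset cancels in the referenced
  differences.
* **partial-agonist**: Em is fixed at the reference curve's fitted
  system maximum and logR and logKA are fitted jointly; plateau plus
  potency identify both.

The transducer slope defaults to n = 1: at the data density of a
typical panel (triplicates over a half-log grid) n is effectively
unidentifiable, and the referenced ΔΔ is insensitive to it.

Bias chain: Δlog(τ/K_A) per pathway against the reference agonist,
ΔΔlog(τ/K_A) between pathways, bias factor 10^ΔΔ with a 95%
normal-approximation CI (10^(ΔΔ ± 1.96·se)). Standard errors combine in
independent quadrature — replicate-level pairing information is not
available from summary tables, which is a known source of divergence
from bias factors computed on paired replicates (see Limitations). A
ligand inactive on either pathway yields an undefined bias cell, never
a number.

All least-squares fits (logistic and operational) use five multi-start
initializations — quantile-spaced potency guesses — keeping the lowest
residual sum of squares, so the convergence flag is not an artifact of
one lucky start. Logistic Hill slopes are bounded to (0.3, 5); plateau
bounds scale with the data range, which keeps the fit scale-equivariant.

## Activity ("NA") calls

A ligand/pathway cell is called inactive when an F-test of the logistic
fit against a constant-mean model is non-significant at α = 0.05
(flat-curve) or the fitted span Emax − basal is below 10% of the
reference maximum (below-floor). Both thresholds are configurable; the
defaults reproduce the inactive pattern of the bundled published panel.
Inactive cells propagate: operational fitting refuses them and the bias
matrix renders them undefined.

## GTPγS percent-of-basal statistics

Basal [35S]GTPγS loading per Gα subunit defines 100%. Effects are
tested with a two-tailed one-sample Student t from summary statistics
(t = (mean − 100)/SEM, df = n − 1); drug-vs-blocked comparisons use a
two-sample t, pooled-variance Student by default with Welch available
by flag. Classification at α = 0.05: significant increase → agonist,
decrease → inverse agonist, else no effect; mediation is complete when
the between-arm test is significant and the blocked arm no longer
differs from basal, partial when both are significant, none when the
arms do not differ. Knockout-tissue comparisons reuse the same
two-sample machinery via genotype arms.

Notes from reproducing the bundled published panel:

* The one-sample column reproduces at printed rounding within ~0.002;
  printed means/SEMs carry one decimal, and half-ulp input rounding
  propagates a few thousandths into p.
* The between-condition column reproduces in **every** cell under the
  Welch variant but only in a subset under pooled Student. The pooled
  default is retained as the conventional reading of "Student's
  t-test"; the Welch agreement is documented here and asserted in the
  tests. Under Welch the table's one ambiguous replicate-count cell
  (n = 5 vs 6 for one antagonist arm) is resolved by the plain n = 6
  parse; the bundled CSV records the alternative parse in `n_alt`.
* No multiple-testing correction is applied, mirroring (not endorsing)
  the source table's convention; a Bonferroni-style correction can be
  applied by lowering α.
* Capture antibodies and GDP conditions differ per subunit, so the
  assay is semiquantitative across subunits: no operation accepts two
  different subunits.

## Trajectory clustering and contact fingerprints

Every frame is rigid-body superposed (Kabsch) onto frame 0 using
receptor heavy atoms, then pairwise ligand heavy-atom RMSD is computed
*without* further fitting — ligand movement in the receptor frame of
reference. A per-pair best-fit ligand RMSD (internal pose change only)
is available by flag, since the upstream convention is not uniquely
determined. Frames are clustered by unweighted average linkage cut at
5 Å; the cluster count is emergent. The main cluster is the largest,
with ties broken by smallest mean intra-cluster RMSD, then lowest
label.

Contacts are computed per frame over main-cluster frames: a residue is
in contact when any heavy-atom pair (residue, ligand) is strictly
within 3 Å. Frequencies are % of main-cluster frames; the reported set
filters strictly above 50% (a residue at exactly 50.0% is excluded);
the ECL2 summary sums unthresholded frequencies over residues tagged
ECL2 in the caller-supplied annotation (so it can exceed 100%).
Hydrogens are excluded everywhere. Generic (Ballesteros–Weinstein)
numbers and loop membership are annotation inputs, never computed.

## Synthetic generators

* **Concentration–response**: operational forward model plus additive
  homoscedastic Gaussian noise on the response scale — the simplest
  model consistent with symmetric error bars; default triplicates with
  noise SD 5% of Em, a mid-range choice for normalized BRET panels
  (the source data do not state a replicate noise magnitude, so this
  is a package default, not a literature value). Default grid: half-log
  steps from 1e-12 to 10^−4.5 M (16 points), bracketing potencies from
  pEC50 ~ 5 to ~ 10.5.
* **GTPγS**: i.i.d. Gaussian replicate sets at designed mean/SD/n on
  the percent-of-basal scale.
* **Trajectories**: designed ligand pose templates (inter-pose RMSD
  validated to exceed the clustering cutoff) with Gaussian positional
  jitter; a rigid receptor scaffold far outside contact range provides
  the alignment frame; designed contact residues place a side-chain
  atom 2 Å from the ligand in exactly round(f·n_main) main-pose frames.
  An optional per-frame global rigid motion (default on) exercises the
  superposition step. Pose frame counts use largest-remainder
  apportionment, so designed weights are realized exactly.

All generators take explicit integer seeds (documented default 42) and
are bitwise reproducible. What they do **not** emulate: raw BRET
ratios or luminescence, radioligand counts, heteroscedastic or
correlated replicate noise, receptor flexibility, solvent, or
force-field physics. Passing tests therefore demonstrate correctness of
the analysis chain under its stated statistical assumptions, not
robustness to real-data pathologies.

The recovery study conditions (two pathways, reference τ = 10⁴, test
ligand full on one pathway and τ = 0.8 on the other) reflect the
receptor reserve the published panel itself implies — a reference
transduction coefficient near 9.5 with micromolar-scale binding
affinity implies log τ ≈ 4 — which keeps the full-agonist
non-identifiability bias log10(1 + 1/τ) far below the reporting
precision.

## Numerical choices

* Logistic/operational fitting via Levenberg–Marquardt least squares
  (lmfit); standard errors from the covariance; singular covariance
  leaves estimates with NaN standard errors and the converged flag
  honest.
* Hierarchical clustering via SciPy's average-linkage implementation;
  an O(n³) naive dendrogram builder lives in the tests as an
  independent oracle, as do a per-pair distance scan for contacts and
  numerical quadrature of the t density for p values.
* p-value rendering: three decimals, "<0.0001" below 1e-4, "<0.001"
  when three decimals would round to zero, "ns" at or above α.
* Pipeline reports are written only after all stages succeed; rows are
  sorted and floats formatted to six significant digits, making bundles
  byte-identical across reruns; the manifest records config, seed,
  version and SHA-256 checksums.

## Known limitations

* Bias factors from summary-level tables cannot reproduce values that
  were originally computed with replicate-level pairing; on the bundled
  panel exactly one printed factor is mean-recoverable and the package
  documents the computed-from-means values for the rest rather than
  matching them.
* The logistic pEC50 equals the operational closed-form EC50 only when
  the curve is logistic in shape (n = 1, or τ large); at n ≠ 1 the
  fitted midpoint deviates by a few hundredths of a log unit from the
  exact half-plateau concentration. Tests assert 0.01 at n = 1 and
  0.03 otherwise.
* The F-test activity call assumes i.i.d. Gaussian residuals; with few
  points or strong heteroscedasticity its α is nominal only.
* Trajectory I/O is multi-model PDB/XYZ plus annotation CSV; binary MD
  formats (DCD/XTC) are expected to be converted externally.
* The pipeline's full-agonist threshold (90% of reference Em) is a
  sharp rule; ligands hovering at the boundary can flip mode between
  noisy replicates, which inflates ΔΔ variance slightly but does not
  bias it.
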