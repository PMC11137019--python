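# gpcrbias

Quantitative analysis chain for multi-pathway GPCR signaling panels,
built around a serotonin 5-HT2A receptor case study: concentration–
response fitting and operational-model bias quantification of BRET
panel data, [35S]GTPγS percent-of-basal statistics with pharmacological
effect classification, and MD ligand-pose clustering with residue
contact-frequency fingerprints. A synthetic-data module generates
inputs with the statistical structure every stage assumes, so the whole
chain is testable without downloads.

Audience: pharmacologists and computational chemists quantifying biased
agonism across G-protein and β-arrestin pathways, and anyone needing a
tested, scriptable implementation of the ΔΔlog(τ/K_A) workflow.

## The model

Responses per ligand/pathway are fitted with the Black–Leff operational
model

    E = basal + (Em − basal) · τⁿAⁿ / ((A + K_A)ⁿ + τⁿAⁿ)

separating functional affinity (K_A, molar) from efficacy (τ). Each
cell of the panel is summarized by the transduction coefficient
log(τ/K_A). Referencing to the endogenous agonist cancels system and
observation bias:

    Δlog(τ/K_A)  = logR(ligand) − logR(reference)      per pathway
    ΔΔlog(τ/K_A) = Δ(pathway₁) − Δ(pathway₂)           per ligand
    bias factor  = 10^ΔΔ

A pathway with no measurable activation (flat or sub-threshold curve)
propagates as an *undefined* bias cell — no formal bias factor exists
without activation on both pathways.

Alongside: four-parameter logistic fits supply the pEC50/Emax columns
and the activity call; the GTPγS module runs two-tailed one-sample
t-tests against basal (= 100%) and two-sample tests against
antagonist-blocked arms to classify each drug/subunit as agonist,
inverse agonist or no effect with complete/partial/no receptor
mediation; the trajectory module superposes frames on the receptor,
clusters ligand poses by RMSD (average linkage, 5 Å cut), and reports
per-residue contact frequencies (3 Å, strictly above 50%) plus the
accumulated contact frequency over ECL2 residues.

## Worked example

```
python analysis/01_simulate_inputs.py --seed 42
python analysis/03_bias_factors.py
```

prints (among other lines):

```
synthetic panel: drugA ΔΔlog(τ/K_A) P1 over P2 = 3.45 ± 0.09 (designed 3.30), factor 2818
published panel: Nitro-I Gq over Gi1 factor = 51.3 (printed as > 50)
published panel: 112 pathway pairs carry no formal bias factor (no measurable activation)
```

The first line is the recovery check on simulated data: a test ligand
designed with ΔΔ = 3.30 between two pathways (full agonist on one,
partial on the other, triplicates with 5%-of-Em noise) comes back at
3.45 ± 0.09 through the full fitting chain. The second line recomputes,
from the bundled published transduction-coefficient means, the Gq-over-
Gi1 bias of the nitro-substituted tryptamine relative to 5-HT
(ΔΔ = 1.71 → 51.3-fold). The third counts the pathway pairs rendered
undefined by "no activity" cells.

`analysis/04_gtpgs_classification.py` classifies the bundled
percent-of-basal panel and prints the headline pharmacology — inverse
agonism at Gαi1 for two of the four drugs, antagonist-reversed:

```
published panel: inverse agonism called for [['Met-I', 'Gi1'], ['OTV1', 'Gi1']] ...
```

`analysis/02_fit_dose_response.py` and
`analysis/05_trajectory_contacts.py` cover the logistic-fit and
contact-fingerprint stages the same way. A `gpcrbias` CLI exposes the
same operations (`gpcrbias --help`).

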