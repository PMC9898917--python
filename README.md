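# thaggfip

Thermodynamic and aggregation fingerprinting of immunoglobulin light
chains (IgLCs).

Free monoclonal light chains — overproduced in multiple myeloma and
deposited as amyloid fibrils in AL amyloidosis — are characterised in the
lab by a battery of biophysical assays: thermal/chemical unfolding by
differential scanning fluorimetry (DSF), aggregation onset by dynamic
light scattering (DLS), the historical Bence-Jones heat-turbidity test,
thioflavin-T (ThT) aggregation kinetics at acidic pH, and proteolytic
digestion by co-purified lysosomal cathepsins.  `thaggfip` implements the
complete data-analysis layer behind such a multiparametric fingerprint as
a tested, reusable Python package, together with a synthetic-data module
that forward-simulates every instrument read-out with known ground truth.

## What it computes

**Protease cleavage analysis** (`thaggfip.cleavage`).  From 8-residue
substrate windows (P4..P1 | P1'..P4') a position-specific scoring matrix
is built per protease: `p(a,j) = (count(a,j) + q) / (N + 20q)` with
additive pseudocount `q = 5`, scored as natural-log odds
`s(a,j) = ln(p(a,j)/b(a))` against the human-proteome background `b`.
Every position of a query sequence gets the maximum window-sum over the
matrices, converted to a cleavage probability by the logistic
`p = e^s/(1+e^s)` (a score of 1.5 is ~81.7 %).  Around observed peptide
fragments a *proximal region* (fragment termini ± a two-residue
exopeptidase margin) is compared with the rest of the sequence by a
one-tailed Mann-Whitney U test — exact by enumeration for small pooled
samples, tie-corrected normal approximation otherwise.

**Thermal-scan analysis** (`thaggfip.thermostab`).  Tm as the maximum of
the first derivative of the smoothed I350/I330 fluorescence ratio; Tagg
as the temperature where a sigmoid fitted to the DLS cumulant radius
first exceeds its baseline extrapolation by 0.5 %; dTm/dlog c and
dTagg/dlog c as least-squares slopes versus log10 concentration; and the
turbidity maximum and its reversibility for the capillary Bence-Jones
test.

**Global unfolding thermodynamics** (`thaggfip.foldfit`).  Two-state
model with Gibbs-Helmholtz temperature dependence and linear urea
dependence,

    dG(T, c) = dHm (1 − T/Tm) + dCp (T − Tm − T ln(T/Tm)) − m·c,

fitted globally across a urea grid and both emission wavelengths
(baselines solved by variable projection), with the m-value optionally
fixed to a shared value (7.1 kJ/mol/M).  Reported as dG(37 °C) with a
confidence interval from 100-fold bootstrap over capillaries.

**Aggregation kinetics** (`thaggfip.aggkin`).  Per-trace fit of the
generic sigmoid `Y = y_i + m_i t + (y_f + m_f t)/(1 + e^{−(t−t50)/k})`
giving the halftime t50, plus the ThT fold increase and the aggregated
fraction from A280 depletion of the supernatant.

**Fingerprint statistics** (`thaggfip.fingerprint`).  Typed fingerprint
table with ordered-categorical encodings (refolding small/medium/large →
0.33/0.50/0.66; refolding at 2 M urea 0/<50/>50 → 0/1/2), mean imputation
and standardisation, pairwise-complete Pearson/Spearman correlation
matrices, and an elastic-net regression against a clinical target with
4-fold cross-validated grid search.

**Synthetic data** (`thaggfip.synthgen`).  Deterministic, seeded
generators for all of the above, writing plain-text FASTA/TSV/CSV plus a
JSON ground-truth sidecar.

## Worked example

```python
import numpy as np
from thaggfip import cleavage, synthgen, foldfit, aggkin

# synthetic proteolysis dataset with a planted cathepsin-like motif
cfg = synthgen.SynthConfig(seed=11)
ds = synthgen.gen_cleavage_dataset(cfg, seq_len=214, n_fragments=6)
pssms = [cleavage.build_pssm(w, pseudocount=5, protease_id=p)
         for p, w in ds.windows.items()]
profile = cleavage.score_sequence(ds.sequence, pssms, parent_id=ds.parent_id)
mask = cleavage.proximal_mask(ds.fragments, len(ds.sequence))
res = cleavage.edge_enrichment_test(profile, mask)
print(f"edge test: U={res.U:.0f}, one-tailed p={res.p_value:.2e}")

# global two-state unfolding fit on a simulated urea grid
truth = synthgen.default_stability_truth()
T = np.arange(25.0, 70.0 + 1e-9, 2.0)
curves = synthgen.gen_melt_curves(truth, T_grid=T, noise_sd=0.003,
                                  n_capillaries=3, seed=11)
est = foldfit.bootstrap_ci(curves, n_boot=100, seed=11, fix_m=7.1)
print(f"dG(37 C) = {est.dG37:.2f} kJ/mol "
      f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f})")

# ThT kinetics halftime
tht = aggkin.SigmoidalFit(y_i=1.0, m_i=0.01, y_f=8.0, m_f=0.02, t50=12.0, k=1.5)
trace = synthgen.gen_tht_trace(tht, np.linspace(0, 40, 200), noise_sd=0.1, seed=11)
fit = aggkin.fit_sigmoid(trace)
print(f"ThT halftime t50 = {fit.t50:.2f} h")
```

Output:

```
edge test: U=5229, one-tailed p=5.15e-05
dG(37 C) = 20.28 kJ/mol (95% CI 20.25-20.31)
ThT halftime t50 = 11.96 h
```

The edge test says that cleavage scores next to the observed fragment
termini are far larger than elsewhere in the sequence — the fragments are
consistent with cathepsin proteolysis.  The fitted dG(37 °C) recovers the
planted stability (20.25 kJ/mol) within its interval, and the kinetics
fit recovers the planted 12 h halftime.

A thin CLI mirrors these stages: `thagg simulate`, `thagg edge-test`,
`thagg dsf`, `thagg foldfit`, `thagg tht-fit`, `thagg correlate`.

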