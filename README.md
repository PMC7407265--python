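# dropquant

Drop-off droplet digital PCR (ddPCR) simulation, Poisson quantification and
mutation-calling toolkit for IDH2 hotspot assays (R140, R172) in acute
myeloid leukemia.

A drop-off ddPCR assay partitions ~16 ng of template DNA into ~20,000
nanolitre droplets and reads two fluorescence channels per droplet: a FAM
reference probe that binds an invariant site in the amplicon (fires on any
template) and a HEX probe that binds the wild-type hotspot sequence. Any
substitution at the hotspot abolishes HEX binding, so wild-type droplets are
double-positive while mutant droplets are FAM-only — one reaction detects
every mutation at the codon. `dropquant` provides the computational half of
such an assay, for assay developers and molecular-diagnostics analysts:

- **simulate** — synthetic droplet amplitude data with known ground truth:
  multinomial partitioning of template copies (exactly conserved), Gaussian
  amplitude clusters per population, optional "rain", dilution series with
  reproducible per-well RNG substreams;
- **classify** — per-channel 1-D two-means thresholding and quadrant
  assignment of droplets to populations (negative / double-positive /
  FAM-only / anomalous HEX-only), with well-level QC;
- **quantify** — Poisson-corrected rates λ = −ln(n_neg/n_total), template
  concentration, and the mutant allele fraction

      MAF = 100 · (λ_total − λ_wt) / λ_total  [%]

  where λ_total comes from FAM-negative droplets and λ_wt from HEX-negative
  droplets; the subtraction corrects for droplets co-containing mutant and
  wild-type template. Limits of blank and detection from dilution series;
- **arms** — the reference method's ΔΔCt calling rules (mutated when
  ΔΔCt > 4, wild-type when ΔΔCt < 3 or Ct_mut > 37, borderline between);
- **concordance** — 2×2 agreement between calling methods (observed
  concordance, Cohen's kappa), cohort prevalences, and a configurable
  trajectory-vs-clinic concordance rule for minimal-residual-disease series.

## Worked example

Simulate one well at 5% mutant fraction (16 ng input → 4848 template
copies), classify its droplets and quantify:

```bash
$ dropquant simulate -f 0.05 --seed 42 --out amplitudes.csv
wrote 20000 droplets (1 wells) to amplitudes.csv
$ dropquant classify amplitudes.csv --out classified.csv
classified 1 wells -> classified.csv
$ dropquant quantify classified.csv --out quantified.csv
```

`classified.csv` reports the droplet populations and fitted thresholds:

```
well_id,n_total,n_negative,n_double_positive,n_fam_only,n_hex_only,ch1_cut,ch2_cut,qc_pass,...
f0.05_r000,20000,15696,4113,191,0,4498.8,5002.5,True
```

15,696 of 20,000 droplets stayed empty, 4,113 are double-positive
(wild-type template) and 191 are FAM-only (mutant template). Quantification
turns those counts into rates and the allele burden:

```
well_id     lam_total  lam_wt   lam_mut  concentration_copies_per_ul  maf_pct  maf_ci_low  maf_ci_high  detected
f0.05_r000  0.2423     0.2302   0.0121   285.1                        4.99     0.92        9.06         True
```

λ_total ≈ 0.242 copies/droplet (≈ 285 copies/µL at 0.85 nL per droplet) and
the estimated mutant allele fraction is 4.99% (95% CI 0.9–9.1%), recovering
the simulated 5% ground truth. The same library functions are importable
directly (`dropquant.simulate_well`, `classify_well`, `dropoff_maf`, …).

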