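# mitofoci

Subcellular analysis of respiratory-chain–deficient foci in human skeletal
muscle fibers.

In mitochondrial DNA (mtDNA) maintenance disorders and in normal ageing,
individual muscle fibers can harbour small, circumscribed regions that have
lost cytochrome c oxidase (COX, complex IV) activity while succinate
dehydrogenase (SDH, complex II — entirely nuclear-encoded) is preserved or
elevated. These *COX-deficient foci* sit in the subsarcolemmal space, and a
central question is whether they arise preferentially next to myonuclei,
as expected if clonal expansion of a mutant mtDNA species is seeded in the
perinuclear compartment. This package provides the quantitative machinery
to ask that question, for anyone analysing multi-channel immunofluorescence
of muscle sections (DAPI / SDHA / MTCOI) together with single-cell triplex
qPCR of laser-microdissected regions:

* **Perimeter profiling** — background-corrected intensity profiles of each
  channel along a fiber's boundary polygon, averaged over an inward
  subsarcolemmal band, plus straight-line "plot profile" transects.
* **Domain annotation** — perinuclear perimeter domains called where
  corrected DAPI exceeds the cohort 0.85 quantile; focal COX deficiency
  from manual interval annotations or an automated MTCOI/SDHA-ratio
  surrogate; whole-fiber classification and cohort prevalence summaries.
* **Overlap statistic** — per fiber, the perimeter fractions perinuclear
  (P), focal (F), and observed overlap (O_obs), against the independence
  null O_pred = P × F (the multiplication rule for independent events); a
  one-tailed one-sample t test on O_pred − O_obs across the cohort.
* **qPCR quantification** — per-region mtDNA copy numbers from a
  D-Loop/ND1/ND4 triplex assay via a log-linear plasmid standard curve
  (Cq = intercept + slope·log₁₀ copies), the major-arc deletion level
  (1 − ND4/ND1) × 100 clipped to [0, 100], and the assay's QC gates:
  95–100% standard-curve efficiency, every region of a fiber ≥ 3 Cq below
  the no-template control for ND1, and a D-Loop/ND1 ratio check.
* **Synthetic data** — a generator of fiber sections (perturbed-ellipse
  polygons, perimeter nuclei, foci with 3.3-fold SDHA elevation and 10×
  MTCOI attenuation, tunable perinuclear enrichment) and of qPCR plates
  with known ground truth, so the whole pipeline is testable end to end.

## Worked example

Simulate a cohort of 74 fibers in which every focus is centered on a
nucleus (full perinuclear enrichment), then run profiling → annotation →
overlap test:

```python
from mitofoci.synthetic import CohortSimParams, simulate_cohort
from mitofoci.pipeline import analyze_sections

sections, truth = simulate_cohort(
    CohortSimParams(n_fibers=74, enrichment_rho=1.0, seed=1)
)
out = analyze_sections(sections)
r = out.result
print(f"fibers: {r.n_fibers}, foci: {r.n_foci}, "
      f"overlapping a perinuclear run: {r.n_foci_overlapping}")
print(f"P = {out.aggregates['weighted_P']:.3f}, "
      f"F = {out.aggregates['weighted_F']:.3f}, "
      f"O = {out.aggregates['weighted_O']:.3f}")
print(f"mean(O_pred - O_obs) = {r.mean_diff:.4f}, "
      f"t = {r.t:.2f}, one-tailed p = {r.p:.2e}")
```

prints

```
fibers: 74, foci: 74, overlapping a perinuclear run: 74
P = 0.150, F = 0.201, O = 0.069
mean(O_pred - O_obs) = -0.0384, t = -14.40, one-tailed p = 2.48e-23
```

Every simulated focus touches a detected perinuclear run; the observed
overlap fraction O (6.9% of perimeter) far exceeds the ≈3% predicted by
P × F under independence, so the one-tailed test rejects decisively. With
`enrichment_rho=0` (foci placed uniformly) the same pipeline returns p
values uniform-ish on [0, 1], rejecting at the nominal 5% rate.

The same composition is available from the shell:

```sh
mitofoci simulate --seed 1 --n-fibers 74 --outdir cohort/
mitofoci run --indir cohort/ --outdir results/
mitofoci report results/
```

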