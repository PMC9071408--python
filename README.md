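# epimark

Marker-modification quality control and profiling for LC–MS/MS RNA
modification data, with a synthetic degradome generator.

## The problem

Quantifying the epitranscriptome of a small-RNA preparation by
nucleoside-resolved LC–MS/MS is only as trustworthy as the RNA behind it.
After cell death — and during isolation — rRNA is cleaved into fragments
that co-migrate with tRNA in a gel, so rRNA-borne modifications leak into
tRNA-size fractions and masquerade as small-RNA chemistry.  Because some
modifications are (near-)exclusive to one RNA class, they can be turned
into tracers of this contamination:

* **m⁶,⁶A** — essentially exclusive to 18S (small-subunit) rRNA;
* **Am** — a ribose methylation absent from tRNA;
* **m³U** — characteristic of 28S rRNA (tracked, but it follows its own
  degradation path);
* **ms²i⁶A** — a mitochondrial tRNA marker.

`epimark` implements, as a tested and scriptable pipeline, the workflow
that exploits these markers: dynamic-MRM peak quantification with
stable-isotope internal-standard (SILIS) normalization, a degradation
index over the rRNA markers in the tRNA-size fraction with a keep/exclude
verdict per sample, and unsupervised profiling (hierarchical clustering,
k-means, PCA, Welch tests) of the validated samples.  A synthetic
degradome generator emulates post-mortem fragmentation kinetics with full
ground truth, so every stage of the chain is testable end to end.

## The quantification ladder

For each modification *m* in sample *s* with light/heavy peak areas
`A12`, `A13`, canonical UV areas `U_C, U_U, U_G, U_A` and internal
standard mass `M = 50 ng` with per-ng UV response `r`:

1. SILIS ratio: `R(m,s) = A12 / A13` (raw `A12` when *m* has no heavy
   channel);
2. UV normalization: `V(m,s) = R(m,s) / (mean(U_C,U_U,U_G,U_A) − r·M)`;
3. mean scaling: `Z(m,s) = V(m,s) / mean_s' V(m,s')` (row means become 1);
4. absolute branch: `ng(m,s) = (R − b) / a` through an external
   calibration line `R = a·ng + b`, reported as % of the adenosine UV
   signal, with below-detection and beyond-calibration-range flags.

The degradation index of a tRNA-fraction sample is the geometric mean of
the m⁶,⁶A and Am fold changes over a pristine baseline (the mean of the
0 h, unfrozen preparations); samples with index > 2 (configurable) are
excluded from profiling.  A modification enters heatmaps/PCA only if its
signal-to-noise reaches 5 in at least one compared sample.

## Worked example

Simulate the post-mortem liver/brain study (0, 1, 8, 24 h; four
replicates; tRNA and RF gel windows), quantify it, and score degradation:

```python
import numpy as np
from epimark import iodata, pipeline, qc_markers, quantify, synth_degradome

table = iodata.load_table1()          # packaged 27-modification MRM panel
sim = synth_degradome.simulate_study(
    synth_degradome.default_config("postmortem", seed=1), table=table)
matrices = pipeline.quantify_stage(sim.peaks, sim.uv, sim.meta, table,
                                   quantify.ISTDSpec())
trna = matrices["tRNA"]

pristine = [s for s in trna.samples
            if sim.meta[s].time_postmortem == 0 and not sim.meta[s].frozen]
baseline = trna.values[pristine].mean(axis=1).to_dict()
for t in (0.0, 1.0, 8.0, 24.0):
    group = [s for s in trna.samples
             if sim.meta[s].tissue == "liver" and sim.meta[s].frozen
             and sim.meta[s].time_postmortem == t]
    idx = [qc_markers.degradation_index(trna.values[s].to_dict(), baseline)
           for s in group]
    print(f"liver {t:>4g} h  degradation index "
          f"{np.mean(idx):7.2f} +/- {np.std(idx):.2f}")

liver = [s for s in trna.samples
         if sim.meta[s].tissue == "liver" and sim.meta[s].frozen]
sub = iodata.NormalizedMatrix(trna.values[liver], trna.stage)
print(f"r(m6,6A, Am) across the liver time course: "
      f"{qc_markers.marker_covariation(sub):.3f}")

reports = qc_markers.qc_cohort(trna, pristine, threshold=2.0)
n_bad = sum(r.verdict == "degraded" for r in reports)
print(f"QC verdicts: {n_bad}/{len(reports)} tRNA-fraction samples degraded")
```

prints

```
liver    0 h  degradation index    1.40 +/- 0.09
liver    1 h  degradation index    2.88 +/- 0.19
liver    8 h  degradation index   21.48 +/- 1.20
liver   24 h  degradation index   99.08 +/- 4.55
r(m6,6A, Am) across the liver time course: 0.971
QC verdicts: 13/40 tRNA-fraction samples degraded
```

Read: rRNA markers flood the liver tRNA window within one hour of death
(index 2.9 ≳ the 2-fold cutoff) and grow ~100-fold by 24 h; the two
markers co-vary tightly (r = 0.97), which is what licenses their joint
use; the flagged samples are the frozen liver 1/8/24 h preparations plus
the latest brain ones, while 0 h material passes.

The same chain is available from the shell:

```sh
epimark run --scenario postmortem --seed 1 --out demo_run
epimark profile --matrix demo_run/matrix_tRNA_uv_normalized.tsv --out demo_profile
```

which writes per-fraction matrices, the QC report (TSV + JSON), cluster
trees, PCA scores/loadings and a `run_report.json` with every parameter
and exclusion.  Reruns with the same seed are bit-identical.

## Packaged reference data

* `epimark.load_table1()` — the 27-modification dynamic-MRM acquisition
  panel (precursor/product m/z, voltages, retention times, light and
  heavy channels).
* `epimark.load_table2()` — a 17-modification × 9-sample absolute
  quantification reference (% of adenosine UV signal) across tRNA, 18S,
  28S, mRNA and total-RNA preparations, with below-detection and
  beyond-calibration flags.  Its column clustering reproduces the
  expected class structure (tRNA replicates | rRNA-containing samples |
  mRNA) and seeds the simulator's per-species modification densities.

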