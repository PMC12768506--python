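# mrsifp

Unsupervised metabolic fingerprinting of glioma subtypes from 3D MR
spectroscopic imaging (MRSI).

Gliomas are classified molecularly — IDH-mutant astrocytoma (AC),
IDH-mutant oligodendroglioma (OG), IDH-wildtype glioblastoma (GBM) — and
their metabolism differs measurably in vivo: mutant-IDH tumors produce
the oncometabolite 2-hydroxyglutarate (2HG), and all gliomas show raised
choline and depleted NAA. `mrsifp` implements a pipeline that separates
these subtypes from voxel-wise MR spectra **without** prior-knowledge
spectral fitting of the tumor content, for researchers working on
non-invasive glioma characterization:

1. **Quality control** — voxels kept iff FWHM < 0.15 ppm, SNR > 3 and
   CRLB < 20 %; baseline-artifact flagging at μ + 2.5σ.
2. **Metabolic indices** — tumor voxels selected by
   HGI = ([2HG] + [Gln]) / [Glu] > 1.5 (mutant-IDH patients) or
   CNR = [tCho]/[tNAA] > 0.4 (wildtype patients).
3. **G-NMU spectral decomposition** — the pooled tumor spectra matrix
   X (m points × n voxels) is factorized as X ≈ WH with W, H ≥ 0 under
   the element-wise *underapproximation* constraint WH ≤ X, which yields
   sparse, additive metabolic source spectra; contributions are
   quantified per voxel by non-negative least squares and projected onto
   healthy tissue.
4. **Classification** — leave-one-patient-out UMAP embedding of the
   source contributions, K-means (K = 3) with Hungarian cluster-subtype
   mapping, bootstrap CIs, one-vs-rest ROC/AUC, linear feature
   importance.
5. **Fingerprints** — per patient and source,
   z = (mean tumor − mean healthy)/SD healthy; UPGMA hierarchical
   clustering of the z-matrix with inter-group distances, intra-group
   variance and Shannon entropy.
6. **Statistics** — Kruskal-Wallis, Welch's t, Mann-Whitney U, Levene,
   Pearson, Cohen's d on patient-level observations.

Because no public MRSI cohort accompanies the method, the package ships a
first-class synthetic cohort generator (`mrsifp.synthetic`) that emulates
the cohort structure the analysis assumes — 12 patients (5 AC / 5 OG /
2 GBM), Lorentzian line spectra on a ppm axis, subtype-specific
concentration profiles, QC metadata — so the whole pipeline is testable
end to end. Real-data entry points accept tabular voxel data (TSV) and
write NIfTI metabolite maps. See `docs/methods.md` for models,
parameters and design decisions.

## Worked example

```python
import json
from mrsifp.pipeline import RunConfig, run_pipeline

run_pipeline(RunConfig(seed=1), "demo_run")
metrics = json.load(open("demo_run/metrics.json"))
print(f"accuracy: {metrics['accuracy_pct']:.2f}%")
print({k: round(v, 3) for k, v in metrics["per_class_auc"].items()})
print(f"tumor HGI median: {metrics['tumor_hgi_median']:.2f}")
```

prints, for the default 12-patient synthetic cohort:

```
accuracy: 99.54%
{'AC': 1.0, 'GBM': 1.0, 'OG': 1.0}
tumor HGI median: 2.11
```

i.e. 99.5 % of tumor voxels are assigned to the correct subtype by the
unsupervised embedding + clustering (the K-means clusters are mapped to
subtypes by optimal assignment, so this is label-permutation-invariant),
each subtype is perfectly ranked one-vs-rest at this seed, and the median
HGI over tumor voxels sits well above the 1.5 tumor-selection threshold.
`demo_run/` also contains the voxel table with per-voxel indices, region
labels, source contributions and embedding coordinates (`voxels.tsv`),
the source spectra (`sources_W.tsv`), their metabolite composition and
cluster-quality indices (`metrics.json`), the patient z-score
fingerprints (`fingerprints.tsv`), group statistics (`stats.tsv`) and a
run manifest with config hash and output checksums (`manifest.json`).

The same stages are scriptable from a shell:

```sh
mrsifp simulate --out sim --seed 42
mrsifp qc --in sim/voxels.tsv
mrsifp index --in sim/voxels.tsv --hgi-min 1.5 --cnr-min 0.4
mrsifp decompose --in sim/spectra.tsv --rank 7 --out sim/gnmu
mrsifp run --out full_run --seed 42     # everything at once
```

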