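# myofuse

Quantification of **myotube fusion** from two-channel fluorescence microscopy.

During myogenic differentiation, mononucleated myoblasts fuse into
multinucleated myotubes. The standard imaging readout scores fields stained
with DAPI (nuclei) and embryonic myosin heavy chain, eMHC (differentiated
cytoplasm): nuclei are segmented from the DAPI channel, assigned to
myotube regions of interest drawn on the eMHC channel, and summarised as

* **nuclei density** — total nuclei per mm² of imaged surface,
* **differentiation index** — `DI = N(nuclei in eMHC⁺ cells) / N(total nuclei)`,
* **nuclei-per-myotube distribution** — the multiset of nucleus counts over
  eMHC⁺ regions with ≥ 2 nuclei, summarised by its median, log₂(median), and
  the fractions of myotubes with 2–14, 15–49 and ≥ 50 nuclei,

compared between conditions with Student's pooled-variance *t*-test (counts,
index) or the two-sided Wilcoxon rank-sum test (the skewed fusion
distributions; exact by full enumeration when n ≤ 12).

`myofuse` implements that analysis as a tested, reusable pipeline —
rolling-ball background subtraction (grayscale opening by a ball structuring
element), Otsu thresholding, binary cleanup, connected-component particle
analysis, even-odd point-in-polygon ROI assignment — plus two companions:

* a **synthetic-data module** that generates ground-truth scenes
  (multinucleated myotubes with controllable nuclei-count distributions,
  mono-nucleated cells, blur, noise) and renders them to two-channel TIFFs, so
  every stage can be scored against known truth without any external data;
* a **differential-expression classifier** for the downstream transcriptomic
  question: given per-gene statistics from two knockdown contrasts, apply
  Benjamini–Hochberg FDR correction, keep genes with |log₂FC| ≥ 0.8
  (a 1.74-fold change) and adjusted p ≤ 0.05, and classify genes significant
  in both contrasts into joint-direction quadrants — the down-in-A/up-in-B
  quadrant being the opposing-regulation candidate set.

## Worked example

```python
from myofuse import (SceneParams, RenderParams, generate_scene, render_scene,
                     segment_nuclei, roi_set_from_scene, build_fusion_report,
                     compare_groups)

scene = generate_scene(SceneParams(seed=11))      # ground truth: 87 nuclei
stack = render_scene(scene, RenderParams(seed=11))  # blur + 5% Gaussian noise
nuclei = segment_nuclei(stack)
report = build_fusion_report(nuclei, roi_set_from_scene(scene))
print(report.total_nuclei)                # 87   (exactly the planted count)
print(round(report.nuclei_density_per_mm2, 1))   # 8297.0
print(round(report.differentiation_index, 3))    # 0.632
print(report.myotube_counts)              # [2, 2, 3, 5, 9, 26]
print(report.median_nuclei_per_myotube)   # 4.0  -> log2(median) = 2.0
print(report.bin_fractions)               # {'2-14': 0.833, '15-49': 0.167, '50+': 0.0}

cmp = compare_groups([2, 3, 4, 4, 11, 16], [5, 9, 15, 18, 22, 31],
                     "wilcoxon_rank_sum")
print(cmp.statistic, round(cmp.p_value, 4))      # 26.0 0.0368 (exact, n<=12)
```

The detected count, per-myotube counts and differentiation index all equal
the simulator's planted ground truth; under the default noise they stay
within ≥ 95 % recall/precision at 1.5 px matching distance.

## Command line

```bash
myofuse simulate --config scene.yaml --out field_dir/ --seed 1
myofuse simulate-deg --out deg_dir/ --seed 1
myofuse segment --image field_dir/field.tif --out nuclei.csv
myofuse quantify --manifest fields.csv --out reports/
myofuse deg-opposing --a contrast_a.csv --b contrast_b.csv --out classified/
myofuse run-all --config examples/run_small.yaml --out run/ --seed 1
```

`run-all` chains simulate → segment → quantify → deg-opposing for a YAML
config of conditions, writes per-field reports, a comparisons table, the DE
classification, and a provenance record; reruns with the same config and seed
are byte-identical.

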