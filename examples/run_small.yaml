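# Small end-to-end demonstration: two conditions x 3 simulated fields each,
# plus one synthetic two-contrast DE pair. Runs in well under a minute.
seed: 1
conditions:
  control:
    n_fields: 3
    scene:
      n_myotubes: 5
      n_mononucleated: 30
      nuclei_per_myotube_sampler: {kind: geometric_shifted, mean: 5.0}
  enhanced_fusion:
    n_fields: 3
    scene:
      n_myotubes: 5
      n_mononucleated: 30
      nuclei_per_myotube_sampler: {kind: geometric_shifted, mean: 15.0}
render: {}          # defaults: blur sigma 1 px, Gaussian noise 5% of peak
segmentation: {}    # defaults: rolling ball 50 px, Otsu, min area 20 px^2
deg: {}             # defaults: 1000 genes, 98 shared / 46 opposing planted
thresholds: {}      # defaults: |log2FC| >= 0.8, padj <= 0.05
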