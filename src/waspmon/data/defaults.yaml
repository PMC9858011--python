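# Default pipeline configuration mirroring the cold-storage study protocol:
# first-overtone window 1300-1600 nm, SG(11,2)+SNV before difference spectra,
# day-1 reference, up to 30 PCs for PCA-LDA chosen by threefold CV, detrended
# spectra for PLS, SG(17,2)+SNV before aquagrams.
simulate:
  seed: 20230258
zones: [inner, outer]
range: [1300, 1600]
reference_day: 1
diffspec:
  pretreat: ["savgol(11,2)", "snv"]
  min_rel_magnitude: 0.10
pca:
  k: 10
  inspect_component:
    inner: 6
    outer: 7
  outlier_alpha: 0.01
lda:
  pretreat:
    inner: []            # raw spectra work best for the protected inner leaves
    outer: ["detrend(2)"]
  max_pcs: 30
  folds: 3
pls:
  pretreat: ["detrend(2)"]
  max_lv: 12
wamac:
  min_sources: 2
  require_both_zones: true
aquagram:
  pretreat: ["savgol(17,2)", "snv"]
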