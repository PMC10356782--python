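"""Classify marker positivity per nucleus with a two-component GMM.

Marker channels are normalized to zero mean / unit variance, a
two-component Gaussian mixture separates background from positive pixels,
and calls are made per nucleus from the mean positive-class probability
plus the fraction of nucleus pixels above threshold (the overlap filter
that removes debris and artefacts).
"""

from mxif3d.benchmarks import classification_benchmark

result = classification_benchmark(seed=7, n_cells=500,
                                  positive_fraction=0.4, marker_snr=6.0)
print(f"cells called: {result.n_cells} "
      f"({result.n_truth_positive} truth-positive)")
print(f"accuracy    {100 * result.accuracy:5.1f} %")
print(f"sensitivity {100 * result.sensitivity:5.1f} %  "
      "(fraction of truth-positive nuclei called positive)")
print(f"specificity {100 * result.specificity:5.1f} %  "
      "(fraction of truth-negative nuclei called negative)")
print("At a signal-to-noise ratio of 6 the mixture components are well "
      "separated, so calls should exceed 90% on all three metrics.")
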