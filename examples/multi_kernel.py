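"""Combining kernels by orthogonal feature-map concatenation.

Concatenating the feature maps of several kernels makes the combined
Gram the elementwise sum of the component Grams. The script fits the
classifier with a single rbf kernel and with an rbf + Laplacian +
inverse-distance combination, printing unlabeled accuracy for each.
"""

import pcper
from pcper.kernels import parse_kernel_spec

spec = pcper.SyntheticSpec(M=3, n_per_class=60, d=4, separation=6.0,
                           noise_sd=0.3, n_labeled_total=9, seed=2)
X, labels, truth, _ = pcper.make_problem(spec)
unl = labels.unlabeled_idx

for kspec in ("rbf", "laplacian", "rbf+laplacian+inverse_distance"):
    cfg = parse_kernel_spec(kspec)
    model = pcper.fit(X, labels, kernel=cfg)
    acc = (pcper.predict(model)[unl] == truth[unl]).mean()
    print(f"{kspec:32s} unlabeled accuracy: {acc:.3f}")
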