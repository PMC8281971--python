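"""How the LWM-consistency weight trades agreement between predictors.

The classifier offers two predictors — the decision function f(x) and
the membership function w(x) — whose agreement diagnoses reliability.
With lambda_s = 0 they agree on every instance (the membership is a
monotone transform of the decision values); as lambda_s grows, instances
whose point and local weighted mean fall on different sides of a boundary
become fake-consistent and eventually inconsistent, and the prediction
consistency rate decays toward the ground-truth (intrinsic) rate.
"""

import pcper
from pcper.core import Hyperparams

spec = pcper.SyntheticSpec(M=3, n_per_class=60, d=2, separation=6.0,
                           noise_sd=1.0, n_labeled_total=10, seed=1)
X, labels, *_ = pcper.make_problem(spec)

print(f"{'lambda_s':>9} {'prediction':>11} {'ground-truth':>13}  categories")
for lam_s in [0.0, 0.001, 0.01, 0.1, 1.0, 10.0, 100.0]:
    model = pcper.fit(X, labels, Hyperparams(lambda_s=lam_s))
    rep = pcper.classify_consistency(model)
    print(f"{lam_s:>9g} {rep.prediction_consistency_rate:>11.4f} "
          f"{rep.ground_truth_consistency_rate:>13.4f}  {rep.counts}")
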