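"""Fit the possibilistic classifier on a scarce-label cluster problem.

Generates three Gaussian classes with only two labels each, fits the
semi-supervised model, and prints the accuracy on the unlabeled pool for
both predictors (decision function and membership function). On this
well-separated problem both should recover essentially all labels from
six labeled points.
"""

import numpy as np

import pcper

spec = pcper.SyntheticSpec(
    M=3, n_per_class=50, d=2, separation=8.0, noise_sd=0.2,
    n_labeled_per_class=2, n_labeled_total=None, seed=0,
)
X, labels, truth, _ = pcper.make_problem(spec)
print(pcper.split_report(labels))

model = pcper.fit(X, labels)
print(f"converged after {len(model.objective_trace)} alternations; "
      f"objective trace: {[round(v, 2) for v in model.objective_trace]}")

unl = labels.unlabeled_idx
for by in ("decision", "membership"):
    acc = (pcper.predict(model, by=by)[unl] == truth[unl]).mean()
    print(f"unlabeled accuracy by {by} function: {acc:.3f}")

# memberships are per-class degrees of belonging in (0, 1]; they need not
# sum to one, and confident instances approach 1 in exactly one class
W = pcper.membership_values(model)[unl]
print(f"mean max-membership of unlabeled instances: {W.max(axis=1).mean():.3f}")
print(f"mean runner-up membership:                  "
      f"{np.sort(W, axis=1)[:, -2].mean():.3f}")
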