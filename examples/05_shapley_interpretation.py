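"""Shapley attribution: exact coalition enumeration on a known model.

For an additive (linear) decision function the Shapley value has a closed
form, phi_j = w_j (x_j - E[x_j]); the exact enumerator must reproduce it,
and a fitted classifier must satisfy local accuracy (base value + sum of
attributions = model output per subject).
"""

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from soleposture import shapley_values


class Linear:
    def __init__(self, w):
        self.w = np.asarray(w, float)

    def decision_function(self, X):
        return np.asarray(X) @ self.w


rng = np.random.default_rng(0)
X = pd.DataFrame(rng.normal(size=(5, 2)), columns=["x1", "x2"])
bg = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x1", "x2"])

res = shapley_values(Linear([2.0, 3.0]), X, bg)
closed = 2.0 * (X["x1"] - bg["x1"].mean())
print("phi(x1), exact enumeration :", np.round(res.values["x1"].to_numpy(), 4))
print("phi(x1), closed form       :", np.round(closed.to_numpy(), 4))

Xtr = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
ytr = (Xtr["a"] + Xtr["c"] > 0).astype(int)
model = LogisticRegression().fit(Xtr.to_numpy(), ytr)
res = shapley_values(model, Xtr.iloc[:5], Xtr)
gap = np.abs(
    res.base_value + res.values.sum(axis=1) - model.predict_proba(Xtr.iloc[:5])[:, 1]
).max()
print(f"local accuracy residual    : {gap:.2e}  (attributions sum to the output)")
print(f"top feature by mean |phi|  : {res.top_feature}")
# 'a' or 'c' must top the ranking: they are the only features the label uses.
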