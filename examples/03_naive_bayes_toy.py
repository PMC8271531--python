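"""Naive Bayes on a tiny categorical problem, with smoothing.

Shows the frequency-table mechanics: class priors from counts, Laplace-
smoothed per-class category probabilities, and what happens to a category
never seen in training (nonzero posterior with smoothing; a hard error
without it — the classic zero-probability failure).
"""

import numpy as np

from whalefs import naive_bayes as nb
from whalefs.exceptions import ZeroProbabilityError

X = np.array(
    [["sunny", "hot"], ["sunny", "mild"], ["rain", "mild"], ["rain", "cool"]],
    dtype=object,
)
y = np.array(["no", "no", "yes", "yes"])

model = nb.fit(X, y, ["categorical", "categorical"], smoothing=1.0)
print("classes:", model.classes.tolist())
print("priors: ", np.round(np.exp(model.log_priors), 3))

x = np.array(["rain", "hot"], dtype=object)
print("P(class | rain, hot):", np.round(nb.predict_proba(model, x), 4))
print("prediction:          ", nb.predict(model, x))

# 'snow' never occurred: smoothing assigns it a small nonzero likelihood
x_unseen = np.array(["snow", "mild"], dtype=object)
print("P(class | snow, mild):", np.round(nb.predict_proba(model, x_unseen), 4))

strict = nb.fit(X, y, ["categorical", "categorical"], smoothing=0.0)
try:
    nb.predict(strict, x_unseen)
except ZeroProbabilityError as exc:
    print("without smoothing:", exc)
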