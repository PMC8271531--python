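"""Independent brute-force oracles used by the tests.

These are deliberately written without reference to the library's internals:
exact-fraction Bayes enumeration for small categorical problems, and a
pairwise Mann-Whitney count for AUC.  They stay slow and obvious.
"""

from fractions import Fraction

import numpy as np


def brute_force_posteriors(train_rows, train_labels, x, smoothing=1):
    """Exact posterior fractions P(c|x) by direct enumeration.

    ``train_rows`` is a list of tuples of category values, ``x`` one such
    tuple.  Laplace-smoothed frequency tables with the training vocabulary
    per feature; returns (classes, posteriors) with posteriors as
    ``Fraction`` summing to 1.
    """
    classes = sorted(set(train_labels))
    n = len(train_labels)
    n_features = len(train_rows[0])
    vocab = [sorted({row[j] for row in train_rows}) for j in range(n_features)]
    joint = {}
    for c in classes:
        members = [row for row, lab in zip(train_rows, train_labels) if lab == c]
        prior = Fraction(len(members), n)
        like = Fraction(1)
        for j in range(n_features):
            count = sum(1 for row in members if row[j] == x[j])
            like *= Fraction(count + smoothing,
                             len(members) + smoothing * len(vocab[j]))
        joint[c] = prior * like
    total = sum(joint.values())
    return classes, [joint[c] / total for c in classes]


def brute_force_predict(train_rows, train_labels, x, smoothing=1):
    classes, post = brute_force_posteriors(train_rows, train_labels, x, smoothing)
    best = max(range(len(classes)), key=lambda i: (post[i], -i))
    return classes[best]


def mann_whitney_auc(scores, y, positive_label=1):
    """AUC as the probability a random positive outscores a random negative,
    ties counted half; O(n_pos * n_neg) pairwise count."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == positive_label]
    neg = scores[y != positive_label]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
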