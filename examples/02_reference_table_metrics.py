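"""Confusion-matrix arithmetic on the packaged reference matrices.

The four matrices summarize a WOA+NB pipeline's test predictions on four
public clinical/benchmark datasets.  Applying the standard rate formulas
reproduces the reported accuracy column exactly — a pure arithmetic
consistency check that needs no data download.
"""

from whalefs import (
    accuracy,
    percent,
    precision,
    recall,
    reference_confusion_matrices,
    sensitivity,
    specificity,
)

print(f"{'dataset':<26} {'acc%':>7} {'prec%':>7} {'rec%':>7} {'spec%':>7}")
for name, m in reference_confusion_matrices().items():
    print(
        f"{name:<26} {percent(accuracy(m)):>7} {percent(precision(m)):>7} "
        f"{percent(recall(m)):>7} {percent(specificity(m)):>7}"
    )
# accuracy column: 79.82 / 85.48 / 87.07 / 88.94 — the pipeline's reported
# accuracies; sensitivity is recall by definition, so it is not repeated.
m = reference_confusion_matrices()["Diabetes"]
assert sensitivity(m) == recall(m)
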