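"""Published operating points of five rectal-cancer nCRT response
models, used as worked-example inputs.

Reported per model and cohort are the sensitivity and specificity at
the training-cohort Youden threshold, together with the cohort
composition (training: 127 patients, 42 good responders; test: 54
patients, 18 good responders). Because sensitivity and specificity each
determine one row of the confusion table, the integer counts — and from
them accuracy, PPV, NPV and F1 — are fully reconstructible.
:func:`reconstruct_confusion` performs that reconstruction through the
package's own confusion-metric code.
"""

from __future__ import annotations

from .metrics import confusion_from_counts

TRAIN_POS, TRAIN_NEG = 42, 85  # 127 training cases
TEST_POS, TEST_NEG = 18, 36  # 54 test cases

#: (model, split) -> printed (sensitivity, specificity)
REFERENCE_OPERATING_POINTS: dict[tuple[str, str], tuple[float, float]] = {
    ("Clinic", "train"): (0.786, 0.718),
    ("Clinic", "test"): (0.722, 0.611),
    ("Habitat", "train"): (0.690, 0.835),
    ("Habitat", "test"): (0.389, 0.861),
    ("Radiomics", "train"): (0.905, 0.600),
    ("Radiomics", "test"): (0.611, 0.639),
    ("Clinic+Radiomics", "train"): (0.952, 0.835),
    ("Clinic+Radiomics", "test"): (0.389, 0.722),
    ("Clinic+Habitat", "train"): (0.952, 0.729),
    ("Clinic+Habitat", "test"): (0.556, 0.833),
}


def cohort_counts(split: str) -> tuple[int, int]:
    if split == "train":
        return TRAIN_POS, TRAIN_NEG
    if split == "test":
        return TEST_POS, TEST_NEG
    raise ValueError(f"unknown split {split!r}")


def reconstruct_confusion(model: str, split: str) -> dict[str, float]:
    """Derive the full metric row from printed sensitivity/specificity.

    TP = round(sensitivity * n_pos), TN = round(specificity * n_neg);
    the remaining cells follow from the cohort composition.
    """
    sens, spec = REFERENCE_OPERATING_POINTS[(model, split)]
    n_pos, n_neg = cohort_counts(split)
    tp = round(sens * n_pos)
    tn = round(spec * n_neg)
    return confusion_from_counts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
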