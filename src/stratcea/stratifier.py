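"""Classification arithmetic: test accuracy x prevalence -> routing fractions.

A "positive" test result means the patient is predicted to respond to a
second-line conventional antipsychotic (an AP2 responder) and is therefore
routed to that drug; a negative result routes the patient straight to
clozapine.  Sensitivity is defined against true AP2-responder status.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import StratifierAccuracy, ValidationError, _check_prob

__all__ = ["ClassificationFractions", "classify_cohort", "split_false_negatives"]


@dataclass(frozen=True)
class ClassificationFractions:
    """Population fractions of the four test-by-truth cells (sum to 1)."""

    tp: float  # AP2 responder, test positive
    fn: float  # AP2 responder, test negative
    tn: float  # non-AP2-responder, test negative
    fp: float  # non-AP2-responder, test positive

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            _check_prob(name, getattr(self, name))
        total = self.tp + self.fn + self.tn + self.fp
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"classification fractions must sum to 1, got {total!r}")

    @property
    def p_positive(self) -> float:
        return self.tp + self.fp

    @property
    def p_negative(self) -> float:
        return self.tn + self.fn


def classify_cohort(acc: StratifierAccuracy, p_ap2: float) -> ClassificationFractions:
    """Split the cohort into TP/FN/TN/FP fractions.

    tp = sens * p_ap2, fn = (1-sens) * p_ap2,
    tn = spec * (1-p_ap2), fp = (1-spec) * (1-p_ap2).
    """
    _check_prob("p_ap2", p_ap2)
    sens, spec = acc.sensitivity, acc.specificity
    return ClassificationFractions(
        tp=sens * p_ap2,
        fn=(1.0 - sens) * p_ap2,
        tn=spec * (1.0 - p_ap2),
        fp=(1.0 - spec) * (1.0 - p_ap2),
    )


def split_false_negatives(fn: float, p_fn_clz_response: float) -> tuple[float, float]:
    """Partition false negatives by their response to clozapine.

    False negatives are AP2 responders started on clozapine unnecessarily.
    A fraction ``p_fn_clz_response`` responds to clozapine and remains on it
    (``fn_on_clz``); the rest fail clozapine, and after one cycle are offered
    a second-line conventional antipsychotic, to which they respond
    (``fn_rerouted``).
    """
    _check_prob("fn", fn)
    _check_prob("p_fn_clz_response", p_fn_clz_response)
    return fn * p_fn_clz_response, fn * (1.0 - p_fn_clz_response)
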