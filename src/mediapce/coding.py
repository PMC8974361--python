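"""Document-level valence coding conventions and coder validation.

Implements the hand-coding eligibility rule for classifier training sets
(a text is usable only when a supermajority of crowd coders agree), the
re-assignment of the five-way coding scheme to two independent binary codes
(anti-or-not, pro-or-not), precision/recall validation against gold labels,
and the per-document contribution each record makes to a daily valence
series.
"""

from __future__ import annotations

import warnings

from .records import CODING_LABELS, MediaDocument

__all__ = [
    "filter_training_eligible",
    "binarize_valence",
    "precision_recall",
    "doc_valence_contribution",
    "UndefinedMetricWarning",
]


class UndefinedMetricWarning(UserWarning):
    """Raised as a warning when precision or recall has an empty denominator."""


def filter_training_eligible(
    docs: list[MediaDocument], agreement: float = 0.70
) -> list[tuple[MediaDocument, str]]:
    """Keep documents whose coders reached the agreement threshold.

    A document is training-eligible when the share of coder votes for its
    plurality label is at least ``agreement`` (ties at exactly the threshold
    are eligible).  A tie *between* plurality labels means no winning
    classification exists and the document is dropped.

    Returns
    -------
    list of (document, winning_label) pairs, in input order.
    """
    if not 0 < agreement <= 1:
        raise ValueError("agreement must be in (0, 1]")
    eligible: list[tuple[MediaDocument, str]] = []
    for doc in docs:
        votes = doc.coder_votes
        if not votes or sum(votes.values()) == 0:
            raise ValueError(f"document {doc.doc_id} has no coder votes")
        total = sum(votes.values())
        top = max(votes.values())
        winners = [lab for lab, n in votes.items() if n == top]
        if len(winners) > 1:
            continue  # tied plurality: no winning classification
        if top / total >= agreement:
            eligible.append((doc, winners[0]))
    return eligible


def binarize_valence(label: str) -> tuple[int, int]:
    """Map a five-way coding label to the (anti, pro) binary code pair.

    ``anti`` -> (1, 0); ``pro`` -> (0, 1); ``mixed`` carries both valences
    and maps to (1, 1); ``not_applicable`` and ``irrelevant`` -> (0, 0).
    """
    if label not in CODING_LABELS:
        raise ValueError(f"unknown coding label {label!r}")
    return {
        "anti": (1, 0),
        "pro": (0, 1),
        "mixed": (1, 1),
        "not_applicable": (0, 0),
        "irrelevant": (0, 0),
    }[label]


def precision_recall(predicted, gold) -> tuple[float, float]:
    """Precision and recall of binary ``predicted`` against binary ``gold``.

    P = TP/(TP+FP), R = TP/(TP+FN).  An empty denominator yields ``nan``
    with an :class:`UndefinedMetricWarning` rather than a silent zero, so
    degenerate validation sets cannot corrupt validity summaries.
    """
    predicted = [int(bool(v)) for v in predicted]
    gold = [int(bool(v)) for v in gold]
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold must have equal length")
    tp = sum(p and g for p, g in zip(predicted, gold))
    fp = sum(p and not g for p, g in zip(predicted, gold))
    fn = sum(g and not p for p, g in zip(predicted, gold))
    if tp + fp == 0:
        warnings.warn("no predicted positives: precision undefined", UndefinedMetricWarning)
        precision = float("nan")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no gold positives: recall undefined", UndefinedMetricWarning)
        recall = float("nan")
    else:
        recall = tp / (tp + fn)
    return precision, recall


def doc_valence_contribution(doc: MediaDocument) -> tuple[float, float]:
    """(anti, pro) contribution of one document to its day's series value.

    Long-form texts contribute their classifier probabilities, but only when
    tobacco is more than a passing mention (valence is not assessed on
    passing mentions, which contribute zero).  Tweets contribute their
    binary flags, so a day's tweet contributions sum to a count.  Videos are
    view-weighted by separate logic and are rejected here.
    """
    if doc.source_type == "youtube":
        raise ValueError(
            "youtube records are aggregated from view streams, not document counts"
        )
    if doc.source_type == "longform" and not doc.more_than_passing:
        return 0.0, 0.0
    return float(doc.p_anti), float(doc.p_pro)
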