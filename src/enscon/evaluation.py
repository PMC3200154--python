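"""Scoring predictions against a native structure.

Precision is the fraction of considered predictions matched by a true
contact; with a tolerance delta > 0 a prediction also counts as correct
when some true contact lies within +/- delta residues of both endpoints
(Chebyshev neighborhood).  Recall is exact-match only (delta = 0) and is
computed over the same truncated prediction list that precision uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from enscon.contacts import (
    Contact,
    ContactMap,
    Parameters,
    DEFAULT_PARAMS,
    contact_distance,
    extract_contacts,
)
from enscon.consensus import PredictionList
from enscon.errors import DataError
from enscon.structure_io import DomainDefinition, StructureModel

RangeClass = Literal["medium", "long", "both"]


@dataclass(frozen=True)
class EvaluationResult:
    """Precision/recall of one (range, delta) evaluation.

    ``defined`` is False when no predictions of the requested range existed;
    precision is then reported as 0.0 rather than undefined.
    """

    n_considered: int
    n_correct: int
    precision: float
    recall: float
    delta: int
    range_class: RangeClass
    n_true: int
    defined: bool = True


def true_contacts(
    native: StructureModel,
    domain: DomainDefinition,
    params: Parameters = DEFAULT_PARAMS,
) -> ContactMap:
    """Contacts of the experimental structure, restricted to the domain."""
    covered = [r for r in native.residues if r.index in domain]
    if len(covered) < 2:
        raise DataError(
            f"native {native.model_id} covers {len(covered)} domain residue(s); need >= 2"
        )
    cmap = extract_contacts(native, params)
    kept = frozenset(c for c in cmap.contacts if c.i in domain and c.j in domain)
    return ContactMap(source_id=native.model_id, contacts=kept)


def _ranges(range_class: RangeClass) -> set[str]:
    return {"medium", "long"} if range_class == "both" else {range_class}


def evaluate(
    pl: PredictionList,
    truth: ContactMap,
    delta: int = 0,
    range_class: RangeClass = "both",
) -> EvaluationResult:
    """Score a prediction list against true contacts.

    Each prediction of the requested range is judged independently: it is
    correct iff some true contact of that same range lies within
    ``contact_distance <= delta``.  One true contact may validate several
    nearby predictions.  Recall counts exact (delta = 0) matches among the
    considered predictions, divided by the number of true contacts of the
    range.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    wanted = _ranges(range_class)
    preds = [c for c, _ in pl.entries if c.range_class in wanted]
    true_set = {c for c in truth.contacts if c.range_class in wanted}

    n_considered = len(preds)
    if n_considered == 0:
        return EvaluationResult(
            n_considered=0, n_correct=0, precision=0.0,
            recall=0.0, delta=delta, range_class=range_class,
            n_true=len(true_set), defined=False,
        )

    if delta == 0:
        n_correct = sum(1 for p in preds if p in true_set)
    else:
        n_correct = sum(
            1 for p in preds if any(contact_distance(p, t) <= delta for t in true_set)
        )
    exact_hits = len(true_set & set(preds))
    recall = exact_hits / len(true_set) if true_set else 0.0
    return EvaluationResult(
        n_considered=n_considered,
        n_correct=n_correct,
        precision=n_correct / n_considered,
        recall=recall,
        delta=delta,
        range_class=range_class,
        n_true=len(true_set),
    )
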