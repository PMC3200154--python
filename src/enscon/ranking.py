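"""Ranking ensemble models by consensus-contact satisfaction.

A model is scored by four fractions: predicted medium-range contacts it
satisfies exactly, medium-range within 1 residue, long-range exactly, and
long-range within 1 residue.  The sum of the four (in [0, 4]) ranks the
models: a model that realizes the interactions most recurrent across the
ensemble scores highest.  Selection loss compares the quality (GDT-TS-like)
of the top-ranked model with the best model available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from enscon.consensus import ConsensusList, PredictionList, QualityTable
from enscon.contacts import Contact, ContactMap, Parameters, DEFAULT_PARAMS, extract_contacts
from enscon.errors import DataError
from enscon.structure_io import DomainDefinition, StructureModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelContactScore:
    model_id: str
    med_exact: float
    med_d1: float
    long_exact: float
    long_d1: float

    @property
    def total(self) -> float:
        return self.med_exact + self.med_d1 + self.long_exact + self.long_d1


def _satisfied_fractions(
    contact_set: frozenset[Contact], preds: Sequence[Contact]
) -> tuple[float, float]:
    """(exact fraction, within-1-residue fraction) of predictions satisfied."""
    if not preds:
        return 0.0, 0.0
    n_exact = 0
    n_d1 = 0
    for p in preds:
        if p in contact_set:
            n_exact += 1
            n_d1 += 1
            continue
        # Chebyshev ball of radius 1 around (i, j): 8 neighbors to probe.
        hit = False
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                i, j = p.i + di, p.j + dj
                if 1 <= i < j and Contact(i, j) in contact_set:
                    hit = True
                    break
            if hit:
                break
        if hit:
            n_d1 += 1
    return n_exact / len(preds), n_d1 / len(preds)


def satisfaction_score(
    model_map: ContactMap,
    med_preds: PredictionList,
    long_preds: PredictionList,
) -> ModelContactScore:
    """Score one model's contact map against medium/long prediction lists.

    An empty prediction list contributes 0 to both of its fractions (logged
    once at debug level, since it usually means the range had no consensus
    support).
    """
    med = med_preds.contacts()
    lng = long_preds.contacts()
    if not med:
        logger.debug("no medium-range predictions; medium fractions set to 0")
    if not lng:
        logger.debug("no long-range predictions; long fractions set to 0")
    med_exact, med_d1 = _satisfied_fractions(model_map.contacts, med)
    long_exact, long_d1 = _satisfied_fractions(model_map.contacts, lng)
    return ModelContactScore(
        model_id=model_map.source_id,
        med_exact=med_exact,
        med_d1=med_d1,
        long_exact=long_exact,
        long_d1=long_d1,
    )


def rank_models(
    models: Sequence[StructureModel],
    med_preds: PredictionList,
    long_preds: PredictionList,
    params: Parameters = DEFAULT_PARAMS,
) -> list[tuple[str, ModelContactScore]]:
    """Rank models by total satisfaction, descending; ties by model_id."""
    if not models:
        raise ValueError("need at least one model to rank")
    scores = []
    for model in models:
        cmap = extract_contacts(model, params)
        scores.append(satisfaction_score(cmap, med_preds, long_preds))
    scores.sort(key=lambda s: (-s.total, s.model_id))
    return [(s.model_id, s) for s in scores]


def ranking_prediction_sets(
    cl: ConsensusList,
    domain: DomainDefinition,
    target_id: str = "",
    long_policy: str = "top:L",
) -> tuple[PredictionList, PredictionList]:
    """Build the (medium, long) prediction lists the ranking scheme uses.

    Medium range: the top L entries (L = domain length).  Long range
    follows `long_policy`: "top:L" (default) keeps the L most frequent —
    the same depth as the medium list; "top:N" an explicit depth; "all"
    every long-range consensus entry; "min-count:k" every entry seen in at
    least k models.  Unbounded policies drag in weakly supported pairs
    that reward models for reproducing ensemble noise, so a bounded
    default ranks better in practice.
    """
    from enscon.consensus import filter_to_domain

    med = filter_to_domain(cl, domain, ranges={"medium"})
    lng = filter_to_domain(cl, domain, ranges={"long"})
    L = domain.length
    med_entries = tuple((e.contact, e.freq) for e in med.entries[:L])

    if long_policy == "all":
        kept = lng.entries
    elif long_policy.startswith("top:"):
        depth_text = long_policy.split(":", 1)[1]
        depth = L if depth_text.upper() == "L" else int(depth_text)
        kept = lng.entries[:depth]
    elif long_policy.startswith("min-count:"):
        k = int(long_policy.split(":", 1)[1])
        kept = tuple(e for e in lng.entries if e.count >= k)
    else:
        raise ValueError(f"unknown long_policy {long_policy!r}")
    long_entries = tuple((e.contact, e.freq) for e in kept)

    return (
        PredictionList(target_id=target_id, entries=med_entries, domain=domain),
        PredictionList(target_id=target_id, entries=long_entries, domain=domain),
    )


def selection_loss(ranking: Sequence[str], qt: QualityTable) -> float:
    """Quality of the best ranked model minus quality of the model ranked first."""
    if not ranking:
        raise ValueError("empty ranking")
    missing = [mid for mid in ranking if mid not in qt]
    if missing:
        raise DataError(f"models missing from quality table: {missing[:5]}")
    best = max(qt[mid] for mid in ranking)
    return best - qt[ranking[0]]


def random_baseline_loss(qt: QualityTable) -> float:
    """Loss of picking the middlemost model when sorted by true quality.

    For an even-sized table the lower median is used (deterministic).
    """
    if len(qt) == 0:
        raise ValueError("empty quality table")
    ranked = sorted(qt.items(), key=lambda kv: (-kv[1], kv[0]))
    median_score = ranked[len(ranked) // 2][1]
    return ranked[0][1] - median_score
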