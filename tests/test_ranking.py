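import numpy as np
import pytest

from enscon.contacts import Contact, ContactMap, contact_distance, extract_contacts
from enscon.consensus import PredictionList, QualityTable, build_consensus
from enscon.errors import DataError
from enscon.ranking import (
    ModelContactScore,
    random_baseline_loss,
    rank_models,
    ranking_prediction_sets,
    satisfaction_score,
    selection_loss,
)
from enscon.structure_io import parse_domain

from helpers import random_contact_set


def pl_from(contacts):
    return PredictionList(target_id="t", entries=tuple((c, 1.0) for c in contacts))


def cmap_from(contacts, source_id="m"):
    return ContactMap(source_id=source_id, contacts=frozenset(contacts))


MED = [Contact(1, 14), Contact(2, 20)]
LONG = [Contact(1, 31), Contact(5, 60)]


def test_full_satisfaction_totals_four():
    score = satisfaction_score(cmap_from(MED + LONG), pl_from(MED), pl_from(LONG))
    assert score.total == pytest.approx(4.0)


def test_no_contact_near_any_prediction_scores_zero():
    far = [Contact(50, 70), Contact(40, 55)]
    score = satisfaction_score(cmap_from(far), pl_from(MED), pl_from(LONG))
    assert score.total == 0.0


def test_delta_one_credit_without_exact_match():
    model = cmap_from([Contact(2, 15), Contact(2, 32)])  # 1 off each prediction
    score = satisfaction_score(model, pl_from([Contact(1, 14)]), pl_from([Contact(1, 31)]))
    assert score.med_exact == 0.0 and score.med_d1 == 1.0
    assert score.long_exact == 0.0 and score.long_d1 == 1.0


def test_fractions_match_brute_force_scan():
    rng = np.random.default_rng(9)
    for _ in range(30):
        model_contacts = random_contact_set(rng, 80)
        med = [c for c in random_contact_set(rng, 25) if c.range_class == "medium"]
        lng = [c for c in random_contact_set(rng, 25) if c.range_class == "long"]
        if not med or not lng:
            continue
        score = satisfaction_score(cmap_from(model_contacts), pl_from(med), pl_from(lng))
        def oracle(preds, delta):
            return sum(
                1 for p in preds
                if any(contact_distance(p, c) <= delta for c in model_contacts)
            ) / len(preds)
        assert score.med_exact == pytest.approx(oracle(med, 0))
        assert score.med_d1 == pytest.approx(oracle(med, 1))
        assert score.long_exact == pytest.approx(oracle(lng, 0))
        assert score.long_d1 == pytest.approx(oracle(lng, 1))
        assert score.med_d1 >= score.med_exact
        assert score.long_d1 >= score.long_exact
        assert 0.0 <= score.total <= 4.0


def test_empty_prediction_range_contributes_zero():
    score = satisfaction_score(cmap_from(MED), pl_from(MED), pl_from([]))
    assert score.long_exact == 0.0 and score.long_d1 == 0.0
    assert score.total == pytest.approx(2.0)


def test_rank_order_and_ties(frozen_ensemble):
    models, truth, _ = frozen_ensemble
    dom = parse_domain("1-80")
    med = pl_from(sorted(c for c in truth.contacts if c.range_class == "medium"))
    lng = pl_from(sorted(c for c in truth.contacts if c.range_class == "long"))
    ranking = rank_models(models, med, lng)
    totals = [s.total for _, s in ranking]
    assert totals == sorted(totals, reverse=True)
    for (id_a, a), (id_b, b) in zip(ranking, ranking[1:]):
        if a.total == b.total:
            assert id_a < id_b
    for _, s in ranking:
        assert s.med_d1 >= s.med_exact and s.long_d1 >= s.long_exact


def test_unperturbed_reference_ranks_first(bundle_ref, frozen_ensemble):
    models, truth, _ = frozen_ensemble
    med = pl_from(sorted(c for c in truth.contacts if c.range_class == "medium"))
    lng = pl_from(sorted(c for c in truth.contacts if c.range_class == "long"))
    ranking = rank_models(list(models) + [bundle_ref], med, lng)
    assert ranking[0][0] == bundle_ref.model_id
    assert ranking[0][1].total == pytest.approx(4.0)


def test_selection_loss_formula():
    qt = QualityTable({"a": 0.50, "b": 0.43})
    assert selection_loss(["b", "a"], qt) == pytest.approx(0.07)
    assert selection_loss(["a", "b"], qt) == 0.0
    with pytest.raises(DataError):
        selection_loss(["a", "zzz"], qt)


def test_random_baseline_uses_middlemost():
    assert random_baseline_loss(QualityTable({"a": 0.9, "b": 0.5, "c": 0.1})) == pytest.approx(0.4)
    assert random_baseline_loss(QualityTable({"a": 0.8})) == 0.0
    # even count: lower median
    qt = QualityTable({"a": 0.9, "b": 0.7, "c": 0.5, "d": 0.1})
    assert random_baseline_loss(qt) == pytest.approx(0.9 - 0.5)


def test_ranking_prediction_sets_policies(frozen_maps):
    dom = parse_domain("1-80")
    cl = build_consensus(frozen_maps)
    med, lng = ranking_prediction_sets(cl, dom, long_policy="top:L")
    assert len(med) <= dom.length and len(lng) <= dom.length
    assert all(c.range_class == "medium" for c in med.contacts())
    assert all(c.range_class == "long" for c in lng.contacts())
    _, lng_all = ranking_prediction_sets(cl, dom, long_policy="all")
    _, lng_k = ranking_prediction_sets(cl, dom, long_policy="min-count:10")
    assert len(lng_k) <= len(lng_all)
    with pytest.raises(ValueError):
        ranking_prediction_sets(cl, dom, long_policy="bogus")
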