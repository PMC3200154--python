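"""Clustering predicted contacts and measuring per-model cluster coverage.

Predicted long-range contacts that are close in sequence (Chebyshev distance
on ordered endpoint pairs <= 4 by default) are grouped by single linkage
into clusters of interacting regions.  Each cluster is summarized by the
member closest to the cluster's mean endpoint position, representatives far
from any true contact are discarded, and every ensemble model is then asked
how many of the surviving clusters it covers — a model covers a cluster when
it has a contact within the tolerance of the representative.  The resulting
histogram shows whether the consensus pools interactions scattered across
models or merely reflects interactions most models already share.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from enscon.contacts import Contact, ContactMap, contact_distance
from enscon.consensus import PredictionList


@dataclass(frozen=True)
class ContactCluster:
    """A single-linkage group of predicted contacts with its representative."""

    members: frozenset[Contact]
    representative: Contact

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster cannot be empty")
        if self.representative not in self.members:
            raise ValueError("representative must be a member")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CoverageReport:
    """Per-model coverage of truth-filtered cluster representatives."""

    representatives: tuple[Contact, ...]
    per_model: dict[str, int]
    histogram: dict[int, float]

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def cumulative(self) -> dict[int, float]:
        """Fraction of models covering at least k clusters, per k."""
        counts = sorted(self.histogram)
        return {
            k: sum(f for c, f in self.histogram.items() if c >= k) for k in counts
        }


def representative(members: Sequence[Contact] | frozenset[Contact]) -> Contact:
    """The member closest (L1) to the mean endpoint position of the cluster.

    The mean is taken per endpoint (mean of i's, mean of j's); ties are
    broken by (i, j) ascending.
    """
    members = sorted(members)
    if not members:
        raise ValueError("empty cluster")
    mean_i = float(np.mean([c.i for c in members]))
    mean_j = float(np.mean([c.j for c in members]))
    return min(members, key=lambda c: (abs(c.i - mean_i) + abs(c.j - mean_j), c.i, c.j))


def cluster_contacts(
    preds: PredictionList | Sequence[Contact], linkage: int = 4
) -> list[ContactCluster]:
    """Single-linkage clusters under contact_distance <= linkage.

    Two contacts whose endpoints both lie within `linkage` residues join the
    same cluster, and membership closes transitively.  Clusters are returned
    ordered by representative (i, j) ascending.
    """
    contacts = preds.contacts() if isinstance(preds, PredictionList) else list(preds)
    contacts = sorted(set(contacts))
    if not contacts:
        raise ValueError("no contacts to cluster")

    parent = list(range(len(contacts)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(contacts)):
        for b in range(a + 1, len(contacts)):
            if contact_distance(contacts[a], contacts[b]) <= linkage:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    groups: dict[int, list[Contact]] = {}
    for idx, c in enumerate(contacts):
        groups.setdefault(find(idx), []).append(c)
    clusters = [
        ContactCluster(members=frozenset(g), representative=representative(g))
        for g in groups.values()
    ]
    clusters.sort(key=lambda cl: (cl.representative.i, cl.representative.j))
    return clusters


def filter_representatives(
    reps: Sequence[Contact], truth: ContactMap, tol: int = 4
) -> list[Contact]:
    """Keep representatives within `tol` residues of some true contact."""
    if tol < 0:
        raise ValueError("tol must be non-negative")
    return [
        r for r in reps if any(contact_distance(r, t) <= tol for t in truth.contacts)
    ]


def cluster_coverage(
    maps: Sequence[ContactMap], reps: Sequence[Contact], tol: int = 4
) -> CoverageReport:
    """Count, per model, how many cluster representatives it covers.

    A representative is covered by a model when the model has a contact at
    contact_distance <= tol from it.  The histogram reports the fraction of
    models at each exact coverage count.
    """
    if not maps:
        raise ValueError("need at least one contact map")
    if not reps:
        raise ValueError("need at least one representative")
    per_model: dict[str, int] = {}
    for cmap in maps:
        covered = sum(
            1
            for r in reps
            if any(contact_distance(r, c) <= tol for c in cmap.contacts)
        )
        per_model[cmap.source_id] = covered
    counts = Counter(per_model.values())
    n = len(maps)
    histogram = {k: v / n for k, v in sorted(counts.items())}
    return CoverageReport(
        representatives=tuple(reps), per_model=per_model, histogram=histogram
    )


def coverage_analysis(
    preds: PredictionList | Sequence[Contact],
    truth: ContactMap,
    maps: Sequence[ContactMap],
    linkage: int = 4,
    tol: int = 4,
) -> tuple[list[ContactCluster], CoverageReport]:
    """Cluster predictions, truth-filter representatives, measure coverage."""
    clusters = cluster_contacts(preds, linkage=linkage)
    reps = filter_representatives([c.representative for c in clusters], truth, tol=tol)
    report = cluster_coverage(maps, reps, tol=tol)
    return clusters, report
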