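"""Contact definition, extraction and the shared sequence-proximity metric.

Two residues are in contact when their representative atoms (CB, CA for
glycine) are strictly closer than 8 A.  Contacts are classified by sequence
separation: medium range for 12-23 positions, long range for >= 24; anything
closer is short range and excluded from prediction output by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from enscon.structure_io import StructureModel

MEDIUM_LO = 12
MEDIUM_HI = 23
LONG_LO = 24


@dataclass(frozen=True)
class Parameters:
    """Tunable constants of the contact pipeline.

    distance_threshold : contact cutoff in Angstroms (strict <).
    medium_lo/medium_hi/long_lo : sequence-separation band edges.
    delta : +/- residue tolerance used in neighborhood evaluation.
    cluster_linkage : single-linkage radius (residues) for contact clustering.
    top_fraction : prediction depth as a fraction of domain length L.
    """

    distance_threshold: float = 8.0
    medium_lo: int = MEDIUM_LO
    medium_hi: int = MEDIUM_HI
    long_lo: int = LONG_LO
    delta: int = 0
    cluster_linkage: int = 4
    top_fraction: Fraction = Fraction(1, 5)

    def __post_init__(self) -> None:
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be positive")
        if not (self.medium_lo <= self.medium_hi < self.long_lo):
            raise ValueError("need medium_lo <= medium_hi < long_lo")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")


DEFAULT_PARAMS = Parameters()


def classify_range(i: int, j: int, params: Parameters = DEFAULT_PARAMS) -> str:
    """Classify the pair (i, j) by |j - i| into short / medium / long."""
    if i == j:
        raise ValueError("a residue cannot contact itself")
    sep = abs(j - i)
    if sep >= params.long_lo:
        return "long"
    if params.medium_lo <= sep <= params.medium_hi:
        return "medium"
    return "short"


@dataclass(frozen=True, order=True)
class Contact:
    """An unordered residue pair, stored with i < j."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if not (1 <= self.i < self.j):
            raise ValueError(f"need 1 <= i < j, got ({self.i}, {self.j})")

    @property
    def sep(self) -> int:
        return self.j - self.i

    @property
    def range_class(self) -> str:
        """Range class under the canonical band edges (12-23 / >=24)."""
        return classify_range(self.i, self.j)


def contact_distance(a: Contact, b: Contact) -> int:
    """Chebyshev distance between ordered contacts.

    max(|a.i - b.i|, |a.j - b.j|): both endpoints must lie within the
    tolerance for two contacts to count as neighbors, and distance 0 means
    equality.  This single metric backs delta-neighborhood evaluation,
    contact clustering and cluster coverage.
    """
    return max(abs(a.i - b.i), abs(a.j - b.j))


@dataclass(frozen=True)
class ContactMap:
    """The set of contacts extracted from one structure."""

    source_id: str
    contacts: frozenset[Contact]

    def __len__(self) -> int:
        return len(self.contacts)

    def __contains__(self, c: Contact) -> bool:
        return c in self.contacts

    def __iter__(self):
        return iter(self.contacts)

    def in_range(self, ranges: Iterable[str]) -> frozenset[Contact]:
        wanted = set(ranges)
        return frozenset(c for c in self.contacts if c.range_class in wanted)


def extract_contacts(model: StructureModel, params: Parameters = DEFAULT_PARAMS) -> ContactMap:
    """Extract all residue pairs closer than the distance threshold.

    Candidate pairs come from a k-d tree ball query; the threshold is then
    applied with a strict ``<`` so a pair at exactly 8.0 A is not a contact.
    All separations >= 1 are retained; range filtering happens downstream.
    """
    if len(model) < 2:
        raise ValueError(f"{model.model_id}: need at least 2 residues to extract contacts")
    coords = model.coords
    indices = model.indices
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=params.distance_threshold, output_type="ndarray")
    contacts = set()
    for a, b in pairs:
        if np.linalg.norm(coords[a] - coords[b]) < params.distance_threshold:
            i, j = int(indices[a]), int(indices[b])
            if i > j:
                i, j = j, i
            contacts.add(Contact(i, j))
    return ContactMap(source_id=model.model_id, contacts=frozenset(contacts))
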