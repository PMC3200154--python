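"""Pooling contacts across an ensemble: count, normalize, rank, filter, serialize.

The consensus pipeline mirrors how a structure-prediction pipeline would use
it: extract a contact map from every model, count each pair across all
models, divide by the ensemble size so scores become "fraction of models
containing the contact", sort by that frequency, restrict to the target
domain and the medium/long separation ranges, and keep the top L/5.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Literal, Sequence

from enscon.contacts import Contact, ContactMap, Parameters, DEFAULT_PARAMS
from enscon.errors import DataError, FormatError
from enscon.structure_io import DomainDefinition, StructureModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusEntry:
    contact: Contact
    count: int
    freq: float


@dataclass(frozen=True)
class ConsensusList:
    """Contacts pooled across an ensemble, sorted by frequency.

    freq = count / n_models, so a score of 0.6 reads "present in 60% of the
    ensemble".  Ties in frequency are broken by (i, j) ascending so output
    is deterministic.
    """

    entries: tuple[ConsensusEntry, ...]
    n_models: int

    def __post_init__(self) -> None:
        for e in self.entries:
            if not (1 <= e.count <= self.n_models):
                raise ValueError(f"count {e.count} outside [1, {self.n_models}]")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class PredictionList:
    """The ranked, truncated prediction set for one target domain."""

    target_id: str
    entries: tuple[tuple[Contact, float], ...]
    domain: DomainDefinition | None = None

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("prediction scores must be non-increasing")
        if self.domain is not None:
            for c, _ in self.entries:
                if c.i not in self.domain or c.j not in self.domain:
                    raise ValueError(f"contact ({c.i},{c.j}) outside domain {self.domain}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def contacts(self) -> list[Contact]:
        return [c for c, _ in self.entries]

    def in_range(self, ranges: Iterable[str]) -> "PredictionList":
        wanted = set(ranges)
        kept = tuple((c, s) for c, s in self.entries if c.range_class in wanted)
        return PredictionList(self.target_id, kept, self.domain)


class QualityTable:
    """model_id -> quality score (GDT-TS-like; scale declared by the producer).

    Scores may live on [0, 1] or [0, 100]; the table never rescales them, it
    only compares and subtracts, so either convention works as long as one
    table is self-consistent.
    """

    def __init__(self, scores: dict[str, float]):
        for mid, s in scores.items():
            if not math.isfinite(s):
                raise ValueError(f"non-finite score for {mid}")
        self._scores = dict(scores)

    def __getitem__(self, model_id: str) -> float:
        return self._scores[model_id]

    def __contains__(self, model_id: str) -> bool:
        return model_id in self._scores

    def __len__(self) -> int:
        return len(self._scores)

    def items(self):
        return self._scores.items()

    def max_score(self) -> float:
        return max(self._scores.values())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QualityTable":
        """Read a 2-column ``model_id<TAB>score`` table; '#' starts a comment."""
        scores: dict[str, float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: expected 'model_id score'")
                try:
                    scores[parts[0]] = float(parts[1])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad score {parts[1]!r}") from exc
        if not scores:
            raise FormatError(f"{path}: empty quality table")
        return cls(scores)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for mid in sorted(self._scores):
                fh.write(f"{mid}\t{self._scores[mid]:.6f}\n")


def build_consensus(
    maps: Sequence[ContactMap], params: Parameters = DEFAULT_PARAMS
) -> ConsensusList:
    """Count each contact across all maps and sort by normalized frequency.

    Every map contributes to the denominator regardless of which residues it
    resolves, so freq is "fraction of the whole ensemble".
    """
    if not maps:
        raise ValueError("need at least one contact map")
    tally: Counter[Contact] = Counter()
    for cmap in maps:
        tally.update(cmap.contacts)
    n = len(maps)
    entries = tuple(
        ConsensusEntry(contact=c, count=k, freq=k / n)
        for c, k in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0].i, kv[0].j))
    )
    return ConsensusList(entries=entries, n_models=n)


def filter_to_domain(
    cl: ConsensusList,
    domain: DomainDefinition,
    ranges: Iterable[str] = ("medium", "long"),
) -> ConsensusList:
    """Keep entries with both endpoints inside the domain and an allowed range."""
    wanted = set(ranges)
    kept = tuple(
        e
        for e in cl.entries
        if e.contact.i in domain and e.contact.j in domain and e.contact.range_class in wanted
    )
    return ConsensusList(entries=kept, n_models=cl.n_models)


def select_top(
    cl: ConsensusList,
    L: int,
    fraction: Fraction | float = Fraction(1, 5),
    target_id: str = "",
    domain: DomainDefinition | None = None,
) -> PredictionList:
    """Truncate the consensus to the top max(1, floor(L * fraction)) entries."""
    if L < 1:
        raise ValueError("L must be >= 1")
    depth = max(1, math.floor(L * Fraction(fraction)))
    if depth > len(cl.entries):
        logger.warning(
            "requested top %d but consensus has only %d entries", depth, len(cl.entries)
        )
    entries = tuple((e.contact, e.freq) for e in cl.entries[:depth])
    return PredictionList(target_id=target_id, entries=entries, domain=domain)


FilterMode = Literal["remove_below", "remove_top_k", "keep_top_k"]


def filter_ensemble(
    members: Sequence,
    qt: QualityTable,
    mode: FilterMode,
    value: float,
) -> list:
    """Filter ensemble members (models or maps) by a quality table.

    remove_below keeps members scoring >= value; remove_top_k drops the
    value highest-scoring members; keep_top_k keeps only the value
    highest-scoring.  Score ties at the cut are broken by model_id
    ascending.  Members without a score are dropped with a warning.
    """

    def member_id(m) -> str:
        return getattr(m, "model_id", None) or getattr(m, "source_id")

    scored = []
    for m in members:
        mid = member_id(m)
        if mid not in qt:
            logger.warning("no quality score for %s; dropping from ensemble", mid)
            continue
        scored.append((m, mid, qt[mid]))

    if mode == "remove_below":
        kept = [m for m, _, s in scored if s >= value]
    elif mode in ("remove_top_k", "keep_top_k"):
        k = int(value)
        if k < 0:
            raise ValueError("k must be non-negative")
        ranked = sorted(scored, key=lambda t: (-t[2], t[1]))
        if k > len(ranked):
            logger.warning("k=%d exceeds ensemble size %d", k, len(ranked))
        if mode == "remove_top_k":
            kept = [m for m, _, _ in ranked[k:]]
        else:
            kept = [m for m, _, _ in ranked[:k]] if k < len(ranked) else [m for m, _, _ in ranked]
    else:
        raise ValueError(f"unknown filter mode {mode!r}")

    if not kept:
        raise DataError(f"ensemble empty after {mode} filter")
    kept.sort(key=member_id)
    return kept


def write_rr(pl: PredictionList, path: str | Path) -> None:
    """Write predictions in CASP RR format.

    Header ``PFRMAT RR`` / ``TARGET id`` / ``MODEL 1``; one body line
    ``i j 0 8 p`` per contact with the probability to six decimals;
    terminator ``END``.  Output is byte-deterministic for a given list.
    """
    lines = ["PFRMAT RR"]
    if pl.target_id:
        lines.append(f"TARGET {pl.target_id}")
    lines.append("MODEL 1")
    for c, score in pl.entries:
        lines.append(f"{c.i} {c.j} 0 8 {score:.6f}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rr(path: str | Path) -> PredictionList:
    """Read a CASP RR file back into a PredictionList.

    Tolerates extra whitespace, comment/keyword lines and an optional
    sequence block (lines of letters between MODEL and the contact records).
    """
    target_id = ""
    entries: list[tuple[Contact, float]] = []
    keywords = ("PFRMAT", "TARGET", "MODEL", "AUTHOR", "METHOD", "REMARK", "END")
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            head = line.split()[0].upper()
            if head in keywords:
                if head == "TARGET":
                    parts = line.split()
                    target_id = parts[1] if len(parts) > 1 else ""
                continue
            if line.isalpha():  # sequence block
                continue
            parts = line.split()
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 'i j d1 d2 p', got {line!r}")
            try:
                i, j = int(parts[0]), int(parts[1])
                score = float(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if i >= j:
                raise FormatError(f"{path}:{lineno}: need i < j, got {i} >= {j}")
            if not (0.0 <= score <= 1.0):
                raise FormatError(f"{path}:{lineno}: score {score} outside [0, 1]")
            entries.append((Contact(i, j), score))
    try:
        return PredictionList(target_id=target_id, entries=tuple(entries))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
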