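"""Synthetic reference structures and model ensembles with known ground truth.

The generator emulates the regime a consensus contact predictor faces on a
hard target: a pool of server models that mostly agree on the fold but are
individually noisy, with a minority that misplace a whole secondary-structure
segment (as happens when predictors swap or displace helices of a bundle).

``make_reference`` builds an idealized C-alpha trace — a packed helical
bundle (guaranteeing long-range inter-helix contacts) or a self-avoiding
random coil.  ``make_ensemble`` perturbs it with per-atom Gaussian noise and
rigid segment shifts, and reports the reference contact map as ground truth
plus a per-model quality score (fraction of true contacts preserved, a
GDT-TS stand-in that needs no superposition).  All randomness flows from a
single integer seed, so fixtures are reproducible byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from enscon.contacts import Contact, ContactMap, Parameters, DEFAULT_PARAMS, extract_contacts
from enscon.consensus import QualityTable
from enscon.structure_io import ResidueRecord, StructureModel, write_model_pdb

# Idealized alpha-helix C-alpha geometry.
_HELIX_RADIUS = 2.3  # A
_HELIX_RISE = 1.5  # A per residue
_HELIX_TURN = math.radians(100.0)  # per residue
_CA_STEP = 3.8  # A between consecutive residues
_AXIS_SPACING = 9.5  # A between adjacent helix axes
_LOOP_LEN = 3  # residues between helices


@dataclass(frozen=True)
class EnsembleSpec:
    """Study conditions for one synthetic ensemble.

    Defaults describe a desk-scale stand-in for a CASP server pool: 50
    models of an 80-residue bundle, 1.0 A coordinate noise, and 20% of
    models with one segment rigidly displaced far enough (15 A) to destroy
    its long-range contacts.
    """

    n_res: int = 80
    n_models: int = 50
    noise_sigma: float = 1.0
    corrupt_fraction: float = 0.2
    corrupt_shift: float = 15.0
    seed: int = 0
    sigma_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_res < 25:
            raise ValueError("n_res must be >= 25 so long-range pairs exist")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if not (0.0 <= self.corrupt_fraction <= 1.0):
            raise ValueError("corrupt_fraction must be in [0, 1]")
        if self.sigma_range is not None and not (
            0.0 <= self.sigma_range[0] <= self.sigma_range[1]
        ):
            raise ValueError("sigma_range must be an ordered non-negative pair")


def make_reference(
    n_res: int, motif: str = "helix_bundle", seed: int = 0
) -> StructureModel:
    """Build a deterministic reference trace with ~3.8 A consecutive spacing.

    helix_bundle packs >= 2 antiparallel helices around a small circle so
    that inter-helix (hence long-range) contacts are guaranteed;
    random_coil grows a self-avoiding walk with a 2 A clash floor.
    """
    if n_res < 25:
        raise ValueError("n_res must be >= 25")
    rng = np.random.default_rng(seed)
    if motif == "helix_bundle":
        coords = _make_bundle(n_res)
        # tiny seeded jitter breaks exact symmetries without moving contacts
        coords = coords + rng.normal(0.0, 0.02, coords.shape)
    elif motif == "random_coil":
        coords = _make_coil(n_res, rng)
    else:
        raise ValueError(f"unknown motif {motif!r}")
    residues = tuple(
        ResidueRecord(index=i + 1, aa="GLY", coord=coords[i]) for i in range(n_res)
    )
    return StructureModel(model_id=f"ref_{motif}_{seed}", residues=residues)


def _make_bundle(n_res: int) -> np.ndarray:
    n_helix = max(2, round(n_res / 21))
    n_loops = n_helix - 1
    helix_budget = n_res - _LOOP_LEN * n_loops
    base = helix_budget // n_helix
    lengths = [base] * n_helix
    lengths[-1] += helix_budget - base * n_helix

    if n_helix == 2:
        centers = [np.array([0.0, 0.0]), np.array([_AXIS_SPACING, 0.0])]
    else:
        R = _AXIS_SPACING / (2.0 * math.sin(math.pi / n_helix))
        centers = [
            R * np.array([math.cos(2 * math.pi * k / n_helix),
                          math.sin(2 * math.pi * k / n_helix)])
            for k in range(n_helix)
        ]

    pieces: list[np.ndarray] = []
    prev_end: np.ndarray | None = None
    for k, (n, c) in enumerate(zip(lengths, centers)):
        direction = 1.0 if k % 2 == 0 else -1.0
        t = np.arange(n)
        angle = math.pi * k + _HELIX_TURN * t
        # antiparallel: odd helices run back down in z
        if direction > 0:
            z = _HELIX_RISE * t
        else:
            z = _HELIX_RISE * (n - 1 - t)
        helix = np.stack(
            [
                c[0] + _HELIX_RADIUS * np.cos(angle),
                c[1] + _HELIX_RADIUS * np.sin(angle),
                z,
            ],
            axis=1,
        )
        if prev_end is not None:
            start = helix[0]
            loop = np.array(
                [
                    prev_end + (start - prev_end) * (s / (_LOOP_LEN + 1))
                    for s in range(1, _LOOP_LEN + 1)
                ]
            )
            pieces.append(loop)
        pieces.append(helix)
        prev_end = helix[-1]
    return np.vstack(pieces)


def _make_coil(n_res: int, rng: np.random.Generator, clash: float = 2.0) -> np.ndarray:
    pts = [np.zeros(3)]
    while len(pts) < n_res:
        for _ in range(200):
            v = rng.normal(size=3)
            v *= _CA_STEP / np.linalg.norm(v)
            cand = pts[-1] + v
            d = np.linalg.norm(np.array(pts) - cand, axis=1)
            if d.min() > clash:
                pts.append(cand)
                break
        else:  # stuck: back up one residue and retry
            pts.pop()
            if not pts:
                pts = [np.zeros(3)]
    return np.array(pts)


def make_ensemble(
    ref: StructureModel,
    spec: EnsembleSpec,
    params: Parameters = DEFAULT_PARAMS,
) -> tuple[list[StructureModel], ContactMap, QualityTable]:
    """Perturb a reference into an ensemble with known truth and quality.

    Every model adds i.i.d. Gaussian noise (noise_sigma per coordinate) to
    the reference.  When sigma_range is set, each model instead draws its
    own noise level uniformly from that range — a quality-graded pool in
    which some models are much better than others, as in a real server
    ensemble.  A corrupt_fraction of models additionally rigid-shift a
    random contiguous segment (about a third of the chain) by corrupt_shift
    along a random direction, which destroys that segment's long-range
    contacts.  The quality score of a model is the fraction of reference
    contacts its own map retains.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(ref)
    ref_coords = ref.coords
    truth = extract_contacts(ref, params)

    n_corrupt = round(spec.corrupt_fraction * spec.n_models)
    corrupt_ids = set(
        rng.choice(spec.n_models, size=n_corrupt, replace=False).tolist()
    )

    models: list[StructureModel] = []
    scores: dict[str, float] = {}
    for m in range(spec.n_models):
        if spec.sigma_range is not None:
            sigma = float(rng.uniform(*spec.sigma_range))
        else:
            sigma = spec.noise_sigma
        coords = ref_coords + rng.normal(0.0, sigma, (n, 3))
        if m in corrupt_ids:
            seg_len = max(5, n // 3)
            start = int(rng.integers(0, n - seg_len + 1))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords[start : start + seg_len] += spec.corrupt_shift * direction
        residues = tuple(
            ResidueRecord(index=r.index, aa=r.aa, coord=coords[k])
            for k, r in enumerate(ref.residues)
        )
        model = StructureModel(model_id=f"model_{m:03d}", residues=residues)
        models.append(model)
        cmap = extract_contacts(model, params)
        scores[model.model_id] = (
            len(truth.contacts & cmap.contacts) / len(truth.contacts)
            if truth.contacts
            else 0.0
        )
    return models, truth, QualityTable(scores)


def make_cluster_subset_maps(
    clusters: Sequence[Sequence[Contact]],
    n_models: int,
    seed: int = 0,
    p_include: float = 0.6,
) -> list[ContactMap]:
    """Maps that each carry a random strict, non-empty subset of clusters.

    Used to probe consensus consolidation: no single map covers every
    planted cluster, yet pooling the maps recovers all of them.
    """
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters to form strict subsets")
    rng = np.random.default_rng(seed)
    maps = []
    for m in range(n_models):
        while True:
            mask = rng.random(len(clusters)) < p_include
            if 0 < mask.sum() < len(clusters):
                break
        contacts = frozenset(
            c for keep, cl in zip(mask, clusters) if keep for c in cl
        )
        maps.append(ContactMap(source_id=f"subset_{m:03d}", contacts=contacts))
    return maps


def write_ensemble(
    models: Sequence[StructureModel],
    truth: ContactMap,
    qt: QualityTable,
    outdir: str | Path,
) -> Path:
    """Write PDB models, the truth contacts (RR) and the quality table (TSV)."""
    from enscon.consensus import PredictionList, write_rr

    outdir = Path(outdir)
    models_dir = outdir / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    for model in models:
        write_model_pdb(model, models_dir / f"{model.model_id}.pdb")
    truth_entries = tuple((c, 1.0) for c in sorted(truth.contacts))
    write_rr(
        PredictionList(target_id="synthetic", entries=truth_entries),
        outdir / "truth.rr",
    )
    qt.to_tsv(outdir / "quality.tsv")
    return outdir
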