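"""Shared test utilities: handcrafted PDB text and independent oracles.

The oracles here deliberately avoid the code paths they check: contact
extraction is a dense all-pairs distance scan (no spatial index), consensus
counting is a plain dictionary tally, and delta-matching is a nested loop.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from enscon.contacts import Contact, ContactMap, contact_distance
from enscon.structure_io import ResidueRecord, StructureModel

# Frozen study conditions for the planted-contact fixture:
# 80-residue helix bundle, 50 models, 1.0 A noise, 20% corrupted.
REF_SEED = 3
ENS_SEED = 7


def atom_line(
    serial: int,
    name: str,
    resname: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    chain: str = "A",
    altloc: str = " ",
    icode: str = " ",
    record: str = "ATOM",
) -> str:
    """One fixed-width PDB coordinate record."""
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}  1.00 20.00           C"
    )


def write_pdb(path, lines) -> None:
    path.write_text("\n".join(list(lines) + ["END"]) + "\n")


def model_from_coords(coords, model_id="m", first_index=1) -> StructureModel:
    coords = np.asarray(coords, dtype=float)
    residues = tuple(
        ResidueRecord(index=first_index + k, aa="GLY", coord=coords[k])
        for k in range(len(coords))
    )
    return StructureModel(model_id=model_id, residues=residues)


def brute_force_contacts(model: StructureModel, threshold: float = 8.0) -> set[Contact]:
    """All-pairs distance scan, strict < threshold."""
    coords = model.coords
    idx = model.indices
    found = set()
    n = len(coords)
    dists = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for a in range(n):
        for b in range(a + 1, n):
            if dists[a, b] < threshold:
                i, j = int(idx[a]), int(idx[b])
                found.add(Contact(min(i, j), max(i, j)))
    return found


def tally_oracle(maps) -> Counter:
    tally: Counter = Counter()
    for m in maps:
        for c in m.contacts:
            tally[c] += 1
    return tally


def brute_force_matches(preds, true_set, delta: int) -> int:
    """Exhaustive per-prediction delta-neighborhood matcher."""
    n = 0
    for p in preds:
        for t in true_set:
            if contact_distance(p, t) <= delta:
                n += 1
                break
    return n


def random_contact_set(rng, n, max_res=120) -> set[Contact]:
    found = set()
    while len(found) < n:
        i = int(rng.integers(1, max_res))
        j = int(rng.integers(i + 1, max_res + 1))
        found.add(Contact(i, j))
    return found
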