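"""Seeded synthetic fixtures: proteins with realistic residue composition,
prediction tables, and target lists, so the full pipeline is testable
without downloading any database sequence.

The default residue weights approximate the average composition of
vertebrate proteins, giving a combined S/T/Y density of roughly 15% —
about what a typical human protein offers to a phosphosite analysis.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .io_formats import PredictionTable, ProteinRecord, TargetList

#: approximate vertebrate average amino-acid frequencies (mole %)
DEFAULT_RESIDUE_WEIGHTS: dict[str, float] = {
    "A": 7.4, "R": 4.2, "N": 4.4, "D": 5.9, "C": 2.9,
    "E": 5.8, "Q": 3.7, "G": 7.4, "H": 2.9, "I": 3.8,
    "L": 7.6, "K": 7.2, "M": 1.8, "F": 4.0, "P": 5.0,
    "S": 7.0, "T": 5.4, "W": 1.3, "Y": 3.0, "V": 6.8,
}


def generate_fixture_protein(
    length: int,
    residue_weights: Mapping[str, float] | None = None,
    seed: int = 0,
    protein_id: str = "synthetic",
) -> ProteinRecord:
    """Draw a random protein sequence, reproducibly for a given seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    weights = dict(residue_weights or DEFAULT_RESIDUE_WEIGHTS)
    letters = sorted(weights)
    probs = np.array([weights[aa] for aa in letters], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("residue weights must be non-negative and sum > 0")
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(letters, size=length, p=probs))
    return ProteinRecord(id=protein_id, sequence=seq, description="synthetic fixture")


def generate_fixture_predictions(
    protein: ProteinRecord,
    fraction: float,
    seed: int = 0,
    modifiable_residues=frozenset("STY"),
) -> PredictionTable:
    """Assign scores in (0, 1] to a reproducible random subset of the
    protein's modifiable positions; ``fraction`` controls the subset size."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    residues = set(modifiable_residues) - {"X"}
    candidates = [
        p for p, aa in enumerate(protein.sequence, start=1) if aa in residues
    ]
    rng = np.random.default_rng(seed)
    k = int(round(fraction * len(candidates)))
    chosen = sorted(rng.choice(candidates, size=k, replace=False)) if k else []
    # 1 - random() lies in (0, 1]
    scores = {int(p): float(1.0 - rng.random()) for p in chosen}
    return PredictionTable(protein_id=protein.id, scores=scores)


def generate_fixture_targets(
    protein: ProteinRecord,
    n_targets: int,
    seed: int = 0,
    modifiable_residues=frozenset("STY"),
) -> TargetList:
    """Pick a reproducible random subset of modifiable positions as targets."""
    residues = set(modifiable_residues) - {"X"}
    candidates = [
        p for p, aa in enumerate(protein.sequence, start=1) if aa in residues
    ]
    if n_targets < 1 or n_targets > len(candidates):
        raise ValueError(
            f"n_targets must lie in [1, {len(candidates)}] for this protein"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_targets, replace=False)
    return TargetList(
        protein_id=protein.id, positions=frozenset(int(p) for p in chosen)
    )


#: N-terminal tail of histone H3 (mature numbering, initiator Met removed);
#: K9 and K14 flank the STGG motif probed in acetylation cross-talk studies.
HISTONE_H3_TAIL = "ARTKQTARKSTGGKAPRKQLATKAAR"


def histone_h3_tail_protein() -> ProteinRecord:
    """The histone H3 N-terminal tail as a fixture protein (26 residues)."""
    return ProteinRecord(
        id="H3_tail",
        sequence=HISTONE_H3_TAIL,
        description="histone H3 N-terminal tail, mature numbering",
    )
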