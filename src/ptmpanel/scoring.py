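"""Digestion-setting scores.

Five scores are computed per protease combination:

* maximal — total number of modifiable residues in the protein; the ceiling
  for any digestion's site coverage, independent of the digestion itself.
* ETD — number of distinct modifiable positions covered by at least one
  retained peptide. Electron-transfer dissociation localises labile
  modifications unambiguously, so every covered site counts.
* CID — sum over retained modified peptides of 1/n, where n is the number
  of modifiable sites the peptide carries. Collision-induced dissociation
  localises mono-modified peptides most reliably, hence the 1/n weighting.
* predicted matched / unmatched — sums of per-site prediction scores over
  the peptides kept vs rejected by the length window (among site-bearing
  peptides); together they conserve the total score mass of the digestion.

Also computed: the mono-modified peptide count, target-site coverage, and
the concordance between a simulated and an observed site set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .filters import FilterConfig, filter_by_length, filter_by_pattern, filter_by_ptm_sites
from .io_formats import PredictionTable, ProteinRecord, TargetList
from .proteases import DigestionSetting, Peptide, ProteaseRule, parallel_digest


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide annotated with the 1-based protein positions of its
    modifiable residues; ``n_sites`` is the peptide's site multiplicity n."""

    peptide: Peptide
    site_positions: tuple

    def __post_init__(self) -> None:
        if not self.site_positions:
            raise ValueError("ModifiedPeptide requires at least one site")
        for p in self.site_positions:
            if not self.peptide.start <= p <= self.peptide.end:
                raise ValueError(
                    f"site {p} outside peptide {self.peptide.start}-{self.peptide.end}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)


@dataclass(frozen=True)
class ScoreRecord:
    """All scores of one digestion setting for one protein."""

    protein_id: str
    combination: tuple
    maximal: int
    etd: int
    cid: float
    predicted_matched: float
    predicted_unmatched: float
    mono_modified_count: int
    targets_covered: frozenset = frozenset()
    targets_uncovered: frozenset = frozenset()

    @property
    def label(self) -> str:
        return "+".join(sorted(self.combination))

    @property
    def n_proteases(self) -> int:
        return len(self.combination)


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement between simulated and observed site sets."""

    matched: frozenset
    false_positives: frozenset
    false_negatives: frozenset
    concordance_percent: float


def annotate_sites(
    peptide: Peptide, protein: ProteinRecord, modifiable_residues: Iterable[str]
) -> ModifiedPeptide | None:
    """Locate the modifiable residues of a peptide on the protein; returns
    None for a site-free peptide. X never counts as modifiable."""
    residues = set(modifiable_residues) - {"X"}
    sites = tuple(
        p
        for p in range(peptide.start, peptide.end + 1)
        if protein.residue(p) in residues
    )
    if not sites:
        return None
    return ModifiedPeptide(peptide=peptide, site_positions=sites)


def maximal_score(protein: ProteinRecord, modifiable_residues: Iterable[str]) -> int:
    """Total number of modifiable residues in the protein."""
    residues = set(modifiable_residues) - {"X"}
    return sum(1 for aa in protein.sequence if aa in residues)


def etd_score(retained: Sequence[ModifiedPeptide]) -> int:
    """Distinct protein positions covered by >= 1 retained modified peptide."""
    covered: set[int] = set()
    for mp in retained:
        covered.update(mp.site_positions)
    return len(covered)


def cid_score(retained: Sequence[ModifiedPeptide]) -> float:
    """Sum of 1/n over retained modified peptides (n = sites per peptide)."""
    return float(sum(1.0 / mp.n_sites for mp in retained))


def mono_modified_count(retained: Sequence[ModifiedPeptide]) -> int:
    """Number of retained peptides carrying exactly one modifiable site."""
    return sum(1 for mp in retained if mp.n_sites == 1)


def predicted_scores(
    site_bearing_selected: Sequence[ModifiedPeptide],
    site_bearing_rejected: Sequence[ModifiedPeptide],
    table: PredictionTable | None,
) -> tuple[float, float]:
    """Per-peptide sums of per-site prediction scores for the selected and
    rejected pools. A site covered by several peptides contributes once per
    peptide occurrence; a site absent from the table scores 0."""
    if table is None:
        return 0.0, 0.0

    def _pool(pool: Sequence[ModifiedPeptide]) -> float:
        return float(
            sum(table.score(p) for mp in pool for p in mp.site_positions)
        )

    return _pool(site_bearing_selected), _pool(site_bearing_rejected)


def target_coverage(
    retained: Sequence[ModifiedPeptide], targets: TargetList | None
) -> tuple[frozenset, frozenset]:
    """Split target positions into covered (appearing among retained
    peptides' sites) and uncovered."""
    if targets is None:
        return frozenset(), frozenset()
    covered_sites: set[int] = set()
    for mp in retained:
        covered_sites.update(mp.site_positions)
    covered = frozenset(targets.positions & covered_sites)
    return covered, frozenset(targets.positions - covered)


def concordance(
    simulated: Iterable[int],
    observed: Iterable[int],
    denominator: str = "union",
) -> ConcordanceResult:
    """Compare simulated (in-silico accessible) and observed site sets.

    matched = S & O, false positives = S - O (simulated only), false
    negatives = O - S (observed only). The percent agreement is
    100 * |S & O| / D with D = |S | O| ("union", the default), |O|
    ("observed") or |S| ("simulated"); 0 when the denominator is empty.
    """
    s, o = frozenset(simulated), frozenset(observed)
    matched = s & o
    denom = {"union": len(s | o), "observed": len(o), "simulated": len(s)}.get(
        denominator
    )
    if denom is None:
        raise ValueError(f"unknown denominator {denominator!r}")
    percent = 100.0 * len(matched) / denom if denom else 0.0
    return ConcordanceResult(
        matched=matched,
        false_positives=s - o,
        false_negatives=o - s,
        concordance_percent=percent,
    )


def score_setting(
    protein: ProteinRecord,
    rules: Sequence[ProteaseRule] | DigestionSetting,
    config: FilterConfig,
    prediction_table: PredictionTable | None = None,
    targets: TargetList | None = None,
    panel: Sequence[ProteaseRule] | None = None,
) -> ScoreRecord:
    """Digest, filter and score one digestion setting for one protein.

    The retained pool (ETD, CID, mono-modified count, target coverage) is
    the outcome of the full site -> length -> pattern pipeline. The
    predicted matched/unmatched partition is the length-filter outcome among
    site-bearing peptides, so the two pools conserve total predicted score
    mass regardless of the window.
    """
    pooled = parallel_digest(protein, rules, panel=panel)
    combination = (
        rules.combination
        if isinstance(rules, DigestionSetting)
        else tuple(sorted(r.name for r in rules))
    )

    site_bearing, _ = filter_by_ptm_sites(pooled, config)
    in_window, out_window = filter_by_length(site_bearing, config)
    retained_peps, _ = filter_by_pattern(in_window, config.compiled_pattern)

    def _annotate(peps: Sequence[Peptide]) -> list[ModifiedPeptide]:
        out = []
        for pep in peps:
            mp = annotate_sites(pep, protein, config.modifiable_residues)
            if mp is not None:
                out.append(mp)
        return out

    retained = _annotate(retained_peps)
    selected_pool = _annotate(in_window)
    rejected_pool = _annotate(out_window)

    matched, unmatched = predicted_scores(selected_pool, rejected_pool, prediction_table)
    covered, uncovered = target_coverage(retained, targets)
    return ScoreRecord(
        protein_id=protein.id,
        combination=combination,
        maximal=maximal_score(protein, config.modifiable_residues),
        etd=etd_score(retained),
        cid=cid_score(retained),
        predicted_matched=matched,
        predicted_unmatched=unmatched,
        mono_modified_count=mono_modified_count(retained),
        targets_covered=covered,
        targets_uncovered=uncovered,
    )
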