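"""Protease cleavage specificities and in-silico digestion.

A cut position ``i`` denotes the scissile bond between residues ``i`` and
``i + 1`` (1-based). A C-side rule cleaves after its recognition residue,
an N-side rule before it. Missed cleavages are additive: a digest with
``max_missed_cleavages = m`` returns every peptide spanning up to ``m + 1``
consecutive fully cleaved fragments, alongside the fully cleaved ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io_formats import ProteinRecord

MAX_MISSED_CLEAVAGES_CAP = 10


@dataclass(frozen=True)
class ProteaseRule:
    """A named cleavage specificity.

    Parameters
    ----------
    name : str
        Protease (or chemical cleavage agent) name.
    cut_residues : frozenset of str
        Residues recognised for cleavage.
    terminal_side : {"C", "N"}
        "C": cleave after the recognised residue; "N": before it.
    blocked_next : frozenset of str
        Residues that cancel a C-side cut when they immediately follow the
        recognised residue (e.g. the proline exception). Must be empty for
        N-side rules.
    max_missed_cleavages : int
        Allowed skipped internal cut sites per peptide (default 0).
    """

    name: str
    cut_residues: frozenset
    terminal_side: str = "C"
    blocked_next: frozenset = frozenset()
    max_missed_cleavages: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cut_residues", frozenset(self.cut_residues))
        object.__setattr__(self, "blocked_next", frozenset(self.blocked_next))
        if not self.cut_residues:
            raise ValueError(f"rule {self.name!r}: empty cut-residue set")
        if self.terminal_side not in ("C", "N"):
            raise ValueError(f"rule {self.name!r}: terminal_side must be 'C' or 'N'")
        if self.terminal_side == "N" and self.blocked_next:
            raise ValueError(
                f"rule {self.name!r}: blocked_next only applies to C-side rules"
            )
        if not 0 <= self.max_missed_cleavages <= MAX_MISSED_CLEAVAGES_CAP:
            raise ValueError(
                f"rule {self.name!r}: max_missed_cleavages outside "
                f"[0, {MAX_MISSED_CLEAVAGES_CAP}]"
            )

    def with_missed_cleavages(self, m: int) -> "ProteaseRule":
        return replace(self, max_missed_cleavages=m)


@dataclass(frozen=True)
class Peptide:
    """A digestion product, with inclusive 1-based coordinates on its parent."""

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    protease: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad peptide interval {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"peptide {self.sequence!r} length does not match "
                f"{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DigestionSetting:
    """A protease combination plus per-protease missed-cleavage allowances."""

    combination: tuple
    missed_cleavages: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(sorted(self.combination))
        if not names:
            raise ValueError("empty combination")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate protease names in {names}")
        object.__setattr__(self, "combination", names)
        object.__setattr__(self, "missed_cleavages", dict(self.missed_cleavages))

    def resolve(self, panel: Sequence[ProteaseRule]) -> list[ProteaseRule]:
        """Materialise the rules of this setting from a panel, applying any
        per-protease missed-cleavage overrides."""
        by_name = {r.name: r for r in panel}
        rules = []
        for name in self.combination:
            if name not in by_name:
                raise KeyError(f"protease {name!r} not in panel")
            rule = by_name[name]
            if name in self.missed_cleavages:
                rule = rule.with_missed_cleavages(self.missed_cleavages[name])
            rules.append(rule)
        return rules


def default_protease_panel() -> list[ProteaseRule]:
    """The nine default cleavage agents: eight proteases commonly used in MS
    plus CNBr, with community-standard specificities and zero missed
    cleavages. All rules are plain data and can be edited or replaced.
    """
    return [
        ProteaseRule("Arg-C", frozenset("R"), "C"),
        ProteaseRule("Asp-N", frozenset("D"), "N"),
        # high-specificity chymotrypsin: after F/Y/W, blocked by proline
        ProteaseRule("chymotrypsin", frozenset("FYW"), "C", frozenset("P")),
        ProteaseRule("Lys-C", frozenset("K"), "C"),
        ProteaseRule("Lys-N", frozenset("K"), "N"),
        # "/P" means no proline exception
        ProteaseRule("trypsin/P", frozenset("KR"), "C"),
        ProteaseRule("V8-DE", frozenset("DE"), "C"),
        ProteaseRule("V8-E", frozenset("E"), "C"),
        ProteaseRule("CNBr", frozenset("M"), "C"),
    ]


def cleavage_sites(sequence: str, rule: ProteaseRule) -> list[int]:
    """Positions ``i`` of cleaved bonds (between residues i and i+1, 1-based),
    strictly increasing; never includes the position after the last residue."""
    if not sequence:
        raise ValueError("empty sequence")
    sites = []
    if rule.terminal_side == "C":
        for i in range(1, len(sequence)):
            if sequence[i - 1] in rule.cut_residues and sequence[i] not in rule.blocked_next:
                sites.append(i)
    else:
        for i in range(1, len(sequence)):
            if sequence[i] in rule.cut_residues:
                sites.append(i)
    return sites


def digest(
    protein: ProteinRecord,
    rule: ProteaseRule,
    max_missed_cleavages: int | None = None,
) -> list[Peptide]:
    """In-silico digestion of one protein with one rule.

    With cut positions c_1 < ... < c_m defining m+1 fully cleaved fragments,
    returns every peptide spanning j consecutive fragments for
    j = 1 .. max_missed_cleavages + 1 (missed_cleavages = j - 1). Fully
    cleaved peptides are always included; output is sorted by (start, end)
    and duplicate-free.
    """
    mc = rule.max_missed_cleavages if max_missed_cleavages is None else max_missed_cleavages
    cuts = cleavage_sites(protein.sequence, rule)
    # fragment boundaries: starts and (inclusive) ends
    bounds = [0] + cuts + [len(protein.sequence)]
    n_frag = len(bounds) - 1
    peptides = []
    for first in range(n_frag):
        for j in range(1, min(mc + 1, n_frag - first) + 1):
            start = bounds[first] + 1
            end = bounds[first + j]
            peptides.append(
                Peptide(
                    protein_id=protein.id,
                    start=start,
                    end=end,
                    sequence=protein.sequence[start - 1 : end],
                    missed_cleavages=j - 1,
                    protease=rule.name,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def parallel_digest(
    protein: ProteinRecord,
    rules: Sequence[ProteaseRule] | DigestionSetting,
    panel: Sequence[ProteaseRule] | None = None,
) -> list[Peptide]:
    """Pool the digests of independent parallel digestions.

    Each peptide keeps its source protease; identical intervals produced by
    different proteases are all kept (site-level scores deduplicate by
    position downstream).
    """
    if isinstance(rules, DigestionSetting):
        if panel is None:
            raise ValueError("a panel is required to resolve a DigestionSetting")
        rules = rules.resolve(panel)
    rules = list(rules)
    if not rules:
        raise ValueError("empty combination")
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate protease names in combination {names}")
    pooled: list[Peptide] = []
    for rule in rules:
        pooled.extend(digest(protein, rule))
    pooled.sort(key=lambda p: (p.start, p.end, p.protease))
    return pooled
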