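"""Peptide filters: modification-site presence, MS-compatible length, and an
optional sequence-pattern filter for cross-talk studies.

Each filter partitions its input: retained + rejected = input, order
preserved. The canonical pipeline order is site -> length -> pattern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .proteases import Peptide

DEFAULT_MODIFIABLE = frozenset("STY")  # phosphorylatable residues
DEFAULT_MIN_LENGTH = 7
DEFAULT_MAX_LENGTH = 40


@dataclass(frozen=True)
class FilterConfig:
    """Filtering parameters.

    Parameters
    ----------
    modifiable_residues : frozenset of str
        Residues that can carry the modification of interest (default S/T/Y
        for phosphorylation; e.g. {"K"} for lysine acetylation). X never
        counts as modifiable.
    min_length, max_length : int
        Inclusive peptide-length window compatible with LC-MS detection
        (default 7-40 amino acids).
    pattern : str or None
        Optional regular expression; a peptide is retained iff the pattern
        matches anywhere in its sequence (search, not anchored). None
        disables the filter.
    """

    modifiable_residues: frozenset = DEFAULT_MODIFIABLE
    min_length: int = DEFAULT_MIN_LENGTH
    max_length: int = DEFAULT_MAX_LENGTH
    pattern: str | None = None
    _compiled: re.Pattern | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        residues = frozenset(self.modifiable_residues) - {"X"}
        if not residues:
            raise ValueError("modifiable_residues must be non-empty (and not only X)")
        object.__setattr__(self, "modifiable_residues", residues)
        if not 1 <= self.min_length:
            raise ValueError("min_length must be >= 1")
        if self.min_length > self.max_length:
            raise ValueError(
                f"min_length {self.min_length} > max_length {self.max_length}"
            )
        if self.pattern is not None:
            try:
                object.__setattr__(self, "_compiled", re.compile(self.pattern))
            except re.error as exc:
                raise ValueError(f"invalid pattern {self.pattern!r}: {exc}") from exc

    @property
    def compiled_pattern(self) -> re.Pattern | None:
        return self._compiled


def filter_by_ptm_sites(
    peptides: Sequence[Peptide], config: FilterConfig
) -> tuple[list[Peptide], list[Peptide]]:
    """Retain peptides containing at least one modifiable residue."""
    residues = config.modifiable_residues
    retained, rejected = [], []
    for pep in peptides:
        (retained if any(aa in residues for aa in pep.sequence) else rejected).append(pep)
    return retained, rejected


def filter_by_length(
    peptides: Sequence[Peptide], config: FilterConfig
) -> tuple[list[Peptide], list[Peptide]]:
    """Retain peptides whose length lies in [min_length, max_length]."""
    retained, rejected = [], []
    for pep in peptides:
        (retained if config.min_length <= len(pep) <= config.max_length else rejected).append(pep)
    return retained, rejected


def filter_by_pattern(
    peptides: Sequence[Peptide], pattern: str | re.Pattern | None
) -> tuple[list[Peptide], list[Peptide]]:
    """Retain peptides matched anywhere by the pattern (regex search).

    A None or empty pattern disables the filter (everything retained).
    """
    if pattern is None or pattern == "":
        return list(peptides), []
    if isinstance(pattern, str):
        try:
            pattern = re.compile(pattern)
        except re.error as exc:
            raise ValueError(f"invalid pattern: {exc}") from exc
    retained, rejected = [], []
    for pep in peptides:
        (retained if pattern.search(pep.sequence) else rejected).append(pep)
    return retained, rejected


def apply_filters(
    peptides: Sequence[Peptide], config: FilterConfig
) -> dict[str, list[Peptide]]:
    """Run the full pipeline (site -> length -> pattern).

    Returns a dict with keys ``retained``, ``no_site``, ``bad_length``,
    ``no_pattern_match``; the four lists partition the input.
    """
    with_sites, no_site = filter_by_ptm_sites(peptides, config)
    in_window, bad_length = filter_by_length(with_sites, config)
    retained, no_match = filter_by_pattern(in_window, config.compiled_pattern)
    return {
        "retained": retained,
        "no_site": no_site,
        "bad_length": bad_length,
        "no_pattern_match": no_match,
    }


def identity_config() -> FilterConfig:
    """A configuration under which filtering is the identity (all 20 residues
    modifiable, unbounded length, no pattern). Useful for testing."""
    return FilterConfig(
        modifiable_residues=frozenset("ACDEFGHIKLMNPQRSTVWY"),
        min_length=1,
        max_length=10**9,
        pattern=None,
    )
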