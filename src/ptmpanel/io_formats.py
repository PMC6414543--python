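"""Input/output: FASTA proteins, prediction tables, target-site lists,
score tables, detail reports, PTM maps, and a protein-mass utility.

Coordinates are 1-based and inclusive everywhere in this package, matching
the residue numbering used in site nomenclature (e.g. S10 is the serine at
position 10 of the mature protein).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from pyteomics import mass as _pt_mass

#: the 20 canonical amino acids
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: X is tolerated in sequences but is never modifiable nor cleavable
ALLOWED_RESIDUES = CANONICAL_RESIDUES | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence.

    Parameters
    ----------
    id : str
        Accession or identifier (first whitespace-separated token of the
        FASTA header).
    description : str
        Remainder of the header line, may be empty.
    sequence : str
        Upper-case amino-acid string; the 20 canonical letters plus X.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} outside protein {self.id!r} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class PredictionTable:
    """Per-site modification-prediction scores for one protein.

    ``scores`` maps a 1-based residue position to a non-negative real score,
    typically the "combined-score" of a phosphosite predictor.
    """

    protein_id: str
    scores: Mapping[int, float] = field(default_factory=dict)

    def score(self, position: int) -> float:
        return self.scores.get(position, 0.0)

    def validate(self, protein: ProteinRecord, modifiable: Iterable[str] = ()) -> None:
        """Check positions against the protein; out-of-range is fatal,
        a scored residue outside the modifiable set is only a warning
        (the entry is kept)."""
        modifiable = set(modifiable)
        for pos in self.scores:
            if not 1 <= pos <= len(protein):
                raise ValueError(
                    f"prediction for {self.protein_id!r}: position {pos} "
                    f"exceeds protein length {len(protein)}"
                )
            if modifiable and protein.residue(pos) not in modifiable:
                warnings.warn(
                    f"prediction for {self.protein_id!r}: residue "
                    f"{protein.residue(pos)}{pos} is not in the modifiable set",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class TargetList:
    """Target modification-site positions (1-based) for one protein."""

    protein_id: str
    positions: frozenset[int]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError(f"empty target list for {self.protein_id!r}")
        if any(p < 1 for p in self.positions):
            raise ValueError("target positions must be >= 1")

    def validate(self, protein: ProteinRecord, modifiable: Iterable[str] = ()) -> None:
        for pos in sorted(self.positions):
            if pos > len(protein):
                raise ValueError(
                    f"target {pos} exceeds protein {protein.id!r} length "
                    f"{len(protein)}"
                )
            if set(modifiable) and protein.residue(pos) not in set(modifiable):
                warnings.warn(
                    f"target {protein.residue(pos)}{pos} of {protein.id!r} is "
                    "not a modifiable residue and can never be covered",
                    stacklevel=2,
                )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased; a trailing ``*`` (stop) is stripped with a
    warning; any other non-amino-acid character is a hard error. The header
    is split at the first whitespace into id and description.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if seq.endswith("*"):
            warnings.warn(f"record {rec.id!r}: trailing '*' stripped", stacklevel=2)
            seq = seq.rstrip("*")
        if "*" in seq:
            raise ValueError(f"record {rec.id!r}: internal stop codon '*'")
        if not seq:
            raise ValueError(f"record {rec.id!r}: empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


#: default column headers as produced by the PhosphoPICK predictor
DEFAULT_POSITION_COLUMNS = ("site", "position", "pos")
DEFAULT_SCORE_COLUMNS = ("combined-score", "combined_score", "score")


def read_prediction_table(
    path: str | Path,
    protein_id: str,
    position_column: str | None = None,
    score_column: str | None = None,
) -> PredictionTable:
    """Read a delimited table of (position, score) predictions.

    The delimiter is sniffed. Column names are configurable; by default the
    reader accepts PhosphoPICK-style headers (``site`` / ``combined-score``)
    and common fallbacks. Duplicate positions collapse to the maximum score
    with a warning; a negative score or non-positive position is a hard
    error. An empty table is valid (all predicted scores are then zero).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty and df.columns.size == 0:
        return PredictionTable(protein_id=protein_id, scores={})
    cols = {c.lower().strip(): c for c in df.columns}

    def _pick(requested: str | None, candidates: Sequence[str], what: str) -> str:
        if requested is not None:
            if requested not in df.columns:
                raise ValueError(f"{what} column {requested!r} not found in {path}")
            return requested
        for cand in candidates:
            if cand in cols:
                return cols[cand]
        raise ValueError(
            f"no {what} column among {list(df.columns)} in {path}; "
            f"expected one of {list(candidates)}"
        )

    pos_col = _pick(position_column, DEFAULT_POSITION_COLUMNS, "position")
    score_col = _pick(score_column, DEFAULT_SCORE_COLUMNS, "score")

    scores: dict[int, float] = {}
    for raw_pos, raw_score in zip(df[pos_col], df[score_col]):
        fpos = float(raw_pos)
        if fpos != int(fpos):
            raise ValueError(f"non-integer position {raw_pos!r} in {path}")
        pos = int(fpos)
        if pos < 1:
            raise ValueError(f"position {pos} < 1 in {path}")
        score = float(raw_score)
        if score < 0:
            raise ValueError(f"negative score {score} at position {pos} in {path}")
        if pos in scores:
            warnings.warn(
                f"duplicate prediction for position {pos}; keeping max score",
                stacklevel=2,
            )
            score = max(score, scores[pos])
        scores[pos] = score
    return PredictionTable(protein_id=protein_id, scores=scores)


def read_target_sites(path: str | Path, protein_id: str) -> TargetList:
    """Read a plain-text target-site list: one 1-based position per line,
    blank lines and ``#`` comments ignored, duplicates collapsed."""
    positions: set[int] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            pos = int(line)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: not an integer: {line!r}") from exc
        positions.add(pos)
    if not positions:
        raise ValueError(f"empty target list in {path}")
    return TargetList(protein_id=protein_id, positions=frozenset(positions))


# ---------------------------------------------------------------------------
# outputs

SCORE_TABLE_COLUMNS = [
    "combination",
    "n_proteases",
    "maximal",
    "etd",
    "cid",
    "predicted_matched",
    "predicted_unmatched",
    "mono_modified_count",
    "n_targets_covered",
    "covered_positions",
    "uncovered_positions",
]


def combination_label(names: Iterable[str]) -> str:
    """Canonical label: protease names sorted alphabetically, joined by '+'."""
    return "+".join(sorted(names))


def write_score_table(records: Sequence, path: str | Path) -> pd.DataFrame:
    """Write one CSV row per digestion setting, ordered by (panel size,
    label). Returns the DataFrame that was written."""
    from .search import scores_to_frame  # local import to avoid a cycle

    df = scores_to_frame(records)
    df.to_csv(path, index=False)
    return df


def write_detail_report(
    protein: ProteinRecord,
    per_combination_peptides: Mapping[str, Sequence],
    path: str | Path,
    modifiable_residues: Iterable[str] = ("S", "T", "Y"),
) -> None:
    """Write the retained modified peptides of every digestion setting, with
    their coordinates, missed-cleavage counts, source protease and the
    1-based protein positions of their modifiable residues."""
    modifiable = set(modifiable_residues) - {"X"}
    lines = [f"# protein {protein.id} length {len(protein)}"]
    site_positions = sorted(
        i for i, aa in enumerate(protein.sequence, start=1) if aa in modifiable
    )
    lines.append(
        "# modifiable sites in protein: "
        + (" ".join(f"{protein.residue(p)}{p}" for p in site_positions) or "none")
    )
    for label in sorted(per_combination_peptides):
        peptides = per_combination_peptides[label]
        lines.append(f"\n== combination {label} ==")
        if not peptides:
            lines.append("no peptides")
            continue
        for pep in peptides:
            sites = [
                p
                for p in range(pep.start, pep.end + 1)
                if protein.residue(p) in modifiable
            ]
            site_str = " ".join(f"{protein.residue(p)}{p}" for p in sites) or "-"
            lines.append(
                f"{pep.sequence}\t{pep.start}-{pep.end}\tmc={pep.missed_cleavages}"
                f"\t{pep.protease}\tsites: {site_str}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def render_ptm_map(
    protein: ProteinRecord,
    retained_peptides: Sequence,
    modifiable_positions: Iterable[int],
    svg_path: str | Path | None = None,
    width: int = 60,
) -> str:
    """Render a per-residue coverage map of the retained modified peptides.

    Returns a plain-text map; if ``svg_path`` is given, also writes a simple
    SVG with one rectangle per peptide interval and one tick per modifiable
    site (covered sites are distinguishable from uncovered ones).
    """
    n = len(protein)
    modifiable_positions = set(modifiable_positions)
    covered = [False] * (n + 1)
    for pep in retained_peptides:
        if pep.protein_id != protein.id:
            raise ValueError(
                f"peptide {pep.sequence!r} belongs to {pep.protein_id!r}, "
                f"not {protein.id!r}"
            )
        for p in range(pep.start, pep.end + 1):
            covered[p] = True

    lines = [f"# PTM map for {protein.id} ({n} aa)"]
    for block in range(0, n, width):
        start, stop = block + 1, min(block + width, n)
        seq = protein.sequence[block:stop]
        marks = []
        for p in range(start, stop + 1):
            if p in modifiable_positions:
                marks.append("*" if covered[p] else "o")
            else:
                marks.append("^" if covered[p] else " ")
        lines.append(f"{start:>6} {seq}")
        lines.append(f"{'':>6} {''.join(marks)}")
    lines.append("# * covered modifiable site, o uncovered modifiable site,")
    lines.append("# ^ covered non-modifiable residue")
    for pep in sorted(retained_peptides, key=lambda p: (p.start, p.end, p.protease)):
        lines.append(
            f"# peptide {pep.start}-{pep.end} {pep.protease} {pep.sequence}"
        )
    text = "\n".join(lines) + "\n"

    if svg_path is not None:
        _write_map_svg(protein, retained_peptides, modifiable_positions, svg_path)
    return text


def _write_map_svg(protein, peptides, modifiable_positions, path) -> None:
    n = len(protein)
    px = 900.0 / max(n, 1)
    lanes: list[int] = []  # rightmost end per lane, for interval packing
    elems = [
        '<rect x="20" y="30" width="900" height="8" fill="#bbb"/>',
    ]
    for pep in sorted(peptides, key=lambda p: (p.start, p.end, p.protease)):
        lane = next(
            (j for j, end in enumerate(lanes) if pep.start > end), len(lanes)
        )
        if lane == len(lanes):
            lanes.append(pep.end)
        else:
            lanes[lane] = pep.end
        x = 20 + (pep.start - 1) * px
        w = max((pep.end - pep.start + 1) * px, 1.0)
        y = 50 + lane * 14
        elems.append(
            f'<rect x="{x:.1f}" y="{y}" width="{w:.1f}" height="10" '
            f'fill="#f5d547" stroke="#555"><title>'
            f"{pep.protease} {pep.start}-{pep.end} {pep.sequence}</title></rect>"
        )
    covered = set()
    for pep in peptides:
        covered.update(range(pep.start, pep.end + 1))
    for pos in sorted(modifiable_positions):
        x = 20 + (pos - 0.5) * px
        color = "#2a7de1" if pos in covered else "#d43d3d"
        elems.append(
            f'<line x1="{x:.1f}" y1="24" x2="{x:.1f}" y2="44" '
            f'stroke="{color}" stroke-width="1.5">'
            f"<title>site {pos}</title></line>"
        )
    height = 70 + 14 * max(len(lanes), 1)
    svg = (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="940" height="{height}">'
        f'<text x="20" y="16" font-family="monospace">{protein.id}</text>'
        + "".join(elems)
        + "</svg>"
    )
    Path(path).write_text(svg)


def compute_protein_mass(sequence: str) -> float:
    """Average (not monoisotopic) molecular mass of a protein, in Da.

    Sum of average residue masses plus one water; matches the database
    convention for predicted MW.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    bad = set(sequence) - CANONICAL_RESIDUES
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)}; canonical letters only")
    return float(_pt_mass.calculate_mass(sequence=sequence, average=True))
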