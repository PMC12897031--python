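"""Readers and writers for every external format the pipeline touches.

The tabular dialects follow MaxQuant conventions: residue positions are
1-based, sequence windows are 15-mers centred on the modified lysine and
padded with ``_`` where the protein terminus is closer than seven residues,
and absent label-free intensities may be encoded as an empty cell, ``0`` or
``NaN`` (MaxQuant emits zeros for missing LFQ values).  Parsing is strict:
schema problems name the offending column, value problems name the line.

The PDB reader consumes only what the distance analysis needs: ``ATOM``
records of the first model, altloc blank or ``A``, heavy atoms.  ``HETATM``
chemistry and multi-model ensembles are deliberately out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"
WINDOW_WIDTH = 15
WINDOW_CENTER = 7  # 0-based index of the modified K in a 15-mer window

#: canonical column names of the site-table dialect
COL_PROTEIN = "Protein"
COL_POSITION = "Position"
COL_LOCPROB = "Localization prob"
COL_WINDOW = "Sequence window"
COL_PEPLEN = "Peptide length"  # optional

MISSING_TOKENS = {"", "0", "nan", "NaN", "NAN", "na", "NA"}


class SchemaError(ValueError):
    """A required column is absent from a tabular input."""


class ValidationError(ValueError):
    """A row holds a value outside the dialect's contract."""


class PDBFormatError(ValueError):
    """An ATOM record could not be parsed."""


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

CONTROL = "control"
STARVED = "starved"


@dataclass(frozen=True)
class SampleDesign:
    """Maps sample names to one of exactly two experimental groups.

    ``reference`` is the denominator group of every fold change; it defaults
    to ``"control"`` when that group name is present.
    """

    groups: Mapping[str, str]
    reference: str | None = None

    def __post_init__(self) -> None:
        names = set(self.groups.values())
        if len(names) != 2:
            raise ValueError(f"design must have exactly two groups, got {sorted(names)}")
        for g in names:
            if not any(v == g for v in self.groups.values()):
                raise ValueError(f"group {g!r} is empty")
        ref = self.reference
        if ref is None:
            ref = CONTROL if CONTROL in names else sorted(names)[0]
            object.__setattr__(self, "reference", ref)
        elif ref not in names:
            raise ValueError(f"reference group {ref!r} not in design")

    @property
    def samples(self) -> list[str]:
        return list(self.groups)

    @property
    def group_names(self) -> tuple[str, str]:
        """(reference, treatment) pair."""
        other = next(g for g in dict.fromkeys(self.groups.values()) if g != self.reference)
        return (self.reference, other)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def replicate_index(self, sample: str) -> int:
        """1-based replicate number of a sample within its group."""
        return self.samples_in(self.groups[sample]).index(sample) + 1


def two_group_design(n_per_group: int = 4,
                     control_prefix: str = "GA_C",
                     starved_prefix: str = "GA_S") -> SampleDesign:
    """The study layout: four biological replicates per condition."""
    groups: dict[str, str] = {}
    for i in range(1, n_per_group + 1):
        groups[f"{control_prefix}{i}"] = CONTROL
    for i in range(1, n_per_group + 1):
        groups[f"{starved_prefix}{i}"] = STARVED
    return SampleDesign(groups)


# ---------------------------------------------------------------------------
# site table
# ---------------------------------------------------------------------------


@dataclass
class KbhbSiteRecord:
    """One modified lysine from a MaxQuant-style sites table."""

    protein: str
    position: int  # 1-based residue number of the modified K
    localization_prob: float
    window: str  # 15-mer, centre K, "_"-padded
    intensities: dict[str, float | None]
    peptide_length: int | None = None

    @property
    def site_id(self) -> str:
        return f"{self.protein}_K{self.position}"


def validate_window(window: str) -> None:
    if len(window) != WINDOW_WIDTH:
        raise ValidationError(f"sequence window must be {WINDOW_WIDTH} characters, got {len(window)}")
    if window[WINDOW_CENTER] != "K":
        raise ValidationError(f"window centre must be K, got {window[WINDOW_CENTER]!r}")
    bad = set(window) - set(AA_ALPHABET + PAD)
    if bad:
        raise ValidationError(f"window holds non-residue characters {sorted(bad)}")


def _parse_intensity(token: str) -> float | None:
    token = token.strip()
    if token in MISSING_TOKENS:
        return None
    value = float(token)
    if value <= 0 or not math.isfinite(value):
        return None
    return value


def read_site_table(path: str | Path, design: SampleDesign) -> list[KbhbSiteRecord]:
    """Parse a tab-delimited Kbhb sites table.

    Raises :class:`SchemaError` naming any absent required column and
    :class:`ValidationError` citing 1-based file line numbers for malformed
    rows.  Intensities of ``0``, empty or ``NaN`` become missing values.
    Rows listing several accessions (shared peptides) are assigned to the
    first accession with a logged warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [COL_PROTEIN, COL_POSITION, COL_LOCPROB, COL_WINDOW, *design.samples]
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"{path.name}: required column {col!r} is missing")

    records: list[KbhbSiteRecord] = []
    problems: list[str] = []
    has_peplen = COL_PEPLEN in frame.columns
    for idx, row in enumerate(frame.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        row_map = dict(zip(frame.columns, row))
        try:
            protein = row_map[COL_PROTEIN].strip()
            if ";" in protein:
                first = protein.split(";")[0].strip()
                logger.warning("line %d: shared peptide %r assigned to first accession %s",
                               line_no, protein, first)
                protein = first
            if not protein:
                raise ValidationError("empty protein accession")
            position = int(row_map[COL_POSITION])
            if position < 1:
                raise ValidationError(f"position must be >= 1, got {position}")
            loc_prob = float(row_map[COL_LOCPROB])
            if not 0.0 <= loc_prob <= 1.0:
                raise ValidationError(f"localization probability {loc_prob} outside [0, 1]")
            window = row_map[COL_WINDOW].strip()
            validate_window(window)
            intensities = {s: _parse_intensity(row_map[s]) for s in design.samples}
            pep_len = None
            if has_peplen and row_map[COL_PEPLEN].strip() not in MISSING_TOKENS:
                pep_len = int(row_map[COL_PEPLEN])
            records.append(KbhbSiteRecord(protein, position, loc_prob, window,
                                          intensities, pep_len))
        except (ValueError, ValidationError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise ValidationError(f"{path.name}: {len(problems)} malformed row(s): " + "; ".join(problems))
    return records


def write_site_table(records: Iterable[KbhbSiteRecord], path: str | Path,
                     design: SampleDesign) -> None:
    """Write records in the site-table dialect (missing intensities as empty cells)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            COL_PROTEIN: rec.protein,
            COL_POSITION: rec.position,
            COL_LOCPROB: f"{rec.localization_prob:.4f}",
            COL_WINDOW: rec.window,
        }
        if rec.peptide_length is not None:
            row[COL_PEPLEN] = rec.peptide_length
        for s in design.samples:
            v = rec.intensities.get(s)
            row[s] = "" if v is None else repr(float(v))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def site_records_to_frames(records: Sequence[KbhbSiteRecord],
                           design: SampleDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into a metadata frame and a site x sample intensity matrix.

    Both are indexed by ``site_id``; missing intensities are NaN.
    """
    meta = pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "position": [r.position for r in records],
            "localization_prob": [r.localization_prob for r in records],
            "window": [r.window for r in records],
            "peptide_length": [r.peptide_length for r in records],
        },
        index=[r.site_id for r in records],
    )
    intensities = pd.DataFrame(
        [[np.nan if r.intensities.get(s) is None else r.intensities[s] for s in design.samples]
         for r in records],
        index=meta.index,
        columns=design.samples,
        dtype=float,
    )
    return meta, intensities


# ---------------------------------------------------------------------------
# protein (proteinGroups-style) table
# ---------------------------------------------------------------------------


def read_protein_table(path: str | Path, design: SampleDesign) -> pd.DataFrame:
    """Read an accession x sample LFQ intensity matrix; missing values are NaN."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in [COL_PROTEIN, *design.samples]:
        if col not in frame.columns:
            raise SchemaError(f"{path.name}: required column {col!r} is missing")
    values = frame[design.samples].map(lambda t: _parse_intensity(t))
    out = pd.DataFrame(values.values, columns=design.samples,
                       index=frame[COL_PROTEIN].str.split(";").str[0].str.strip(),
                       dtype=float)
    out.index.name = COL_PROTEIN
    return out


def write_protein_table(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.insert(0, COL_PROTEIN, out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# FASTA / GMT / annotation
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Accession (first whitespace token of the header) -> sequence."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id.split()[0]] = str(rec.seq)
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: ``term<TAB>description<TAB>member...`` per line."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"line {line_no}: GMT line needs term, description and members")
            out[parts[0]] = {m for m in parts[2:] if m}
    return out


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in gene_sets:
            members = sorted(gene_sets[term])
            fh.write("\t".join([term, "na", *members]) + "\n")


def read_annotation(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV: accession -> ';'-separated compartment labels."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"line {line_no}: expected two tab-separated columns")
            out[parts[0]] = [c for c in parts[1].split(";") if c]
    return out


def write_annotation(annotation: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, comps in annotation.items():
            fh.write(f"{acc}\t{';'.join(comps)}\n")


# ---------------------------------------------------------------------------
# PDB subset
# ---------------------------------------------------------------------------


@dataclass
class Residue:
    chain: str
    resnum: int
    name: str
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3) in Angstrom


@dataclass
class ResidueGeometry:
    """Heavy-atom coordinates plus the labelled residue sets of one structure."""

    residues: list[Residue]
    kbhb_lysines: set[int] = field(default_factory=set)
    functional_residues: set[int] = field(default_factory=set)
    ptm_residues: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._index: dict[int, Residue] = {}
        for res in self.residues:
            if res.resnum in self._index:
                raise ValueError(f"duplicate residue number {res.resnum}")
            if not np.all(np.isfinite(res.coords)):
                raise ValueError(f"non-finite coordinates in residue {res.resnum}")
            self._index[res.resnum] = res
        for label, group in (("kbhb", self.kbhb_lysines),
                             ("functional", self.functional_residues),
                             ("ptm", self.ptm_residues)):
            missing = group - set(self._index)
            if missing:
                raise ValueError(f"{label} residues {sorted(missing)} not in structure")

    def residue(self, resnum: int) -> Residue:
        return self._index[resnum]

    @property
    def resnums(self) -> list[int]:
        return [r.resnum for r in self.residues]


def _element_of(atom_name: str, element_field: str) -> str:
    if element_field.strip():
        return element_field.strip().upper()
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


def read_pdb(path: str | Path) -> ResidueGeometry:
    """Parse ATOM records (first model, altloc blank/'A', heavy atoms only)."""
    residues: dict[tuple[str, int], Residue] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            record = line[:6]
            if record == "ENDMDL":
                break  # first model only
            if record != "ATOM  ":
                continue
            try:
                atom_name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                chain = line[21]
                resnum = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise PDBFormatError(f"{Path(path).name}: line {line_no}: unparseable ATOM record ({exc})")
            if altloc not in (" ", "A"):
                continue
            if _element_of(atom_name, line[76:78] if len(line) >= 78 else "") == "H":
                continue
            key = (chain, resnum)
            if key not in residues:
                residues[key] = Residue(chain, resnum, resname, [], np.empty((0, 3)))
            res = residues[key]
            res.atom_names.append(atom_name)
            res.coords = np.vstack([res.coords, [x, y, z]])
    return ResidueGeometry(list(residues.values()))


def write_pdb(geometry: ResidueGeometry, path: str | Path) -> None:
    serial = 0
    with open(path, "w") as fh:
        for res in geometry.residues:
            for atom_name, (x, y, z) in zip(res.atom_names, res.coords):
                serial += 1
                name_field = atom_name if len(atom_name) == 4 else f" {atom_name:<3s}"
                element = _element_of(atom_name, "")
                fh.write(
                    f"ATOM  {serial:5d} {name_field} {res.name:<3s} {res.chain}{res.resnum:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}\n"
                )
        fh.write("END\n")


def read_structure_labels(path: str | Path) -> dict[str, set[int]]:
    """TSV of ``resnum<TAB>label`` rows; labels are kbhb, functional or ptm."""
    out: dict[str, set[int]] = {"kbhb": set(), "functional": set(), "ptm": set()}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in out:
                raise ValidationError(f"line {line_no}: expected 'resnum<TAB>kbhb|functional|ptm'")
            out[parts[1]].add(int(parts[0]))
    return out


def write_structure_labels(labels: Mapping[str, Iterable[int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for label in ("kbhb", "functional", "ptm"):
            for resnum in sorted(labels.get(label, ())):
                fh.write(f"{resnum}\t{label}\n")
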