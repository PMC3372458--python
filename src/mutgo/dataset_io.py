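"""Readers and writers for variant tables, FASTA, GO annotations and PSSMs.

All formats are plain text.  Writers emit exactly the dialect the parsers
read, so every file round-trips bit-identically on its semantic fields.
"""

from __future__ import annotations

import re
from collections import OrderedDict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from Bio import SeqIO

#: PSI-BLAST column order; also the index order of every 20-vector here.
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

GO_TERM_RE = re.compile(r"^GO:\d{7}$")
ASPECTS = ("C", "F", "P")


class Label(str, Enum):
    """Disease class of a variation."""

    CANCER = "CANCER"
    OTHER = "OTHER"
    UNLABELLED = "UNLABELLED"


class Origin(str, Enum):
    GERMLINE = "GERMLINE"
    SOMATIC = "SOMATIC"
    UNKNOWN = "UNKNOWN"


class ParseError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """A record violates a dataset invariant."""


@dataclass(frozen=True)
class VariantRecord:
    """One amino-acid substitution on a protein, with its disease label.

    Positions are 1-based along the protein sequence, following the
    UniProtKB variant annotation convention.
    """

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    label: Label = Label.UNLABELLED
    origin: Origin = Origin.UNKNOWN

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_INDEX or self.mut_aa not in AA_INDEX:
            raise ValidationError(
                f"non-standard residue in {self.protein_id} "
                f"{self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.wt_aa == self.mut_aa:
            raise ValidationError(
                f"wild-type equals mutant residue at {self.protein_id} "
                f"position {self.position}"
            )
        if self.position < 1:
            raise ValidationError(
                f"position must be >= 1, got {self.position} for {self.protein_id}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity triple; unique within a dataset."""
        return (self.protein_id, self.position, self.mut_aa)


@dataclass
class GoAnnotationSet:
    """GO terms of one protein, partitioned by sub-ontology aspect.

    Every aspect key (C, F, P) is always present, possibly with an empty
    set; a term belongs to exactly one aspect.
    """

    protein_id: str
    terms_by_aspect: dict[str, set[str]] = field(
        default_factory=lambda: {a: set() for a in ASPECTS}
    )

    def __post_init__(self) -> None:
        for aspect in ASPECTS:
            self.terms_by_aspect.setdefault(aspect, set())
        seen: dict[str, str] = {}
        for aspect, terms in self.terms_by_aspect.items():
            if aspect not in ASPECTS:
                raise ValidationError(
                    f"unknown GO aspect {aspect!r} for {self.protein_id}"
                )
            for term in terms:
                if not GO_TERM_RE.match(term):
                    raise ValidationError(
                        f"malformed GO identifier {term!r} for {self.protein_id}"
                    )
                if term in seen and seen[term] != aspect:
                    raise ValidationError(
                        f"term {term} of {self.protein_id} appears under "
                        f"aspects {seen[term]} and {aspect}"
                    )
                seen[term] = aspect

    def add(self, term: str, aspect: str) -> None:
        if aspect not in ASPECTS:
            raise ValidationError(f"unknown GO aspect {aspect!r}")
        if not GO_TERM_RE.match(term):
            raise ValidationError(f"malformed GO identifier {term!r}")
        for other in ASPECTS:
            if other != aspect and term in self.terms_by_aspect[other]:
                raise ValidationError(
                    f"term {term} of {self.protein_id} appears under "
                    f"aspects {other} and {aspect}"
                )
        self.terms_by_aspect[aspect].add(term)


@dataclass
class PssmProfile:
    """Per-position substitution log-odds and observed frequencies.

    ``logodds[i]`` holds 20 integers on the legacy PSI-BLAST scale and
    ``freqs[i]`` 20 weighted observed percentages in [0, 100], both in
    the column order of :data:`AA_ALPHABET` as recorded in the file
    header.  ``residues[i]`` is the sequence residue at position i+1.
    """

    protein_id: str
    residues: str
    logodds: list[list[int]]
    freqs: list[list[float]]

    def __post_init__(self) -> None:
        n = len(self.residues)
        if len(self.logodds) != n or len(self.freqs) != n:
            raise ValidationError(
                f"profile {self.protein_id}: row counts disagree with length {n}"
            )
        for i in range(n):
            if len(self.logodds[i]) != 20 or len(self.freqs[i]) != 20:
                raise ValidationError(
                    f"profile {self.protein_id}: position {i + 1} does not "
                    "have 20 log-odds and 20 frequencies"
                )

    @property
    def length(self) -> int:
        return len(self.residues)

    def logodds_at(self, position: int, aa: str) -> int:
        """Log-odds for residue ``aa`` at 1-based ``position``."""
        return self.logodds[position - 1][AA_INDEX[aa]]

    def freq_at(self, position: int, aa: str) -> float:
        return self.freqs[position - 1][AA_INDEX[aa]]


SequenceSet = dict  # protein_id -> sequence string

_VARIANT_COLUMNS = ("protein_id", "position", "wt_aa", "mut_aa", "label", "origin")


def parse_variant_table(
    path: str | Path,
    exclude_origins: Iterable[Origin] = (),
    row_adapter: Callable[[dict[str, str]], dict[str, str]] | None = None,
) -> list[VariantRecord]:
    """Read a tab-separated variant table.

    The expected header names at least ``protein_id``, ``position``,
    ``wt_aa``, ``mut_aa`` and ``label``; ``origin`` is optional and
    defaults to UNKNOWN.  ``row_adapter`` is a converter hook: it
    receives the raw column mapping of each row and may rename or
    synthesise fields, which adapts other column layouts without a
    separate parser.

    Records whose origin is in ``exclude_origins`` are dropped.
    Duplicate (protein, position, mutant) triples raise
    :class:`ValidationError` — the dataset must be non-ambiguous, each
    mutated residue univocally associated with one disease class.
    """
    exclude = {Origin(o) for o in exclude_origins}
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ParseError(f"{path}: empty file, expected a header line")
        header = header_line.rstrip("\n").split("\t")
        records: list[VariantRecord] = []
        seen: set[tuple[str, int, str]] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(header, fields))
            if row_adapter is not None:
                row = row_adapter(row)
            missing = [c for c in _VARIANT_COLUMNS[:5] if c not in row]
            if missing:
                raise ParseError(f"{path}:{lineno}: missing columns {missing}")
            try:
                rec = VariantRecord(
                    protein_id=row["protein_id"],
                    position=int(row["position"]),
                    wt_aa=row["wt_aa"],
                    mut_aa=row["mut_aa"],
                    label=Label(row["label"]),
                    origin=Origin(row.get("origin", "UNKNOWN")),
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if rec.origin in exclude:
                continue
            if rec.key in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate variation "
                    f"{rec.protein_id} {rec.wt_aa}{rec.position}{rec.mut_aa}"
                )
            seen.add(rec.key)
            records.append(rec)
    return records


def write_variant_table(path: str | Path, records: Sequence[VariantRecord]) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_VARIANT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.protein_id}\t{r.position}\t{r.wt_aa}\t{r.mut_aa}\t"
                f"{r.label.value}\t{r.origin.value}\n"
            )


def parse_go_annotations(path: str | Path, dialect: str = "TSV") -> list[GoAnnotationSet]:
    """Read GO annotations in GAF 2.x or three-column TSV dialect.

    The TSV dialect has columns ``protein_id``, ``term``, ``aspect``
    (header optional); GAF follows the standard column order with the
    DB object identifier in column 2, the GO identifier in column 5 and
    the aspect in column 9.  Duplicated (protein, term) pairs collapse
    to a single entry.  Returns one :class:`GoAnnotationSet` per
    distinct protein, in order of first appearance.
    """
    path = Path(path)
    dialect = dialect.upper()
    if dialect not in {"TSV", "GAF"}:
        raise ValueError(f"unknown GO dialect {dialect!r}")
    sets: "OrderedDict[str, GoAnnotationSet]" = OrderedDict()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if dialect == "TSV":
                if fields == ["protein_id", "term", "aspect"]:
                    continue
                if len(fields) != 3:
                    raise ParseError(
                        f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                    )
                protein, term, aspect = fields
            else:
                if len(fields) < 9:
                    raise ParseError(
                        f"{path}:{lineno}: GAF line with {len(fields)} columns"
                    )
                protein, term, aspect = fields[1], fields[4], fields[8]
            if aspect not in ASPECTS:
                raise ValidationError(
                    f"{path}:{lineno}: aspect {aspect!r} not one of C/F/P"
                )
            if not GO_TERM_RE.match(term):
                raise ValidationError(
                    f"{path}:{lineno}: malformed GO identifier {term!r}"
                )
            annset = sets.setdefault(protein, GoAnnotationSet(protein_id=protein))
            try:
                annset.add(term, aspect)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return list(sets.values())


def write_go_annotations(path: str | Path, sets: Sequence[GoAnnotationSet]) -> None:
    """Write annotations in the three-column TSV dialect (sorted within protein)."""
    with Path(path).open("w") as fh:
        fh.write("protein_id\tterm\taspect\n")
        for s in sets:
            for aspect in ASPECTS:
                for term in sorted(s.terms_by_aspect[aspect]):
                    fh.write(f"{s.protein_id}\t{term}\t{aspect}\n")


def parse_fasta(path: str | Path) -> SequenceSet:
    """Read a multi-FASTA into an id -> sequence mapping.

    The identifier is the first whitespace-delimited token after ``>``.
    Sequences may contain the 20 standard letters plus X; duplicate
    identifiers and empty sequences are errors.
    """
    path = Path(path)
    sequences: SequenceSet = {}
    allowed = set(AA_ALPHABET + "X")
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if record.id in sequences:
            raise ValidationError(f"{path}: duplicate identifier {record.id!r}")
        if not seq:
            raise ValidationError(f"{path}: empty sequence for {record.id!r}")
        bad = set(seq) - allowed
        if bad:
            raise ValidationError(
                f"{path}: sequence {record.id!r} contains {sorted(bad)}"
            )
        sequences[record.id] = seq
    return sequences


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_PSSM_HEADER = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts"
)


def parse_pssm(path: str | Path, protein_id: str | None = None) -> PssmProfile:
    """Read a legacy PSI-BLAST ``-Q`` ASCII profile.

    The format is a banner line, a header row naming the 40 amino-acid
    columns (20 log-odds, 20 frequencies), then one row per position:
    index, residue, 20 integers, 20 frequency percentages (two optional
    trailing statistics per row are ignored).  The residue column is
    retained so callers can cross-validate the profile against FASTA.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    residues: list[str] = []
    logodds: list[list[int]] = []
    freqs: list[list[float]] = []
    alphabet: str | None = None
    expected_index = 1
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if alphabet is None:
                if len(fields) == 40 and all(f in AA_INDEX for f in fields):
                    first = "".join(fields[:20])
                    second = "".join(fields[20:])
                    if first != second:
                        raise ParseError(
                            f"{path}:{lineno}: log-odds and frequency column "
                            "orders differ"
                        )
                    alphabet = first
                continue
            if not fields[0].isdigit():
                continue  # trailing statistics block
            if len(fields) not in (42, 44):
                raise ParseError(
                    f"{path}:{lineno}: expected 42 fields "
                    f"(index, residue, 40 numbers), got {len(fields)}"
                )
            index = int(fields[0])
            if index != expected_index:
                raise ParseError(
                    f"{path}:{lineno}: non-monotonic position index {index}, "
                    f"expected {expected_index}"
                )
            expected_index += 1
            residue = fields[1]
            try:
                row_lo = [int(x) for x in fields[2:22]]
                row_fr = [float(x) for x in fields[22:42]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            perm = None
            if alphabet != AA_ALPHABET:
                perm = [alphabet.index(aa) for aa in AA_ALPHABET]
                row_lo = [row_lo[j] for j in perm]
                row_fr = [row_fr[j] for j in perm]
            residues.append(residue)
            logodds.append(row_lo)
            freqs.append(row_fr)
    if alphabet is None:
        raise ParseError(f"{path}: no amino-acid column header found")
    if not residues:
        raise ParseError(f"{path}: no position rows found")
    return PssmProfile(
        protein_id=protein_id, residues="".join(residues), logodds=logodds, freqs=freqs
    )


def write_pssm(path: str | Path, profile: PssmProfile) -> None:
    """Emit the same legacy ``-Q`` ASCII dialect :func:`parse_pssm` reads."""
    cols = "  ".join(AA_ALPHABET)
    with Path(path).open("w") as fh:
        fh.write(_PSSM_HEADER + "\n")
        fh.write("            " + cols + "   " + cols + "\n")
        for i in range(profile.length):
            lo = " ".join(f"{v:3d}" for v in profile.logodds[i])
            fr = " ".join(f"{v:3.0f}" for v in profile.freqs[i])
            fh.write(f"{i + 1:5d} {profile.residues[i]}  {lo}  {fr}\n")


def load_pssm_dir(
    directory: str | Path, protein_ids: Iterable[str], suffix: str = ".pssm"
) -> dict[str, PssmProfile]:
    """Load one ``<protein_id><suffix>`` profile per requested protein."""
    directory = Path(directory)
    profiles: dict[str, PssmProfile] = {}
    for pid in protein_ids:
        fp = directory / f"{pid}{suffix}"
        if not fp.exists():
            raise FileNotFoundError(f"no profile for protein {pid!r} at {fp}")
        profiles[pid] = parse_pssm(fp, protein_id=pid)
    return profiles


def check_consistency(
    variants: Sequence[VariantRecord], sequences: Mapping[str, str]
) -> tuple[list[VariantRecord], list[str]]:
    """Split variants into (valid, problem report lines) against sequences.

    A variant is invalid when its protein has a sequence and either the
    position exceeds the sequence length or the sequence residue differs
    from the annotated wild type.  An X at the variant position is
    treated as unverifiable and excluded too.  Violations are reported,
    never silently dropped: callers log the report.
    """
    valid: list[VariantRecord] = []
    problems: list[str] = []
    for v in variants:
        seq = sequences.get(v.protein_id)
        if seq is None:
            valid.append(v)
            continue
        if v.position > len(seq):
            problems.append(
                f"{v.protein_id}: position {v.position} beyond sequence "
                f"length {len(seq)}"
            )
        elif seq[v.position - 1] == "X":
            problems.append(
                f"{v.protein_id}: position {v.position} is X in the sequence"
            )
        elif seq[v.position - 1] != v.wt_aa:
            problems.append(
                f"{v.protein_id}: sequence has {seq[v.position - 1]} at "
                f"position {v.position}, variant says {v.wt_aa}"
            )
        else:
            valid.append(v)
    return valid, problems
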