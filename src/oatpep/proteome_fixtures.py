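"""Packaged oat proteome fixtures and synthetic protein generation.

The eight main storage proteins of common oat (*Avena sativa*) — the 11S and
12S globulins, five avenins and tryptophanin/2S albumin — ship with the
package as a FASTA file keyed by UniProt accession, together with a table of
peptides previously reported as ACE-I or DPP-IV inhibitors in the BIOPEP
database.  A seeded random-protein generator and a motif implanter provide
substrates with known ground truth for testing the digestion engine.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids (one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Alphabet accepted in protein sequences: the 20 standard residues plus
#: 'X' for an undetermined position (present in the Avenin-A fixture).
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}

#: The nine candidate peptides selected for chemical synthesis in the study
#: this pipeline reproduces.
NOVEL_PEPTIDES = (
    "FFG", "IFFFL", "PFL", "WWK", "WCY", "FPIL", "CPA", "FLLA", "FEPL",
)

# SHA-256 of the concatenation of the eight fixture sequences, recorded when
# the fixtures were packaged; load_oat_proteins() refuses corrupted data.
_FIXTURE_SHA256 = "cd54f6e6fc29f1477dc89287991b23ee965270211fb8f58c67aa9c7604785701"

_DATA = resources.files("oatpep") / "data"


class FixtureIntegrityError(RuntimeError):
    """Packaged fixture data does not match its recorded checksum."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence, the substrate of digestion."""

    id: str
    name: str
    uniprot_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("protein sequence must be non-empty")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(f"invalid residue(s) in {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class KnownPeptideEntry:
    """One row of the known-bioactive-peptide table.

    The same sequence may appear under several BIOPEP identifiers (PG is
    listed three times, PL twice); ``(sequence, biopep_id)`` is unique.
    ``ic50_um`` is None where no IC50 has been reported.  ``ranker_score``
    carries the externally computed PeptideRanker score as an annotation
    only — no scoring model is implemented here.
    """

    sequence: str
    biopep_id: int
    activity: str  # "ACE-I inhibitor" | "DPP-IV inhibitor" | "other"
    ic50_um: float | None
    printed_mass_da: float
    ranker_score: float | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError("known peptides are at least dipeptides")
        if self.printed_mass_da <= 0:
            raise ValueError("printed mass must be positive")
        if self.ic50_um is not None and self.ic50_um <= 0:
            raise ValueError("IC50 must be positive when present")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    Headers of the form ``>ACCESSION|short_id free text name`` populate all
    three identifier fields; a plain header is used for id and name alike,
    with an empty accession.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" in rec.id:
            acc, short = rec.id.split("|", 1)
        else:
            acc, short = "", rec.id
        name = rec.description.split(None, 1)[1] if " " in rec.description else short
        records.append(ProteinRecord(id=short, name=name, uniprot_id=acc,
                                     sequence=str(rec.seq).upper()))
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA with ``>acc|id name`` headers."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=f"{r.uniprot_id}|{r.id}" if r.uniprot_id else r.id,
                  description=r.name)
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=60)
    writer.write_file(seqrecords)


def _check_unique_ids(records: Sequence[ProteinRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate protein id {r.id!r}")
        seen.add(r.id)


def load_oat_proteins() -> list[ProteinRecord]:
    """Load the eight packaged oat storage proteins, in stable table order.

    Raises :class:`FixtureIntegrityError` if the packaged sequences do not
    hash to the checksum recorded at packaging time.
    """
    with resources.as_file(_DATA / "oat_storage_proteins.fasta") as p:
        records = read_fasta(p)
    digest = hashlib.sha256("".join(r.sequence for r in records).encode()).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            "packaged oat protein fixtures are corrupted "
            f"(sha256 {digest} != {_FIXTURE_SHA256})"
        )
    return records


def load_known_peptides() -> list[KnownPeptideEntry]:
    """Load the packaged table of previously reported oat peptides (19 rows)."""
    entries: list[KnownPeptideEntry] = []
    text = (_DATA / "known_peptides.tsv").read_text()
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        entries.append(
            KnownPeptideEntry(
                sequence=row["sequence"],
                biopep_id=int(row["biopep_id"]),
                activity=row["activity"],
                ic50_um=float(row["ic50_um"]) if row["ic50_um"] else None,
                printed_mass_da=float(row["mass_da"]),
                ranker_score=float(row["ranker_score"]) if row["ranker_score"] else None,
            )
        )
    keys = [(e.sequence, e.biopep_id) for e in entries]
    if len(set(keys)) != len(keys):
        raise FixtureIntegrityError("duplicate (sequence, biopep_id) in known-peptide table")
    return entries


@dataclass(frozen=True)
class NovelPeptideAnnotation:
    """Published screen annotations for one synthesised candidate peptide.

    ``toxicity`` and ``allergenicity`` come from external trained predictors
    and are carried as annotations only — nothing in this package computes
    them.  ``solubility`` and ``resistant_to_digestion`` are the published
    calls that the calculators in this package reproduce.
    """

    peptide: str
    solubility: str               # "good" | "poor"
    resistant_to_digestion: bool
    toxicity: str
    allergenicity: str


def load_novel_peptide_annotations() -> list[NovelPeptideAnnotation]:
    """Published per-candidate annotations for the nine synthesised peptides."""
    out = []
    lines = (_DATA / "novel_peptide_annotations.tsv").read_text().strip().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        out.append(NovelPeptideAnnotation(
            peptide=row["peptide"],
            solubility=row["solubility"],
            resistant_to_digestion=row["resistant_to_digestion"] == "yes",
            toxicity=row["toxicity"],
            allergenicity=row["allergenicity"],
        ))
    return out


def validation_peptides() -> list[str]:
    """Distinct validation sequences: known peptides plus the nine candidates."""
    known = {e.sequence for e in load_known_peptides()}
    out = sorted(known)
    out.extend(p for p in NOVEL_PEPTIDES if p not in known)
    return out


def random_protein(
    length: int,
    composition: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    record_id: str = "synthetic",
) -> ProteinRecord:
    """Generate a reproducible random protein with a given residue composition.

    Parameters
    ----------
    length
        Number of residues (>= 1).
    composition
        Map residue -> non-negative weight; weights are normalised.  ``None``
        means uniform over the 20 standard residues.
    seed
        Integer seed or a ``numpy.random.Generator``; the same seed always
        yields the same sequence.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if composition is None:
        composition = {aa: 1.0 for aa in AMINO_ACIDS}
    if not composition:
        raise ValueError("composition must name at least one residue")
    residues = sorted(composition)
    bad = set(residues) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"composition names non-standard residues: {sorted(bad)}")
    weights = np.array([composition[r] for r in residues], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = "".join(rng.choice(list(residues), size=length, p=weights / weights.sum()))
    return ProteinRecord(id=record_id, name="synthetic protein",
                         uniprot_id="", sequence=seq)


def implant_motif(record: ProteinRecord, motif: str, position: int) -> ProteinRecord:
    """Return a copy of ``record`` with ``motif`` overwriting the window at
    ``position`` (0-based); length is unchanged."""
    if not motif or set(motif) - SEQUENCE_ALPHABET:
        raise ValueError("motif must be a non-empty standard-residue string")
    if not 0 <= position <= len(record) - len(motif):
        raise ValueError(
            f"position {position} out of range for motif of length {len(motif)} "
            f"in sequence of length {len(record)}"
        )
    seq = record.sequence
    return ProteinRecord(
        id=record.id, name=record.name, uniprot_id=record.uniprot_id,
        sequence=seq[:position] + motif + seq[position + len(motif):],
    )
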