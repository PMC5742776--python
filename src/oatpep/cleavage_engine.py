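"""Data-driven protease specificity simulation.

A protease is modelled as a :class:`CleavageRuleSet` — positional constraints
in Schechter–Berger notation (P4…P2′ around the scissile bond) read from a
plain-text rule file.  Digestion is exhaustive: every bond matched by a rule
(and by no exception) is cut, i.e. no missed-cleavage combinatorics.

Bond ``i`` lies between residues ``i`` and ``i+1`` (0-based); peptide
coordinates are 0-based half-open.  A constrained position that falls outside
the sequence makes the rule not match at that bond, and the undetermined
residue 'X' matches no residue set, so no bond adjacent to an X is ever cut.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .proteome_fixtures import AMINO_ACIDS, SEQUENCE_ALPHABET, ProteinRecord

#: Offset of each position label relative to bond i (P1 = residue i).
_POSITION_OFFSETS = {"P4": -3, "P3": -2, "P2": -1, "P1": 0, "P1'": 1, "P2'": 2}

#: Release proteases of the reproduced workflow.
RELEASE_ENZYMES = ("papain", "ficin")

#: The five-enzyme gastrointestinal panel used for resistance prediction.
GI_PANEL_ENZYMES = (
    "chymotrypsin_low", "chymotrypsin_high", "pepsin_ph1_3", "pepsin_ph2", "trypsin",
)

_RULES_DIR = resources.files("oatpep") / "data" / "rules"


@dataclass(frozen=True)
class PositionalRule:
    """Residue-set constraints on positions around the scissile bond.

    ``constraints`` maps a label in {P4, P3, P2, P1, P1', P2'} to the set of
    residues allowed there; absent labels are unconstrained.  Either P1 or P1'
    must be constrained so the rule anchors the bond.
    """

    constraints: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        bad = set(self.constraints) - set(_POSITION_OFFSETS)
        if bad:
            raise ValueError(f"unknown position label(s): {sorted(bad)}")
        if "P1" not in self.constraints and "P1'" not in self.constraints:
            raise ValueError("a rule must constrain P1 or P1'")
        for label, residues in self.constraints.items():
            if not residues or not residues <= set(AMINO_ACIDS):
                raise ValueError(
                    f"{label} set must be a non-empty subset of the 20 standard residues"
                )

    def matches(self, sequence: str, bond: int) -> bool:
        """True iff every constrained position exists and its residue is allowed."""
        for label, residues in self.constraints.items():
            pos = bond + _POSITION_OFFSETS[label]
            if not 0 <= pos < len(sequence):
                return False
            if sequence[pos] not in residues:  # 'X' is in no set
                return False
        return True


@dataclass(frozen=True)
class CleavageRuleSet:
    """A named protease specificity: positive rules plus exception patterns.

    A bond is cut iff some rule matches it and no exception matches it.
    """

    enzyme_name: str
    rules: tuple[PositionalRule, ...]
    exceptions: tuple[PositionalRule, ...] = ()

    def __post_init__(self) -> None:
        if not self.enzyme_name:
            raise ValueError("enzyme_name must be non-empty")
        if not self.rules:
            raise ValueError("a rule set needs at least one rule")

    def cuts(self, sequence: str, bond: int) -> bool:
        if any(e.matches(sequence, bond) for e in self.exceptions):
            return False
        return any(r.matches(sequence, bond) for r in self.rules)


@dataclass(frozen=True)
class Peptide:
    """A released fragment with provenance."""

    sequence: str
    source_id: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    released_by: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with its sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestResult:
    """Outcome of one exhaustive digestion of one protein."""

    source_id: str
    enzyme_name: str
    cut_sites: tuple[int, ...]
    peptides: tuple[Peptide, ...]


@dataclass(frozen=True)
class ResistanceReport:
    """Per-enzyme internal cleavage sites found in a peptide."""

    resistant: bool
    sites_by_enzyme: Mapping[str, tuple[int, ...]]


_SET_RE = re.compile(r"^(P[1-4]'?)=(!?)\{([A-Z,]*)\}$")


def _parse_rule_line(line: str, lineno: int) -> PositionalRule:
    constraints: dict[str, frozenset[str]] = {}
    for token in line.split()[1:]:
        m = _SET_RE.match(token)
        if not m:
            raise ValueError(f"line {lineno}: cannot parse constraint {token!r}")
        label, negated, body = m.groups()
        residues = frozenset(r for r in body.split(",") if r)
        if negated:
            residues = frozenset(AMINO_ACIDS) - residues
        constraints[label] = residues
    return PositionalRule(constraints)


def parse_rules(text: str, default_name: str = "") -> CleavageRuleSet:
    """Parse a rule file.

    Line-oriented format::

        # comment
        NAME trypsin
        RULE P1={K,R} P1'=!{P}
        EXCEPT P2={C} P1={K} P1'={D}

    ``!{...}`` denotes the complement of the listed residues within the 20
    standard amino acids.
    """
    name = default_name
    rules: list[PositionalRule] = []
    exceptions: list[PositionalRule] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        keyword = line.split()[0]
        if keyword == "NAME":
            name = line.split(None, 1)[1].strip()
        elif keyword == "RULE":
            rules.append(_parse_rule_line(line, lineno))
        elif keyword == "EXCEPT":
            exceptions.append(_parse_rule_line(line, lineno))
        else:
            raise ValueError(f"line {lineno}: unknown directive {keyword!r}")
    return CleavageRuleSet(enzyme_name=name, rules=tuple(rules),
                           exceptions=tuple(exceptions))


def load_enzyme(name: str, rules_dir: str | Path | None = None) -> CleavageRuleSet:
    """Load ``<name>.rules`` from ``rules_dir`` (default: the packaged tables)."""
    if rules_dir is None:
        try:
            text = (_RULES_DIR / f"{name}.rules").read_text()
        except FileNotFoundError:
            raise FileNotFoundError(f"no packaged rule table for enzyme {name!r}") from None
    else:
        path = Path(rules_dir) / f"{name}.rules"
        if not path.exists():
            raise FileNotFoundError(f"no rule file for enzyme {name!r} in {rules_dir}")
        text = path.read_text()
    return parse_rules(text, default_name=name)


def gi_panel(rules_dir: str | Path | None = None) -> list[CleavageRuleSet]:
    """The default five-enzyme gastrointestinal resistance panel."""
    return [load_enzyme(n, rules_dir) for n in GI_PANEL_ENZYMES]


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = set(sequence) - SEQUENCE_ALPHABET
    if bad:
        raise ValueError(f"unknown residue(s): {sorted(bad)}")


def find_cleavage_sites(sequence: str, rules: CleavageRuleSet) -> list[int]:
    """All bond indices cut by ``rules``; strictly increasing, internal bonds only."""
    _validate_sequence(sequence)
    return [b for b in range(len(sequence) - 1) if rules.cuts(sequence, b)]


def digest(record: ProteinRecord | str, rules: CleavageRuleSet) -> DigestResult:
    """Exhaustively digest one protein: every matching bond is cut."""
    if isinstance(record, str):
        record = ProteinRecord(id="synthetic", name="ad hoc substrate",
                               uniprot_id="", sequence=record)
    sites = find_cleavage_sites(record.sequence, rules)
    bounds = [0] + [s + 1 for s in sites] + [len(record.sequence)]
    peptides = tuple(
        Peptide(sequence=record.sequence[a:b], source_id=record.id,
                start=a, end=b, released_by=rules.enzyme_name)
        for a, b in zip(bounds, bounds[1:])
    )
    return DigestResult(source_id=record.id, enzyme_name=rules.enzyme_name,
                        cut_sites=tuple(sites), peptides=peptides)


def digest_many(
    records: Iterable[ProteinRecord],
    enzymes: Sequence[CleavageRuleSet],
) -> dict[str, list[Peptide]]:
    """Pooled unique peptides of all (record × enzyme) digests.

    Returns an ordered mapping sequence -> every provenance that released it,
    sorted by sequence, then (source, start, enzyme).
    """
    records = list(records)
    if not records or not enzymes:
        raise ValueError("digest_many needs at least one record and one enzyme")
    pooled: dict[str, list[Peptide]] = {}
    for record in records:
        for enzyme in enzymes:
            for pep in digest(record, enzyme).peptides:
                pooled.setdefault(pep.sequence, []).append(pep)
    return {
        seq: sorted(set(pooled[seq]),
                    key=lambda p: (p.source_id, p.start, p.released_by))
        for seq in sorted(pooled)
    }


def is_resistant(
    peptide: Peptide | str,
    panel: Sequence[CleavageRuleSet],
) -> ResistanceReport:
    """Predict survival of gastrointestinal digestion.

    A peptide is resistant iff no panel enzyme cuts any *internal* bond of its
    sequence; a residue that would be cut after the final position releases
    nothing and is not counted.
    """
    if not panel:
        raise ValueError("resistance panel must not be empty")
    sequence = peptide.sequence if isinstance(peptide, Peptide) else peptide
    _validate_sequence(sequence)
    sites = {e.enzyme_name: tuple(find_cleavage_sites(sequence, e)) for e in panel}
    return ResistanceReport(
        resistant=all(not s for s in sites.values()),
        sites_by_enzyme=sites,
    )


def oracle_digest(sequence: str, rules: CleavageRuleSet) -> list[str]:
    """Naive re-implementation of exhaustive digestion, for verification only.

    Re-derives every fragment by explicit per-bond window slicing and
    straight-line loops, sharing no matching code with the engine above.
    """
    _validate_sequence(sequence)
    cut_after = []
    for bond in range(len(sequence) - 1):
        matched = False
        for rule in rules.rules:
            ok = True
            for label in rule.constraints:
                pos = bond + _POSITION_OFFSETS[label]
                window = sequence[pos: pos + 1] if pos >= 0 else ""
                if window == "" or window not in rule.constraints[label]:
                    ok = False
                    break
            if ok:
                matched = True
                break
        if matched:
            for exc in rules.exceptions:
                ok = True
                for label in exc.constraints:
                    pos = bond + _POSITION_OFFSETS[label]
                    window = sequence[pos: pos + 1] if pos >= 0 else ""
                    if window == "" or window not in exc.constraints[label]:
                        ok = False
                        break
                if ok:
                    matched = False
                    break
        if matched:
            cut_after.append(bond)
    fragments = []
    begin = 0
    for bond in cut_after:
        fragments.append(sequence[begin: bond + 1])
        begin = bond + 1
    fragments.append(sequence[begin:])
    return fragments
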