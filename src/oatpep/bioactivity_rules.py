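"""Positional bioactivity criteria, known-peptide matching and candidate ranking.

The selection criteria encode the published positional characteristics of
renin-, ACE-I- and DPP-IV-inhibitory peptides: residue sets for the
N-terminal residue (N1), the second residue (N2) and the C-terminal residue
(C), plus the Xaa-Pro motif for DPP-IV (proline at the second residue from
the N-terminus, the canonical DPP-IV substrate signature).

The literature describes the per-position preferences but not how they
combine, so the combination policy is explicit and configurable.  Defaults:

* renin   — N1 (hydrophobic) AND C (bulky);
* ACE-I   — (N1 or N2) AND any C alternative;
* DPP-IV  — N1 OR the Xaa-Pro motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .cleavage_engine import Peptide
from .peptide_chem import PeptideProperties
from .proteome_fixtures import KnownPeptideEntry, ProteinRecord

TARGETS = ("renin", "ace", "dppiv")


@dataclass(frozen=True)
class BioactivityCriterion:
    """Positional residue-set criteria for one enzyme target.

    ``n1_sets`` / ``n2_sets`` / ``c_sets`` each list alternative residue sets
    (a position passes when the residue is in any alternative; an empty list
    means the position is unconstrained, as for the renin and DPP-IV N2).
    ``xaa_pro_motif`` enables the proline-at-position-2 check.
    """

    target: str
    n1_sets: tuple[frozenset[str], ...] = ()
    n2_sets: tuple[frozenset[str], ...] = ()
    c_sets: tuple[frozenset[str], ...] = ()
    xaa_pro_motif: bool = False


#: Renin: hydrophobic N-terminus, bulky C-terminus.
RENIN_CRITERION = BioactivityCriterion(
    target="renin",
    n1_sets=(frozenset("AGVLIPFMW"),),
    c_sets=(frozenset("WVILYMF"),),
)

#: ACE-I: small hydrophobic N1 or charged/lipophilic N2; C-terminal
#: alternatives are aromatic (P/F/W), Leu, positively charged (K/R), or Pro.
ACE_CRITERION = BioactivityCriterion(
    target="ace",
    n1_sets=(frozenset("VIL"),),
    n2_sets=(frozenset("LR"),),
    c_sets=(frozenset("PFW"), frozenset("L"), frozenset("KR"), frozenset("P")),
)

#: DPP-IV: hydrophobic/aromatic N1 or the Xaa-Pro motif; C-terminal Pro/Ala.
DPPIV_CRITERION = BioactivityCriterion(
    target="dppiv",
    n1_sets=(frozenset("LIVFWY"),),
    c_sets=(frozenset("PA"),),
    xaa_pro_motif=True,
)

CRITERIA: dict[str, BioactivityCriterion] = {
    "renin": RENIN_CRITERION,
    "ace": ACE_CRITERION,
    "dppiv": DPPIV_CRITERION,
}


@dataclass(frozen=True)
class CriteriaResult:
    """Per-position outcome of one criterion on one peptide."""

    target: str
    n1_pass: bool
    n2_pass: bool
    c_pass: bool
    motif_pass: bool
    satisfied_alternatives: int
    overall_pass: bool
    reason: str = ""


PolicyFn = Callable[[CriteriaResult], bool]

DEFAULT_POLICY: dict[str, PolicyFn] = {
    "renin": lambda r: r.n1_pass and r.c_pass,
    "ace": lambda r: (r.n1_pass or r.n2_pass) and r.c_pass,
    "dppiv": lambda r: r.n1_pass or r.motif_pass,
}


def _position_pass(residue: str, alternatives: Sequence[frozenset[str]]) -> bool:
    if not alternatives:  # unconstrained position passes vacuously
        return True
    return any(residue in s for s in alternatives)


def evaluate_criteria(
    peptide: str,
    target: str,
    policy: Mapping[str, PolicyFn] | None = None,
) -> CriteriaResult:
    """Evaluate one target's positional criteria on one peptide sequence.

    Peptides shorter than two residues fail with reason "too short".
    """
    if target not in CRITERIA:
        raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
    crit = CRITERIA[target]
    policy_fn = (policy or DEFAULT_POLICY)[target]
    if len(peptide) < 2:
        return CriteriaResult(target=target, n1_pass=False, n2_pass=False,
                              c_pass=False, motif_pass=False,
                              satisfied_alternatives=0, overall_pass=False,
                              reason="too short")
    n1 = _position_pass(peptide[0], crit.n1_sets)
    n2 = _position_pass(peptide[1], crit.n2_sets)
    c = _position_pass(peptide[-1], crit.c_sets)
    motif = crit.xaa_pro_motif and peptide[1] == "P"
    satisfied = sum(
        any(residue in s for s in sets)
        for residue, sets in ((peptide[0], crit.n1_sets),
                              (peptide[1], crit.n2_sets),
                              (peptide[-1], crit.c_sets))
        if sets
    ) + bool(motif)
    result = CriteriaResult(target=target, n1_pass=n1, n2_pass=n2, c_pass=c,
                            motif_pass=motif, satisfied_alternatives=satisfied,
                            overall_pass=False)
    return CriteriaResult(**{**result.__dict__, "overall_pass": policy_fn(result)})


def match_known(
    peptides: Iterable[str],
    db: Sequence[KnownPeptideEntry],
) -> dict[str, list[KnownPeptideEntry]]:
    """Exact full-sequence matches of each peptide against the known table."""
    by_seq: dict[str, list[KnownPeptideEntry]] = {}
    for entry in db:
        by_seq.setdefault(entry.sequence, []).append(entry)
    return {p: list(by_seq.get(p, [])) for p in peptides}


def occurrence_frequency(
    protein: ProteinRecord,
    activity: str,
    db: Sequence[KnownPeptideEntry],
) -> float:
    """BIOPEP-style occurrence profile A for one activity.

    The number of positions in the protein at which some database peptide with
    the given activity begins (overlapping occurrences counted), divided by
    the protein length.
    """
    sequences = {e.sequence for e in db if e.activity == activity}
    seq = protein.sequence
    starts = {
        i
        for pep in sequences
        for i in range(len(seq) - len(pep) + 1)
        if seq.startswith(pep, i)
    }
    return len(starts) / len(seq)


@dataclass(frozen=True)
class CandidateAnnotation:
    """Everything the screen knows about one pooled peptide sequence."""

    sequence: str
    provenance: tuple[Peptide, ...]
    known_matches: tuple[KnownPeptideEntry, ...]
    criteria_results: Mapping[str, CriteriaResult]
    properties: PeptideProperties
    resistant: bool
    external_score: float | None = None

    @property
    def novel(self) -> bool:
        return not self.known_matches

    @property
    def targets_passed(self) -> tuple[str, ...]:
        return tuple(t for t in TARGETS if self.criteria_results[t].overall_pass)


@dataclass(frozen=True)
class SelectionPolicy:
    """Filters and ordering for candidate selection.

    Length bounds default to the 2–30-residue range typical of bioactive
    peptides.  With ``novel_only`` peptides already present in the known
    table are excluded.  ``require_target`` drops peptides passing no
    target's criteria.
    """

    novel_only: bool = False
    min_length: int = 2
    max_length: int = 30
    require_target: bool = True


def select_candidates(
    annotations: Iterable[CandidateAnnotation],
    policy: SelectionPolicy = SelectionPolicy(),
) -> list[CandidateAnnotation]:
    """Filter and deterministically rank annotated peptides.

    Ordering: externally supplied ranker score (descending, missing scores
    last), then number of targets passed (descending), then sequence
    lexicographically — so repeated runs produce identical tables.
    """
    passing = [
        a for a in annotations
        if policy.min_length <= len(a.sequence) <= policy.max_length
        and not (policy.novel_only and not a.novel)
        and not (policy.require_target and not a.targets_passed)
    ]
    return sorted(
        passing,
        key=lambda a: (
            -(a.external_score if a.external_score is not None else float("-inf")),
            -len(a.targets_passed),
            a.sequence,
        ),
    )
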