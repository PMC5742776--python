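"""End-to-end orchestration: fixtures → digestion → properties → resistance →
criteria/matching → ranked candidate report.

``run_pipeline`` reproduces the published workflow on the packaged oat
proteome (or any FASTA): release digestion with papain and ficin, pooling and
deduplication, exact matching against the known-peptide table, evaluation of
the three targets' positional criteria, physicochemical characterisation,
gastrointestinal-resistance prediction, and deterministic candidate ranking.
Outputs are a TSV candidate table, a FASTA of released peptides with
provenance headers, and a JSON run report echoing the configuration and the
SHA-256 of every rule file consumed.

``validate_rules`` is the calibration harness for the release tables: the
exact papain/ficin specificity tables behind the published hydrolysates are
not public, so the shipped tables are calibrated and this utility reports,
for any rule directory, which validation peptides the current tables release
and — for the missing ones — which bonds would need to change.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .bioactivity_rules import (
    CandidateAnnotation,
    SelectionPolicy,
    TARGETS,
    evaluate_criteria,
    match_known,
    select_candidates,
)
from .cleavage_engine import (
    GI_PANEL_ENZYMES,
    RELEASE_ENZYMES,
    CleavageRuleSet,
    Peptide,
    digest,
    digest_many,
    find_cleavage_sites,
    gi_panel,
    is_resistant,
    load_enzyme,
)
from .peptide_chem import peptide_properties
from .proteome_fixtures import (
    ProteinRecord,
    load_known_peptides,
    load_oat_proteins,
    read_fasta,
    validation_peptides,
)

logger = logging.getLogger("oatpep")

CANDIDATE_COLUMNS = (
    "rank", "sequence", "sources", "enzymes", "targets_passed",
    "known_match_ids", "solubility", "resistant", "avg_mass", "external_score",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run; every field has a CLI flag."""

    input: str = "builtin:oat"  # "builtin:oat" or a FASTA path
    release_enzymes: tuple[str, ...] = RELEASE_ENZYMES
    gi_panel: tuple[str, ...] = GI_PANEL_ENZYMES
    rules_dir: str | None = None  # None = packaged tables
    novel_only: bool = False
    min_length: int = 2
    max_length: int = 30
    require_target: bool = True
    external_scores: str | None = None  # optional TSV: sequence<TAB>score
    output_dir: str = "oatpep_out"
    seed: int = 0  # reserved for synthetic inputs; echoed in the report
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("release_enzymes", "gi_panel"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: Mapping
    digest_summaries: tuple[Mapping, ...]
    n_unique_peptides: int
    candidates: tuple[CandidateAnnotation, ...]
    rule_file_hashes: Mapping[str, str]
    version: str = __version__

    def to_json_dict(self) -> dict:
        return {
            "version": self.version,
            "config": dict(self.config),
            "rule_file_hashes": dict(self.rule_file_hashes),
            "digest_summaries": [dict(s) for s in self.digest_summaries],
            "n_unique_peptides": self.n_unique_peptides,
            "n_candidates": len(self.candidates),
            "note": ("In vitro confirmation of candidate bioactivity is "
                     "external to this pipeline."),
        }


def _load_records(config: PipelineConfig) -> list[ProteinRecord]:
    if config.input == "builtin:oat":
        return load_oat_proteins()
    path = Path(config.input)
    if not path.exists():
        raise FileNotFoundError(f"input FASTA not found: {path}")
    return read_fasta(path)


def _load_enzymes(names: Sequence[str], rules_dir: str | None) -> list[CleavageRuleSet]:
    enzymes = []
    for name in names:
        try:
            enzymes.append(load_enzyme(name, rules_dir))
        except FileNotFoundError as exc:
            raise FileNotFoundError(
                f"no rule table for enzyme {name!r}"
                + (f" in {rules_dir}" if rules_dir else " among the packaged tables")
            ) from exc
    return enzymes


def _rule_hashes(names: Sequence[str], rules_dir: str | None) -> dict[str, str]:
    hashes = {}
    for name in names:
        if rules_dir is None:
            text = (resources.files("oatpep") / "data" / "rules" / f"{name}.rules").read_text()
        else:
            text = (Path(rules_dir) / f"{name}.rules").read_text()
        hashes[name] = hashlib.sha256(text.encode()).hexdigest()
    return hashes


def _read_scores(path: str | None) -> dict[str, float]:
    if path is None:
        return {}
    scores = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("sequence"):
            continue
        seq, score = line.split("\t")[:2]
        scores[seq] = float(score)
    return scores


def annotate_peptides(
    pooled: Mapping[str, Sequence[Peptide]],
    panel: Sequence[CleavageRuleSet],
    external_scores: Mapping[str, float] | None = None,
) -> list[CandidateAnnotation]:
    """Attach matches, criteria, properties and resistance to pooled peptides."""
    db = load_known_peptides()
    matches = match_known(pooled.keys(), db)
    scores = external_scores or {}
    annotations = []
    for seq, provenance in pooled.items():
        annotations.append(
            CandidateAnnotation(
                sequence=seq,
                provenance=tuple(provenance),
                known_matches=tuple(matches[seq]),
                criteria_results={t: evaluate_criteria(seq, t) for t in TARGETS},
                properties=peptide_properties(seq),
                resistant=is_resistant(seq, panel).resistant,
                external_score=scores.get(seq),
            )
        )
    return annotations


def _write_candidates_tsv(candidates: Sequence[CandidateAnnotation], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for rank, a in enumerate(candidates, start=1):
            mass = a.properties.average_mass_da
            fh.write("\t".join([
                str(rank),
                a.sequence,
                ",".join(sorted({p.source_id for p in a.provenance})),
                ",".join(sorted({p.released_by for p in a.provenance})),
                ",".join(a.targets_passed),
                ",".join(str(e.biopep_id) for e in a.known_matches),
                a.properties.solubility_call,
                "yes" if a.resistant else "no",
                f"{mass:.3f}" if mass is not None else "",
                "" if a.external_score is None else repr(a.external_score),
            ]) + "\n")


def _write_peptides_fasta(pooled: Mapping[str, Sequence[Peptide]], path: Path) -> None:
    with open(path, "w") as fh:
        for seq in pooled:
            for p in pooled[seq]:
                fh.write(f">{p.sequence}|{p.source_id}|{p.start}-{p.end}|{p.released_by}\n")
                fh.write(p.sequence + "\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow and write candidates.tsv, peptides.fasta
    and report.json into ``config.output_dir``; deterministic for a fixed
    configuration and rule files."""
    logging.basicConfig(level=config.log_level)
    records = _load_records(config)
    release = _load_enzymes(config.release_enzymes, config.rules_dir)
    panel = _load_enzymes(config.gi_panel, config.rules_dir)
    logger.info("digesting %d protein(s) with %d release enzyme(s)",
                len(records), len(release))

    summaries = []
    for record in records:
        for enzyme in release:
            result = digest(record, enzyme)
            summaries.append({
                "protein": record.id,
                "enzyme": enzyme.enzyme_name,
                "n_sites": len(result.cut_sites),
                "n_peptides": len(result.peptides),
            })
    pooled = digest_many(records, release)
    logger.info("pooled %d unique peptide sequences", len(pooled))

    annotations = annotate_peptides(pooled, panel, _read_scores(config.external_scores))
    policy = SelectionPolicy(novel_only=config.novel_only,
                             min_length=config.min_length,
                             max_length=config.max_length,
                             require_target=config.require_target)
    candidates = select_candidates(annotations, policy)
    logger.info("%d candidate(s) selected", len(candidates))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_candidates_tsv(candidates, out / "candidates.tsv")
    _write_peptides_fasta(pooled, out / "peptides.fasta")
    report = RunReport(
        config=dataclasses.asdict(config),
        digest_summaries=tuple(summaries),
        n_unique_peptides=len(pooled),
        candidates=tuple(candidates),
        rule_file_hashes=_rule_hashes(
            tuple(config.release_enzymes) + tuple(config.gi_panel), config.rules_dir),
    )
    (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=1,
                                                sort_keys=True) + "\n")
    return report


@dataclass(frozen=True)
class PeptideCoverage:
    """Whether the release tables produce one validation peptide, and if not,
    what would have to change at its best occurrence."""

    peptide: str
    produced: bool
    produced_by: tuple[tuple[str, str], ...]  # (protein id, enzyme)
    missing_detail: tuple[str, ...] = ()


@dataclass(frozen=True)
class CoverageReport:
    """Calibration-harness outcome over the whole validation set."""

    peptides: tuple[PeptideCoverage, ...]
    n_produced: int
    n_total: int

    @property
    def coverage(self) -> float:
        return self.n_produced / self.n_total if self.n_total else 0.0


def _diagnose_occurrence(record: ProteinRecord, start: int, peptide: str,
                         enzyme: CleavageRuleSet) -> str:
    """Explain why one occurrence is not released by one enzyme."""
    seq = record.sequence
    end = start + len(peptide)
    sites = set(find_cleavage_sites(seq, enzyme))
    problems = []
    if start > 0 and start - 1 not in sites:
        problems.append(f"bond {start - 1} ({seq[start - 1]}|{seq[start]}) not cut")
    if end < len(seq) and end - 1 not in sites:
        problems.append(f"bond {end - 1} ({seq[end - 1]}|{seq[end]}) not cut")
    wrong = [b for b in range(start, end - 1) if b in sites]
    if wrong:
        problems.append("internal bond(s) cut: "
                        + ", ".join(f"{b} ({seq[b]}|{seq[b + 1]})" for b in wrong))
    return f"{record.id}@{start} [{enzyme.enzyme_name}]: " + "; ".join(problems)


def validate_rules(
    rules_dir: str | None = None,
    enzymes: Sequence[str] = RELEASE_ENZYMES,
    validation_set: Sequence[str] | None = None,
    records: Sequence[ProteinRecord] | None = None,
) -> CoverageReport:
    """Report which validation peptides the release tables produce.

    For each peptide not produced, every occurrence in every substrate is
    diagnosed: the boundary bonds that would need to be cuttable and the
    internal bonds that are wrongly cut.
    """
    if records is None:
        records = load_oat_proteins()
    if validation_set is None:
        validation_set = validation_peptides()
    rule_sets = _load_enzymes(enzymes, rules_dir)
    pooled_by_enzyme = {
        rs.enzyme_name: digest_many(records, [rs]) for rs in rule_sets
    }
    coverages = []
    for pep in validation_set:
        produced_by = tuple(
            sorted({
                (p.source_id, name)
                for name, pooled in pooled_by_enzyme.items()
                for p in pooled.get(pep, [])
            })
        )
        detail: tuple[str, ...] = ()
        if not produced_by:
            notes = []
            for record in records:
                i = record.sequence.find(pep)
                while i != -1:
                    for rs in rule_sets:
                        notes.append(_diagnose_occurrence(record, i, pep, rs))
                    i = record.sequence.find(pep, i + 1)
            detail = tuple(notes) or ("no occurrence in any substrate",)
        coverages.append(PeptideCoverage(peptide=pep, produced=bool(produced_by),
                                         produced_by=produced_by,
                                         missing_detail=detail))
    return CoverageReport(
        peptides=tuple(coverages),
        n_produced=sum(c.produced for c in coverages),
        n_total=len(coverages),
    )
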