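"""Table readers/writers, run configuration, and the end-to-end report.

All tables are plain CSV/TSV with documented headers. The report bundle
mirrors the analysis stages: bookkeeping overview, parsing classification
with subject/item rate tables, assignment tally with eligibility and rate
tables, entropy tables, and the distinct-response histogram. Every table is
checked against its module's conservation invariants before writing, and
partial outputs are removed on failure so a report directory is either
complete or absent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .analysis import (
    NONSTANDARD,
    STANDARD,
    UNANALYSABLE,
    AssignmentTally,
    ParseClassification,
    ResponseRecord,
    classify_responses,
    eligible_graphemes,
    status_counts,
    tally_assignments,
)
from .errors import AnalysisError, GraphovarError
from .inventory import GraphemeInventory, default_inventory, load_inventory
from .phonology import PhonemeInventory, default_phoneme_inventory
from .stats import (
    EntropyReport,
    RateReport,
    distinct_response_counts,
    grapheme_entropy_across_subjects,
    nonstandard_rates,
    subject_grapheme_entropy,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "nonword", "transcription")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_responses(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[ResponseRecord]:
    """Read a subject x nonword response table (CSV/TSV).

    ``column_map`` maps file column names to the canonical
    ``subject_id, nonword, transcription[, analysable]`` names, so files
    with a different layout need no preprocessing. Rows with an empty
    transcription are flagged unanalysable; nonwords are normalized to
    uppercase; duplicate (subject, nonword) rows are logged and the last
    one wins.
    """
    df = _read_table(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise GraphovarError(
            f"{path}: missing required column(s) {missing}; present: {list(df.columns)}"
        )
    records: dict[tuple[str, str], ResponseRecord] = {}
    dupes = 0
    for row in df.itertuples(index=False):
        subject = str(getattr(row, "subject_id")).strip()
        nonword = str(getattr(row, "nonword")).strip().upper()
        transcription = str(getattr(row, "transcription")).strip()
        analysable = bool(transcription)
        if "analysable" in df.columns:
            flag = str(getattr(row, "analysable")).strip().lower()
            analysable = analysable and flag not in ("0", "false", "no", "n")
        key = (subject, nonword)
        if key in records:
            dupes += 1
        records[key] = ResponseRecord(subject, nonword, transcription, analysable)
    if dupes:
        logger.warning("%s: %d duplicate (subject, nonword) rows; last wins", path, dupes)
    return list(records.values())


def write_responses(records: Iterable[ResponseRecord], path: str | Path) -> None:
    """Write records as a TSV round-trippable through :func:`read_responses`."""
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "nonword": r.nonword,
                "transcription": r.transcription,
                "analysable": int(r.analysable),
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Knobs for an end-to-end report run."""

    inventory_path: str | None = None
    phoneme_path: str | None = None
    min_per_subject: int = 4
    min_cell: int = 1
    column_map: dict[str, str] = field(default_factory=dict)
    out_dir: str | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        for attr in ("inventory_path", "phoneme_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise GraphovarError(f"{attr}={p!r} does not exist")
        if self.min_per_subject < 1 or self.min_cell < 1:
            raise GraphovarError("min_per_subject and min_cell must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def load_inventory(self) -> GraphemeInventory:
        phinv: PhonemeInventory | None = None
        if self.phoneme_path:
            phinv = PhonemeInventory.from_file(self.phoneme_path)
        if self.inventory_path:
            return load_inventory(self.inventory_path, phinv)
        return default_inventory()

    @property
    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All report tables plus provenance, ready to write."""

    provenance: dict
    classifications: list[ParseClassification]
    tally: AssignmentTally
    rates: RateReport
    entropy_subjects: EntropyReport
    entropy_graphemes: EntropyReport
    distinct_counts: dict[str, int]
    frames: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            summary = out / "summary.json"
            summary.write_text(
                json.dumps(self.provenance, indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )
            written.append(summary)
            for name, frame in self.frames.items():
                p = out / f"{name}.csv"
                frame.to_csv(p, index=False)
                written.append(p)
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise
        return written


def _check_conservation(
    records: Sequence[ResponseRecord],
    classifications: Sequence[ParseClassification],
    tally: AssignmentTally,
    rates: RateReport,
) -> None:
    counts = status_counts(classifications)
    if sum(counts.values()) != len(records):
        raise AnalysisError("classification does not partition the records")
    overall = rates.overall.get("parsing")
    if overall is not None:
        if overall.numerator != sum(
            r.numerator for r in rates.item_parsing_rates.values()
        ):
            raise AnalysisError("subject vs item parsing numerators disagree")
        if overall.denominator != counts[STANDARD] + counts[NONSTANDARD]:
            raise AnalysisError("parsing denominator != analysable records")
    n_incidences = sum(
        c.n_graphemes for c in classifications if c.status == STANDARD
    )
    if tally.total != n_incidences:
        raise AnalysisError(
            f"tally total {tally.total} != standard-parse grapheme incidences {n_incidences}"
        )


def run_report(
    responses: str | Path | Sequence[ResponseRecord],
    config: RunConfig | None = None,
    inv: GraphemeInventory | None = None,
) -> ReportBundle:
    """Run the full analysis and assemble the report bundle.

    ``responses`` may be a table path or an in-memory record list. The
    provenance section recomputes all bookkeeping from its own inputs:
    potential responses (subjects x nonwords), unavailable and analysable
    counts, and the maximal number of grapheme-phoneme data points implied
    by the eligible grapheme set.
    """
    config = config or RunConfig()
    if inv is None:
        inv = config.load_inventory()
    if isinstance(responses, (str, Path)):
        records = read_responses(responses, config.column_map or None)
    else:
        records = list(responses)

    classifications = classify_responses(records, inv)
    tally = tally_assignments(records, inv)
    subjects = sorted({r.subject_id for r in records})
    eligible = eligible_graphemes(
        tally, min_per_subject=config.min_per_subject, subjects=subjects
    )
    rates = nonstandard_rates(classifications, tally, inv, eligible=eligible)
    ent_subj = subject_grapheme_entropy(tally, eligible, min_cell=config.min_cell)
    ent_graph = grapheme_entropy_across_subjects(tally, eligible)
    distinct = distinct_response_counts(records, inv)
    _check_conservation(records, classifications, tally, rates)

    counts = status_counts(classifications)
    nonwords = sorted({r.nonword for r in records})
    per_subject_totals = tally.per_subject_totals()
    max_per_grapheme = {
        g: max(
            (n for (s, gg), n in per_subject_totals.items() if gg == g),
            default=0,
        )
        for g in sorted(eligible, key=lambda g: g.label)
    }
    max_gpc_per_subject = sum(max_per_grapheme.values())
    eligible_tally = tally.restrict(eligible)

    n_potential = len(subjects) * len(nonwords)
    provenance = {
        "package": "graphovar",
        "version": __version__,
        "config_digest": config.digest,
        "inventory": inv.name,
        "n_rules": len(inv),
        "n_subjects": len(subjects),
        "n_nonwords": len(nonwords),
        "n_potential_responses": n_potential,
        "n_records": len(records),
        "n_unavailable": counts[UNANALYSABLE],
        "n_analysable": sum(counts.values()) - counts[UNANALYSABLE],
        "n_standard_parsings": counts[STANDARD],
        "n_nonstandard_parsings": counts[NONSTANDARD],
        "pct_nonstandard_parsings": (
            round(rates.overall["parsing"].pct, 4) if "parsing" in rates.overall else None
        ),
        "n_eligible_graphemes": len(eligible),
        "min_per_subject": config.min_per_subject,
        "max_gpc_per_subject": max_gpc_per_subject,
        "max_gpc_total": max_gpc_per_subject * len(subjects),
        "n_assignments_eligible": eligible_tally.total,
        "n_nonstandard_assignments": (
            rates.overall["assignment"].numerator
            if "assignment" in rates.overall
            else 0
        ),
        "pct_nonstandard_assignments": (
            round(rates.overall["assignment"].pct, 4)
            if "assignment" in rates.overall
            else None
        ),
    }

    frames = {
        "parse_classifications": pd.DataFrame(
            [
                {
                    "subject_id": c.subject_id,
                    "nonword": c.nonword,
                    "n_graphemes": c.n_graphemes,
                    "n_phonemes": c.n_phonemes,
                    "status": c.status,
                }
                for c in classifications
            ]
        ),
        "subject_parsing_rates": _rate_frame(rates.subject_parsing_rates, "subject_id"),
        "item_parsing_rates": _rate_frame(rates.item_parsing_rates, "nonword"),
        "subject_assignment_rates": _rate_frame(
            rates.subject_assignment_rates, "subject_id"
        ),
        "assignment_tally": pd.DataFrame(
            [
                {
                    "subject_id": s,
                    "grapheme": g.label,
                    "phoneme": p.ipa,
                    "count": n,
                    "eligible": int(g in eligible),
                }
                for (s, g, p), n in sorted(
                    tally.counts.items(), key=lambda kv: (kv[0][0], kv[0][1].label, kv[0][2].ipa)
                )
            ]
        ),
        "subject_grapheme_entropy": pd.DataFrame(
            [
                {"subject_id": s, "grapheme": g, "H_bits": round(h, 6)}
                for (s, g), h in sorted(ent_subj.per_subject_grapheme.items())
            ]
        ),
        "subject_mean_entropy": pd.DataFrame(
            [
                {"subject_id": s, "mean_H_bits": round(h, 6)}
                for s, h in sorted(ent_subj.subject_means.items())
            ]
        ),
        "grapheme_entropy": pd.DataFrame(
            [
                {
                    "grapheme": g,
                    "H_pooled_bits": round(ent_graph.per_grapheme_pooled[g], 6),
                    "H_mean_subjects_bits": round(ent_graph.per_grapheme_mean[g], 6),
                }
                for g in sorted(ent_graph.per_grapheme_pooled)
            ]
        ),
        "distinct_response_counts": pd.DataFrame(
            [{"nonword": w, "n_distinct": n} for w, n in distinct.items()]
        ),
    }

    return ReportBundle(
        provenance=provenance,
        classifications=classifications,
        tally=tally,
        rates=rates,
        entropy_subjects=ent_subj,
        entropy_graphemes=ent_graph,
        distinct_counts=distinct,
        frames=frames,
    )


def _rate_frame(rates: Mapping[str, "object"], key: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                key: k,
                "nonstandard": r.numerator,
                "total": r.denominator,
                "pct": round(r.pct, 4),
            }
            for k, r in rates.items()
        ]
    )
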