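"""Case lifecycle: distribute, review, merge, resolve, validate, archive.

A case project moves every variant through a fixed pipeline:

    uploaded -> assigned -> reviewed -> merged -> resolved
             -> (Sanger validation) -> reported -> archived

Each variant is independently reviewed by at least two reviewers.  Reviewer
calls are journaled append-only the moment they arrive — the contract is
that no reviewer work is ever lost, with a configurable flush interval only
for buffering batch clients.  Merging highlights discordance (any
disagreement on either the gene-level or the variant-level call), because a
gene-level disagreement changes the decision-matrix action just as surely
as a variant-level one.  Concordant variants whose action is terminal
auto-resolve; discordant variants and those whose action demands discussion
go to the group meeting, whose outcome is recorded with minutes and
re-entered through the decision matrix.  Variants whose final action
requires Sanger confirmation form the validation queue; a failed
confirmation routes the variant back to discussion.  Archived cases feed
recurrence queries for future cases.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import random
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .config import ProjectConfig
from .decisions import decide
from .errors import (
    AuthorizationError,
    ConfigurationError,
    WorkflowError,
)
from .rules import validate_call_context
from .variant_io import (
    CallRow,
    VariantKey,
    VariantRecord,
    record_from_dict,
    record_to_dict,
)
from .vocab import (
    Action,
    AnalysisType,
    GeneLevelCall,
    VariantLevelCall,
    parse_gene_call,
    parse_variant_call,
)


@dataclasses.dataclass
class Assignment:
    variant: VariantKey
    reviewer: str
    deadline: _dt.date
    status: str = "pending"  # pending | submitted

    def is_late(self, as_of: _dt.date) -> bool:
        return self.status == "pending" and as_of > self.deadline


@dataclasses.dataclass
class ReviewCall:
    variant: VariantKey
    reviewer: str
    gene_call: GeneLevelCall
    variant_call: VariantLevelCall
    comment: str = ""
    timestamp: str = ""


@dataclasses.dataclass
class Resolution:
    variant: VariantKey
    final_gene_call: GeneLevelCall
    final_variant_call: VariantLevelCall
    final_action: Action
    resolved_by: str  # concordant_auto | group_meeting
    minutes: str = ""


@dataclasses.dataclass
class MergedRow:
    """One variant in the administrator's merged review table."""

    variant: VariantKey
    calls: list[ReviewCall]
    complete: bool
    late: bool
    discordant: bool
    auto_action: Optional[Action]
    status: str  # incomplete | discordant | needs_discussion | error_call | auto_resolved


@dataclasses.dataclass
class SangerEntry:
    variant: VariantKey
    action: Action
    status: str = "pending"  # pending | confirmed | not_confirmed


def distribute(
    variants: Sequence[VariantRecord | VariantKey],
    reviewers: Sequence[str],
    min_reviewers: int,
    deadline: _dt.date,
    seed: int = 0,
) -> list[Assignment]:
    """Assign every variant to ``min_reviewers`` distinct reviewers.

    Round-robin over a seeded shuffle: deterministic for a fixed seed, and
    load-balanced so that per-reviewer loads differ by at most one.  At
    least two independent reviewers are required per variant.
    """
    if min_reviewers < 2:
        raise ConfigurationError(
            f"every variant needs at least 2 independent reviewers, "
            f"got min_reviewers={min_reviewers}"
        )
    if len(set(reviewers)) < min_reviewers:
        raise ConfigurationError(
            f"{min_reviewers} reviewers per variant requested but only "
            f"{len(set(reviewers))} distinct reviewer(s) available"
        )
    rng = random.Random(seed)
    pool = sorted(set(reviewers))
    rng.shuffle(pool)
    keys = [v.key if isinstance(v, VariantRecord) else v for v in variants]
    order = list(range(len(keys)))
    rng.shuffle(order)
    assignments = []
    slot = 0
    for idx in order:
        for _ in range(min_reviewers):
            assignments.append(
                Assignment(
                    variant=keys[idx],
                    reviewer=pool[slot % len(pool)],
                    deadline=deadline,
                )
            )
            slot += 1
    assignments.sort(key=lambda a: (a.variant, a.reviewer))
    return assignments


def replay_journal(entries: Iterable[dict]) -> dict[tuple[str, str], dict]:
    """Reconstruct the current-call table from the append-only journal.

    The journal is the source of truth: the last ``call`` entry per
    (variant, reviewer) pair wins.  Used by tests and crash recovery.
    """
    table: dict[tuple[str, str], dict] = {}
    for entry in entries:
        if entry.get("kind") == "call":
            payload = entry["payload"]
            table[(payload["variant"], payload["reviewer"])] = payload
    return table


class CaseProject:
    """All state for one patient case, persisted as a single JSON document."""

    def __init__(self, case_id: str, config: Optional[ProjectConfig] = None):
        self.case_id = case_id
        self.config = config or ProjectConfig()
        self.variants: dict[str, VariantRecord] = {}  # key token -> record
        self.assignments: list[Assignment] = []
        self.journal: list[dict] = []  # append-only
        self.current_calls: dict[tuple[str, str], ReviewCall] = {}
        self.merged: dict[str, MergedRow] = {}
        self.resolutions: dict[str, Resolution] = {}
        self.sanger_queue: dict[str, SangerEntry] = {}
        self.reopened: set[str] = set()
        self.audit_log: list[dict] = []
        self.revision = 0
        self.report_revision: Optional[int] = None
        self.signed_report: Optional[dict] = None
        self.archived = False
        self._seq = 0

    # -- plumbing ----------------------------------------------------------

    def _tick(self) -> int:
        self._seq += 1
        return self._seq

    def _touch(self) -> None:
        self.revision += 1

    def audit(self, event: str, **payload) -> None:
        self.audit_log.append({"seq": self._tick(), "event": event, **payload})

    def _journal(self, kind: str, payload: dict) -> None:
        self.journal.append({"seq": self._tick(), "kind": kind, "payload": payload})

    def record(self, token: str) -> VariantRecord:
        try:
            return self.variants[token]
        except KeyError:
            raise WorkflowError(f"unknown variant {token} in case {self.case_id}") from None

    # -- lifecycle ---------------------------------------------------------

    def upload(self, records: Iterable[VariantRecord]) -> int:
        """Add variant records to the case (state: uploaded)."""
        if self.archived:
            raise WorkflowError("case is archived and frozen")
        n = 0
        for record in records:
            token = record.key.token()
            if token in self.variants:
                raise WorkflowError(f"variant {token} uploaded twice")
            self.variants[token] = record
            n += 1
        self.audit("upload", count=n)
        self._touch()
        return n

    def distribute(
        self,
        reviewers: Sequence[str],
        deadline: _dt.date,
        min_reviewers: Optional[int] = None,
        seed: int = 0,
    ) -> list[Assignment]:
        """Assign every uploaded variant (state: uploaded -> assigned)."""
        if not self.variants:
            raise WorkflowError("no variants uploaded; nothing to distribute")
        min_reviewers = (
            self.config.min_reviewers if min_reviewers is None else min_reviewers
        )
        if min_reviewers < self.config.min_reviewers:
            raise ConfigurationError(
                f"project policy requires at least {self.config.min_reviewers} "
                f"reviewers per variant"
            )
        self.assignments = distribute(
            list(self.variants.values()), reviewers, min_reviewers, deadline, seed
        )
        self.audit(
            "distribute",
            reviewers=sorted(set(reviewers)),
            deadline=deadline.isoformat(),
            assignments=len(self.assignments),
        )
        self._touch()
        return self.assignments

    def assignment_for(self, variant: VariantKey, reviewer: str) -> Optional[Assignment]:
        for a in self.assignments:
            if a.variant == variant and a.reviewer == reviewer:
                return a
        return None

    def record_call(self, call: ReviewCall) -> None:
        """Journal and register one reviewer call (state: assigned -> reviewed).

        The journal entry is written before anything else; resubmission
        overwrites the current call but the journal keeps every version.
        """
        assignment = self.assignment_for(call.variant, call.reviewer)
        if assignment is None:
            raise AuthorizationError(
                f"variant {call.variant.token()} is not assigned to reviewer "
                f"{call.reviewer!r}"
            )
        record = self.record(call.variant.token())
        validate_call_context(
            call.gene_call,
            call.variant_call,
            record.analysis_type,
            self.config.secondary_findings_consent,
        )
        if not call.timestamp:
            call.timestamp = _dt.datetime.now().isoformat(timespec="seconds")
        self._journal(
            "call",
            {
                "variant": call.variant.token(),
                "reviewer": call.reviewer,
                "gene_call": call.gene_call.value,
                "variant_call": call.variant_call.value,
                "comment": call.comment,
                "timestamp": call.timestamp,
            },
        )
        self.current_calls[(call.variant.token(), call.reviewer)] = call
        assignment.status = "submitted"
        self._touch()

    def ingest_call_rows(self, rows: Iterable[CallRow]) -> int:
        """Record calls parsed from a reviewer call file."""
        n = 0
        for row in rows:
            self.record_call(
                ReviewCall(
                    variant=row.key,
                    reviewer=row.reviewer,
                    gene_call=row.gene_call,
                    variant_call=row.variant_call,
                    comment=row.comment,
                )
            )
            n += 1
        return n

    def merge_and_flag(self, as_of: Optional[_dt.date] = None) -> list[MergedRow]:
        """Merge reviewer calls per variant and flag discordance.

        A variant is merged when all its assignments are submitted, or when
        its deadline has passed (then flagged incomplete).  Discordant means
        any two reviewers differ on the gene-level *or* the variant-level
        call.  Concordant variants with a terminal action auto-resolve;
        actions demanding discussion, and decision-matrix error cells, hold
        the variant for the group meeting.  Idempotent.
        """
        if not self.assignments:
            raise WorkflowError("variants are not assigned; distribute first")
        as_of = as_of or _dt.date.today()
        by_variant: dict[str, list[Assignment]] = {}
        for a in self.assignments:
            by_variant.setdefault(a.variant.token(), []).append(a)
        rows: list[MergedRow] = []
        for token, assigned in sorted(by_variant.items()):
            calls = [
                self.current_calls[(token, a.reviewer)]
                for a in assigned
                if (token, a.reviewer) in self.current_calls
            ]
            complete = all(a.status == "submitted" for a in assigned)
            late = any(a.is_late(as_of) for a in assigned)
            if not complete and not late:
                continue  # still within deadline; not ready to merge
            pairs = {(c.gene_call, c.variant_call) for c in calls}
            discordant = len(pairs) > 1
            auto_action: Optional[Action] = None
            if complete and not discordant and calls:
                gene_call, variant_call = next(iter(pairs))
                auto_action = decide(variant_call, gene_call)
                if auto_action.is_error():
                    status = "error_call"
                elif auto_action.needs_discussion():
                    status = "needs_discussion"
                else:
                    status = "auto_resolved"
                    if token not in self.resolutions:
                        self.resolutions[token] = Resolution(
                            variant=calls[0].variant,
                            final_gene_call=gene_call,
                            final_variant_call=variant_call,
                            final_action=auto_action,
                            resolved_by="concordant_auto",
                        )
                        self.audit(
                            "auto_resolve", variant=token, action=auto_action.value
                        )
            elif discordant:
                status = "discordant"
            else:
                status = "incomplete"
            row = MergedRow(
                variant=VariantKey.from_token(token),
                calls=calls,
                complete=complete,
                late=late,
                discordant=discordant,
                auto_action=auto_action,
                status=status,
            )
            rows.append(row)
            self.merged[token] = row
        self._touch()
        return rows

    def discussion_queue(self) -> list[MergedRow]:
        """Variants awaiting a group-meeting resolution."""
        pending = [
            row
            for token, row in sorted(self.merged.items())
            if (
                row.status in ("discordant", "needs_discussion", "error_call")
                and token not in self.resolutions
            )
            or token in self.reopened
        ]
        return pending

    def resolve(
        self,
        variant: VariantKey,
        final_gene_call: GeneLevelCall | str,
        final_variant_call: VariantLevelCall | str,
        minutes: str,
        override: bool = False,
    ) -> Resolution:
        """Record a group-meeting resolution for one variant.

        Only discordant or discussion-pending variants (or Sanger failures
        routed back) may be resolved here; overriding a concordant
        auto-resolution requires the explicit ``override`` flag and is
        audited.  The final action is recomputed through the decision
        matrix, and a resolution that lands on an error cell is rejected:
        the calls must be re-categorised first.
        """
        token = variant.token()
        row = self.merged.get(token)
        if row is None:
            raise WorkflowError(
                f"variant {token} has not been merged; run merge_and_flag first"
            )
        eligible = (
            row.status in ("discordant", "needs_discussion", "error_call")
            or token in self.reopened
        )
        if not eligible and not override:
            raise WorkflowError(
                f"variant {token} auto-resolved concordantly; pass override=True "
                f"to supersede"
            )
        final_gene_call = (
            final_gene_call
            if isinstance(final_gene_call, GeneLevelCall)
            else parse_gene_call(str(final_gene_call))
        )
        final_variant_call = (
            final_variant_call
            if isinstance(final_variant_call, VariantLevelCall)
            else parse_variant_call(str(final_variant_call))
        )
        record = self.record(token)
        validate_call_context(
            final_gene_call,
            final_variant_call,
            record.analysis_type,
            self.config.secondary_findings_consent,
        )
        action = decide(final_variant_call, final_gene_call)
        if action.is_error():
            raise WorkflowError(
                f"resolution maps to a category error ({action.label!r}); "
                f"re-categorise the calls instead"
            )
        resolution = Resolution(
            variant=variant,
            final_gene_call=final_gene_call,
            final_variant_call=final_variant_call,
            final_action=action,
            resolved_by="group_meeting",
            minutes=minutes,
        )
        self.resolutions[token] = resolution
        self.reopened.discard(token)
        self.audit(
            "group_resolution",
            variant=token,
            action=action.value,
            override=bool(override and not eligible),
            minutes=minutes,
        )
        self._touch()
        return resolution

    def unresolved(self) -> list[str]:
        return sorted(t for t in self.variants if t not in self.resolutions)

    def build_sanger_queue(self) -> list[SangerEntry]:
        """Queue every resolved variant whose action requires Sanger.

        All variants must be resolved first; existing validation outcomes
        survive a rebuild.
        """
        missing = self.unresolved()
        if missing:
            raise WorkflowError(
                "cannot build the validation queue with unresolved variants: "
                + ", ".join(missing)
            )
        for token, resolution in sorted(self.resolutions.items()):
            if resolution.final_action.sanger_required():
                if token not in self.sanger_queue:
                    self.sanger_queue[token] = SangerEntry(
                        variant=resolution.variant, action=resolution.final_action
                    )
            else:
                self.sanger_queue.pop(token, None)
        self._touch()
        return [self.sanger_queue[t] for t in sorted(self.sanger_queue)]

    def record_sanger_result(self, variant: VariantKey, confirmed: bool) -> SangerEntry:
        """Record a validation outcome; a failure reopens group discussion."""
        token = variant.token()
        entry = self.sanger_queue.get(token)
        if entry is None:
            raise WorkflowError(f"variant {token} is not in the Sanger queue")
        entry.status = "confirmed" if confirmed else "not_confirmed"
        self.audit("sanger_result", variant=token, status=entry.status)
        if not confirmed:
            self.reopened.add(token)
            self.audit("reopen_discussion", variant=token)
        self._touch()
        return entry

    def pending_validation(self) -> list[str]:
        return sorted(
            t for t, e in self.sanger_queue.items() if e.status == "pending"
        )

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        def key_token(k: VariantKey) -> str:
            return k.token()

        return {
            "case_id": self.case_id,
            "config": self.config.to_dict(),
            "variants": {t: record_to_dict(r) for t, r in self.variants.items()},
            "assignments": [
                {
                    "variant": key_token(a.variant),
                    "reviewer": a.reviewer,
                    "deadline": a.deadline.isoformat(),
                    "status": a.status,
                }
                for a in self.assignments
            ],
            "journal": self.journal,
            "merged": {
                t: {
                    "reviewers": [c.reviewer for c in row.calls],
                    "complete": row.complete,
                    "late": row.late,
                    "discordant": row.discordant,
                    "auto_action": row.auto_action.value if row.auto_action else None,
                    "status": row.status,
                }
                for t, row in self.merged.items()
            },
            "resolutions": {
                t: {
                    "gene_call": r.final_gene_call.value,
                    "variant_call": r.final_variant_call.value,
                    "action": r.final_action.value,
                    "resolved_by": r.resolved_by,
                    "minutes": r.minutes,
                }
                for t, r in self.resolutions.items()
            },
            "sanger_queue": {
                t: {"action": e.action.value, "status": e.status}
                for t, e in self.sanger_queue.items()
            },
            "reopened": sorted(self.reopened),
            "audit_log": self.audit_log,
            "revision": self.revision,
            "report_revision": self.report_revision,
            "signed_report": self.signed_report,
            "archived": self.archived,
            "seq": self._seq,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CaseProject":
        project = cls(data["case_id"], ProjectConfig.from_dict(data.get("config")))
        project.variants = {
            t: record_from_dict(d) for t, d in data.get("variants", {}).items()
        }
        project.assignments = [
            Assignment(
                variant=VariantKey.from_token(a["variant"]),
                reviewer=a["reviewer"],
                deadline=_dt.date.fromisoformat(a["deadline"]),
                status=a["status"],
            )
            for a in data.get("assignments", [])
        ]
        project.journal = list(data.get("journal", []))
        for (token, reviewer), payload in replay_journal(project.journal).items():
            project.current_calls[(token, reviewer)] = ReviewCall(
                variant=VariantKey.from_token(token),
                reviewer=reviewer,
                gene_call=GeneLevelCall(payload["gene_call"]),
                variant_call=VariantLevelCall(payload["variant_call"]),
                comment=payload.get("comment", ""),
                timestamp=payload.get("timestamp", ""),
            )
        for token, row in data.get("merged", {}).items():
            project.merged[token] = MergedRow(
                variant=VariantKey.from_token(token),
                calls=[
                    project.current_calls[(token, reviewer)]
                    for reviewer in row["reviewers"]
                    if (token, reviewer) in project.current_calls
                ],
                complete=row["complete"],
                late=row["late"],
                discordant=row["discordant"],
                auto_action=Action(row["auto_action"]) if row["auto_action"] else None,
                status=row["status"],
            )
        project.resolutions = {
            t: Resolution(
                variant=VariantKey.from_token(t),
                final_gene_call=GeneLevelCall(r["gene_call"]),
                final_variant_call=VariantLevelCall(r["variant_call"]),
                final_action=Action(r["action"]),
                resolved_by=r["resolved_by"],
                minutes=r.get("minutes", ""),
            )
            for t, r in data.get("resolutions", {}).items()
        }
        project.sanger_queue = {
            t: SangerEntry(
                variant=VariantKey.from_token(t),
                action=Action(e["action"]),
                status=e["status"],
            )
            for t, e in data.get("sanger_queue", {}).items()
        }
        project.reopened = set(data.get("reopened", []))
        project.audit_log = list(data.get("audit_log", []))
        project.revision = data.get("revision", 0)
        project.report_revision = data.get("report_revision")
        project.signed_report = data.get("signed_report")
        project.archived = data.get("archived", False)
        project._seq = data.get("seq", len(project.audit_log) + len(project.journal))
        return project

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "CaseProject":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# Case archive
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ArchiveEntry:
    """Frozen summary of a completed case."""

    case_id: str
    final_calls: dict[str, dict]  # key token -> {gene_call, variant_call, action}
    reviewers: list[str]


class CaseArchive:
    """Append-only archive of completed cases, persisted as JSON."""

    def __init__(self, entries: Optional[list[ArchiveEntry]] = None):
        self._entries: dict[str, ArchiveEntry] = {
            e.case_id: e for e in (entries or [])
        }

    def entries(self) -> list[ArchiveEntry]:
        return [self._entries[c] for c in sorted(self._entries)]

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, case_id: str) -> bool:
        return case_id in self._entries

    def add(self, entry: ArchiveEntry) -> None:
        self._entries[entry.case_id] = entry

    def reviewer_history(self, reviewer: str) -> list[str]:
        """Case ids this reviewer worked on (historic assignments)."""
        return [e.case_id for e in self.entries() if reviewer in e.reviewers]

    def to_dict(self) -> dict:
        return {
            "cases": {
                e.case_id: {"final_calls": e.final_calls, "reviewers": e.reviewers}
                for e in self.entries()
            }
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CaseArchive":
        return cls(
            [
                ArchiveEntry(
                    case_id=cid,
                    final_calls=body.get("final_calls", {}),
                    reviewers=body.get("reviewers", []),
                )
                for cid, body in data.get("cases", {}).items()
            ]
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "CaseArchive":
        path = Path(path)
        if not path.exists():
            return cls()
        return cls.from_dict(json.loads(path.read_text(encoding="utf-8")))


def archive_case(project: CaseProject, archive: CaseArchive) -> ArchiveEntry:
    """Freeze a reported case into the archive (idempotent).

    Requires a generated report; the archived final calls feed
    :func:`exomereview.annotation.query_recurrent` and reviewer-history
    queries in later cases.
    """
    if project.report_revision is None:
        raise WorkflowError(
            f"case {project.case_id} has no generated report; cannot archive"
        )
    if project.case_id in archive:
        project.archived = True
        return archive.entries()[
            [e.case_id for e in archive.entries()].index(project.case_id)
        ]
    entry = ArchiveEntry(
        case_id=project.case_id,
        final_calls={
            token: {
                "gene_call": r.final_gene_call.value,
                "variant_call": r.final_variant_call.value,
                "action": r.final_action.value,
            }
            for token, r in project.resolutions.items()
        },
        reviewers=sorted({a.reviewer for a in project.assignments}),
    )
    archive.add(entry)
    project.archived = True
    project.audit("archive", case=project.case_id)
    return entry
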