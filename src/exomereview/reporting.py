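"""Clinical report-table generation and director sign-off.

Reported variants are split across three disjoint tables:

* **primary findings** — (likely) pathogenic variants explaining the
  indication,
* **supplementary findings** — reported variants of uncertain or
  likely-benign significance, and
* **secondary findings** — medically actionable variants unrelated to the
  indication, reported per patient consent.

Routing is by final call class: secondary-finding actions go to the
secondary table; pathogenic / likely-pathogenic calls to the primary table;
every other reportable resolution (VUS, deleterious VUS reported as VUS,
likely benign, intronic likely benign) to the supplementary table.  The
union of the tables is exactly the set of reportable resolutions — nothing
is dropped silently; the laboratory director may drop or re-route entries
at sign-off, and every such edit is audited while the archived resolution
is retained.

Rendering is deterministic: regenerating from the same frozen project is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Callable, Optional

from .annotation import AnnotationStore, annotate
from .errors import StalenessError, WorkflowError
from .variant_io import VariantKey
from .vocab import Action, VariantLevelCall
from .workflow import CaseProject


@dataclasses.dataclass
class ReportEntry:
    """One reported variant row."""

    key: str  # chrom-pos-ref-alt token
    gene: str
    transcript: str
    hgvs_c: str
    hgvs_p: str
    zygosity: str
    analysis_type: str
    gene_call: str
    variant_call: str
    action: str
    validation_status: str  # confirmed | waived | not_required
    assertions: list[str]
    interpretation: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


TABLES = ("primary_findings", "supplementary_findings", "secondary_findings")

_PRIMARY_CALLS = (VariantLevelCall.PATHOGENIC, VariantLevelCall.LIKELY_PATHOGENIC)


def default_routing(action: Action, variant_call: VariantLevelCall) -> str:
    """Default table routing for one reportable resolution."""
    if action is Action.REPORT_AS_SECONDARY_AND_SANGER:
        return "secondary_findings"
    if variant_call in _PRIMARY_CALLS:
        return "primary_findings"
    return "supplementary_findings"


@dataclasses.dataclass
class ReportTables:
    """Draft (or signed) clinical report tables for one case."""

    case_id: str
    revision: int
    primary_findings: list[ReportEntry]
    supplementary_findings: list[ReportEntry]
    secondary_findings: list[ReportEntry]
    metadata: dict
    signed_by: str = ""
    project: Optional[CaseProject] = dataclasses.field(
        default=None, repr=False, compare=False
    )

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in TABLES}

    def all_entries(self) -> list[ReportEntry]:
        return [e for name in TABLES for e in getattr(self, name)]

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "revision": self.revision,
            "counts": self.counts,
            "metadata": self.metadata,
            "signed_by": self.signed_by,
            **{name: [e.to_dict() for e in getattr(self, name)] for name in TABLES},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def render(self) -> str:
        """Human-readable report document (deterministic plain text)."""
        lines = [
            f"CLINICAL EXOME VARIANT REPORT — case {self.case_id}",
            f"revision {self.revision}",
            "",
        ]
        titles = {
            "primary_findings": "PRIMARY FINDINGS",
            "supplementary_findings": "SUPPLEMENTARY FINDINGS",
            "secondary_findings": "SECONDARY FINDINGS",
        }
        any_rows = False
        for name in TABLES:
            entries = getattr(self, name)
            lines.append(f"{titles[name]} (n={len(entries)})")
            if not entries:
                lines.append("  none")
            for e in entries:
                any_rows = True
                lines.append(
                    f"  {e.gene} {e.transcript} {e.hgvs_c} {e.hgvs_p or '-'} "
                    f"[{e.zygosity or 'zygosity n/a'}; {e.analysis_type}]"
                )
                lines.append(
                    f"    gene call: {e.gene_call}; variant call: {e.variant_call}; "
                    f"action: {e.action}; validation: {e.validation_status}"
                )
                if e.assertions:
                    lines.append("    assertions: " + "; ".join(e.assertions))
                if e.interpretation:
                    lines.append(f"    interpretation: {e.interpretation}")
            lines.append("")
        if not any_rows:
            lines.append(
                "No reportable sequence variants were identified in this analysis."
            )
            lines.append("")
        if self.signed_by:
            lines.append(f"Approved by laboratory director: {self.signed_by}")
        return "\n".join(lines) + "\n"


def generate_report(
    project: CaseProject,
    store: Optional[AnnotationStore] = None,
    routing: Callable[[Action, VariantLevelCall], str] = default_routing,
    waive_validation: bool = False,
    waiver_note: str = "",
) -> ReportTables:
    """Build the report tables from a fully resolved, validated project.

    Preconditions: every variant resolved; no variant awaiting group
    re-discussion; every Sanger-required entry has an outcome, unless
    explicitly waived (``waive_validation`` with an audit note).  Raises
    :class:`WorkflowError` listing offenders otherwise.
    """
    unresolved = project.unresolved()
    if unresolved:
        raise WorkflowError(
            "report blocked; unresolved variants: " + ", ".join(unresolved)
        )
    if project.reopened:
        raise WorkflowError(
            "report blocked; variants reopened for discussion: "
            + ", ".join(sorted(project.reopened))
        )
    needs_queue = [
        t
        for t, r in project.resolutions.items()
        if r.final_action.sanger_required() and t not in project.sanger_queue
    ]
    if needs_queue:
        raise WorkflowError(
            "report blocked; Sanger queue not built for: " + ", ".join(sorted(needs_queue))
        )
    pending = project.pending_validation()
    if pending and not waive_validation:
        raise WorkflowError(
            "report blocked; validation pending for: " + ", ".join(pending)
        )
    if pending and waive_validation:
        project.audit(
            "validation_waived", variants=sorted(pending), note=waiver_note
        )

    tables: dict[str, list[ReportEntry]] = {name: [] for name in TABLES}
    for token in sorted(project.resolutions):
        resolution = project.resolutions[token]
        action = resolution.final_action
        if not action.reportable():
            continue
        record = project.record(token)
        assertions: list[str] = []
        if store is not None:
            bundle = annotate(record, store, project.config)
            assertions = [
                f"{r.source}: {r.assertion}" for r in bundle.records if r.assertion
            ]
        if action.sanger_required():
            entry_status = project.sanger_queue[token].status
            validation = "waived" if entry_status == "pending" else entry_status
        else:
            validation = "not_required"
        table = routing(action, resolution.final_variant_call)
        tables[table].append(
            ReportEntry(
                key=token,
                gene=record.gene,
                transcript=record.transcript,
                hgvs_c=record.hgvs_c,
                hgvs_p=record.hgvs_p,
                zygosity=record.zygosity,
                analysis_type=record.analysis_type.value,
                gene_call=resolution.final_gene_call.label,
                variant_call=resolution.final_variant_call.label,
                action=action.label,
                validation_status=validation,
                assertions=assertions,
                interpretation=resolution.minutes,
            )
        )
    for entries in tables.values():
        entries.sort(key=lambda e: (e.gene, e.key))

    report = ReportTables(
        case_id=project.case_id,
        revision=project.revision,
        metadata={
            "variants_total": len(project.variants),
            "resolutions": len(project.resolutions),
            "sanger_queue": len(project.sanger_queue),
        },
        project=project,
        **tables,
    )
    project.report_revision = project.revision
    project.audit("report_generated", counts=report.counts)
    return report


def director_signoff(
    tables: ReportTables,
    director: str,
    drop: tuple[str, ...] = (),
) -> ReportTables:
    """Finalize the report under the laboratory director's signature.

    ``drop`` lists key tokens the director removes from the report; each
    drop is audited and the underlying resolution stays in the project for
    the archive.  Sign-off on tables generated before the latest project
    modification raises :class:`StalenessError` — regenerate first.
    """
    project = tables.project
    if project is None:
        raise WorkflowError("report tables are detached from their project")
    if tables.revision != project.revision or project.report_revision != project.revision:
        raise StalenessError(
            f"report tables at revision {tables.revision} are stale "
            f"(project is at revision {project.revision}); regenerate"
        )
    dropped = set(drop)
    known = {e.key for e in tables.all_entries()}
    unknown = dropped - known
    if unknown:
        raise WorkflowError(
            "cannot drop entries not in the report: " + ", ".join(sorted(unknown))
        )
    final = ReportTables(
        case_id=tables.case_id,
        revision=tables.revision,
        primary_findings=[e for e in tables.primary_findings if e.key not in dropped],
        supplementary_findings=[
            e for e in tables.supplementary_findings if e.key not in dropped
        ],
        secondary_findings=[
            e for e in tables.secondary_findings if e.key not in dropped
        ],
        metadata=dict(tables.metadata),
        signed_by=director,
        project=project,
    )
    for token in sorted(dropped):
        project.audit("director_drop", variant=token, director=director)
    project.signed_report = final.to_dict()
    # sign-off itself does not advance the revision: the tables stay current
    project.audit("director_signoff", director=director, counts=final.counts)
    return final


def resolve_key(token: str) -> VariantKey:
    """Convenience: parse a ``chrom-pos-ref-alt`` report key token."""
    return VariantKey.from_token(token)
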