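"""Controlled vocabularies shared across the triage engine.

The clinical review of an exome case hinges on three small label sets:

* the six *gene-level* calls answering "is the phenotype of this patient
  applicable to the disease associated with this gene?",
* the nine *variant-level* interpretive categories, and
* the eleven reporting/validation actions the decision matrix can emit.

They are deliberately closed enums: the decision matrix is total over the
gene x variant cross-product and adding a label silently would punch a hole
in it.  Each label carries the human-readable wording used in call files and
report tables.
"""

from __future__ import annotations

import enum


class AnalysisType(str, enum.Enum):
    """Which upstream inheritance-model filter produced a variant list."""

    DE_NOVO = "de_novo"
    RECESSIVE = "recessive"
    COMPOUND_HET = "compound_het"
    DOMINANT = "dominant"
    X_LINKED = "x_linked"
    HGMD = "hgmd"
    SECONDARY = "secondary"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class InheritancePattern(str, enum.Enum):
    """Inheritance pattern used by the allele-frequency benign rule."""

    RECESSIVE = "recessive"
    X_LINKED = "x_linked"
    DOMINANT = "dominant"
    DE_NOVO = "de_novo"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class GeneLevelCall(str, enum.Enum):
    """Phenotype applicability of the gene to the case under review."""

    PHENOTYPE_YES = "phenotype_yes"
    UNCERTAIN_POSSIBLY = "uncertain_possibly"
    NO_CLEARLY_UNRELATED = "no_clearly_unrelated"
    NO_LITTLE_EVIDENCE = "no_little_evidence"
    DE_NOVO_NO_LITTLE_EVIDENCE = "de_novo_no_little_evidence"
    REPORTABLE_SECONDARY = "reportable_secondary"

    @property
    def label(self) -> str:
        return _GENE_LABELS[self]

    @property
    def is_no_little_evidence(self) -> bool:
        """True for the two no/little-phenotypic-evidence columns."""
        return self in (
            GeneLevelCall.NO_LITTLE_EVIDENCE,
            GeneLevelCall.DE_NOVO_NO_LITTLE_EVIDENCE,
        )

    def __str__(self) -> str:
        return self.value


_GENE_LABELS = {
    GeneLevelCall.PHENOTYPE_YES: "Yes",
    GeneLevelCall.UNCERTAIN_POSSIBLY: "Uncertain/possibly",
    GeneLevelCall.NO_CLEARLY_UNRELATED: "No (clearly unrelated)",
    GeneLevelCall.NO_LITTLE_EVIDENCE: "No/little phenotypic evidence available",
    GeneLevelCall.DE_NOVO_NO_LITTLE_EVIDENCE: "de novo - No/little phenotypic evidence",
    GeneLevelCall.REPORTABLE_SECONDARY: "Reportable secondary finding",
}


class VariantLevelCall(str, enum.Enum):
    """Interpretive category assigned to a single variant."""

    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    INTRONIC_LIKELY_BENIGN = "intronic_likely_benign"
    VUS = "vus"
    DELETERIOUS_VUS = "deleterious_vus"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"
    MAPPING_ERROR = "mapping_error"
    COMPOUND_HET_ERROR = "compound_het_error"

    @property
    def label(self) -> str:
        return _VARIANT_LABELS[self]

    @property
    def is_benign_class(self) -> bool:
        """Benign-spectrum calls, as used by the compound-het sanity check."""
        return self in (
            VariantLevelCall.BENIGN,
            VariantLevelCall.LIKELY_BENIGN,
            VariantLevelCall.INTRONIC_LIKELY_BENIGN,
        )

    def __str__(self) -> str:
        return self.value


_VARIANT_LABELS = {
    VariantLevelCall.BENIGN: "Benign",
    VariantLevelCall.LIKELY_BENIGN: "Likely benign",
    VariantLevelCall.INTRONIC_LIKELY_BENIGN: "Intronic-likely benign",
    VariantLevelCall.VUS: "VUS",
    VariantLevelCall.DELETERIOUS_VUS: "Deleterious VUS",
    VariantLevelCall.LIKELY_PATHOGENIC: "Likely pathogenic",
    VariantLevelCall.PATHOGENIC: "Pathogenic",
    VariantLevelCall.MAPPING_ERROR: "Mapping error",
    VariantLevelCall.COMPOUND_HET_ERROR: "CompoundHet error",
}


class Action(str, enum.Enum):
    """One cell of the reporting/validation decision matrix."""

    DO_NOT_REPORT = "do_not_report"
    REPORT = "report"
    REPORT_AND_SANGER = "report_and_sanger"
    REPORT_AS_VUS = "report_as_vus"
    REPORT_AS_VUS_AND_SANGER = "report_as_vus_and_sanger"
    REPORT_AS_SECONDARY_AND_SANGER = "report_as_secondary_and_sanger"
    NEED_DISCUSSION = "need_discussion"
    INVESTIGATE_VIA_SANGER = "investigate_via_sanger"
    ERROR_CHANGE_CATEGORY = "error_change_category"
    ERROR_CHANGE_TO_DELETERIOUS_VUS = "error_change_to_deleterious_vus"
    ERROR_NOT_COMPOUND_HET = "error_not_compound_het"

    @property
    def label(self) -> str:
        return _ACTION_LABELS[self]

    def reportable(self) -> bool:
        """Does this action put the variant on the clinical report?"""
        return self in _REPORTABLE

    def sanger_required(self) -> bool:
        """Does this action require orthogonal Sanger confirmation?"""
        return self in _SANGER

    def is_error(self) -> bool:
        """Is this a mis-categorisation that must be corrected by the reviewer?"""
        return self in _ERRORS

    def needs_discussion(self) -> bool:
        """Does this action route the variant to the group meeting?"""
        return self in (Action.NEED_DISCUSSION, Action.INVESTIGATE_VIA_SANGER)

    def __str__(self) -> str:
        return self.value


_ACTION_LABELS = {
    Action.DO_NOT_REPORT: "Do not report",
    Action.REPORT: "Report",
    Action.REPORT_AND_SANGER: "Report & Sanger",
    Action.REPORT_AS_VUS: "Report as VUS",
    Action.REPORT_AS_VUS_AND_SANGER: "Report as VUS & Sanger",
    Action.REPORT_AS_SECONDARY_AND_SANGER: "Report as secondary & Sanger",
    Action.NEED_DISCUSSION: "Need discussion",
    Action.INVESTIGATE_VIA_SANGER: "Investigate further via Sanger",
    Action.ERROR_CHANGE_CATEGORY: "Error - please change category",
    Action.ERROR_CHANGE_TO_DELETERIOUS_VUS: "Error - please change to Deleterious VUS",
    Action.ERROR_NOT_COMPOUND_HET: "Error - not compound het",
}

_REPORTABLE = frozenset(
    {
        Action.REPORT,
        Action.REPORT_AND_SANGER,
        Action.REPORT_AS_VUS,
        Action.REPORT_AS_VUS_AND_SANGER,
        Action.REPORT_AS_SECONDARY_AND_SANGER,
    }
)

_SANGER = frozenset(
    {
        Action.REPORT_AND_SANGER,
        Action.REPORT_AS_VUS_AND_SANGER,
        Action.REPORT_AS_SECONDARY_AND_SANGER,
        Action.INVESTIGATE_VIA_SANGER,
    }
)

_ERRORS = frozenset(
    {
        Action.ERROR_CHANGE_CATEGORY,
        Action.ERROR_CHANGE_TO_DELETERIOUS_VUS,
        Action.ERROR_NOT_COMPOUND_HET,
    }
)


def _build_lookup(enum_cls):
    table = {}
    for member in enum_cls:
        table[member.value] = member
        table[member.name.lower()] = member
        label = getattr(member, "label", None)
        if label:
            table[label.lower()] = member
    return table


_GENE_LOOKUP = _build_lookup(GeneLevelCall)
_VARIANT_LOOKUP = _build_lookup(VariantLevelCall)
_ACTION_LOOKUP = _build_lookup(Action)


def parse_gene_call(text: str) -> GeneLevelCall:
    """Parse a gene-level call from its enum value, name, or display label."""
    try:
        return _GENE_LOOKUP[text.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown gene-level call: {text!r}") from None


def parse_variant_call(text: str) -> VariantLevelCall:
    """Parse a variant-level call from its enum value, name, or display label."""
    try:
        return _VARIANT_LOOKUP[text.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown variant-level call: {text!r}") from None


def parse_action(text: str) -> Action:
    """Parse an action from its enum value, name, or display label."""
    try:
        return _ACTION_LOOKUP[text.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown action: {text!r}") from None
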