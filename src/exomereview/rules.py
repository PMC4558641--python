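"""Automatable variant-level classification criteria.

These are the rules a reviewer applies mechanically before exercising
judgement:

* **Benign by frequency** — an allele seen in >1 % of a reference population
  under a recessive or X-linked model (with hemizygous males reported for
  X-linked), or >0.1 % under a dominant or de novo model, is too common to
  cause the rare phenotype under test.
* **Likely benign repeat indel** — an in-frame insertion/deletion of 1–2
  amino acids inside a homopolymeric/tandem repeat of at least 8 units.
* **Intronic likely benign** — intronic changes outside the canonical splice
  positions (-1, -2, +1, +2), unless a disease database asserts
  pathogenicity.
* **Putative loss of function** — nonsense, frameshift, or canonical-splice
  changes, recognised from the nomenclature.
* **Compound-het sanity check** — a "compound heterozygous" gene with only a
  single non-benign variant cannot be compound heterozygous.

Everything here is a suggestion engine: reviewers always see the triggering
rationale and may override.  Nomenclature handling is pattern-based (intronic
offsets, ``Ter``/``*``/``fs`` tokens), not a full HGVS grammar; strings that
do not look like HGVS raise rather than silently passing, because upstream
nomenclature is occasionally wrong.
"""

from __future__ import annotations

import dataclasses
import enum
import re
from typing import Optional, Sequence

from .annotation import AnnotationBundle, is_pathogenic_assertion
from .config import ProjectConfig
from .errors import (
    CallValidationError,
    HgvsParseError,
    NotEvaluableError,
    RuleNotApplicableError,
)
from .variant_io import VariantRecord
from .vocab import AnalysisType, GeneLevelCall, InheritancePattern, VariantLevelCall

# ---------------------------------------------------------------------------
# Inheritance context
# ---------------------------------------------------------------------------

_PATTERN_BY_ANALYSIS = {
    AnalysisType.RECESSIVE: InheritancePattern.RECESSIVE,
    AnalysisType.COMPOUND_HET: InheritancePattern.RECESSIVE,
    AnalysisType.X_LINKED: InheritancePattern.X_LINKED,
    AnalysisType.DOMINANT: InheritancePattern.DOMINANT,
    AnalysisType.DE_NOVO: InheritancePattern.DE_NOVO,
}


@dataclasses.dataclass(frozen=True)
class InheritanceContext:
    """Inheritance pattern plus the X-linked hemizygote evidence."""

    pattern: InheritancePattern
    hemi_male_count: int = 0

    @classmethod
    def from_analysis_type(
        cls,
        analysis_type: AnalysisType | str,
        hemi_male_count: int = 0,
        default_pattern: InheritancePattern = InheritancePattern.RECESSIVE,
    ) -> "InheritanceContext":
        """Derive the pattern from the source list's analysis type.

        Disease-database and secondary-finding lists carry no inheritance
        model of their own; they fall back to ``default_pattern`` (recessive,
        i.e. the stricter 1 % threshold, unless the caller knows better).
        """
        analysis_type = AnalysisType(analysis_type)
        pattern = _PATTERN_BY_ANALYSIS.get(analysis_type, default_pattern)
        return cls(pattern=pattern, hemi_male_count=hemi_male_count)


# ---------------------------------------------------------------------------
# Benign frequency rule
# ---------------------------------------------------------------------------


def benign_frequency_met(
    af: Optional[float],
    ctx: InheritanceContext,
    config: Optional[ProjectConfig] = None,
) -> bool:
    """Is the allele common enough to call benign under this model?

    Strict inequalities: >1 % for recessive/X-linked, >0.1 % for dominant/de
    novo.  The X-linked pattern additionally requires at least
    ``config.hemi_male_min`` hemizygous males reported in the databases —
    a common X allele never observed hemizygous may still be deleterious in
    males.  A missing frequency never satisfies the rule.
    """
    if af is None:
        return False
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency outside [0, 1]: {af}")
    config = config or ProjectConfig()
    if ctx.pattern in (InheritancePattern.RECESSIVE, InheritancePattern.X_LINKED):
        if af <= config.af_threshold_recessive:
            return False
        if ctx.pattern is InheritancePattern.X_LINKED:
            return ctx.hemi_male_count >= config.hemi_male_min
        return True
    return af > config.af_threshold_dominant


# ---------------------------------------------------------------------------
# Protein nomenclature helpers
# ---------------------------------------------------------------------------

_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|"
    "Tyr|Val|Ter|Sec"
)
_RESIDUE = rf"(?:{_AA3}|[A-Z])(\d+)"
_INDEL_RE = re.compile(
    rf"^p\.\(?{_RESIDUE}(?:_{_RESIDUE})?(del|dup|ins)((?:{_AA3}|[A-Z])*)\)?$"
)


def parse_inframe_indel(hgvs_p: str) -> Optional[int]:
    """Length in amino acids of an in-frame protein indel, else ``None``.

    Recognises ``p.Gln10del``, ``p.Gln10_Gln12del``, ``p.Gln10dup``,
    ``p.Gln10_Gln11insAla`` (and one-letter forms).  Frameshifts are *not*
    in-frame and return ``None``.
    """
    if not hgvs_p or is_frameshift(hgvs_p):
        return None
    m = _INDEL_RE.match(hgvs_p.strip())
    if not m:
        return None
    start, end, kind, inserted = m.group(1), m.group(2), m.group(3), m.group(4)
    if kind in ("del", "dup"):
        if end is None:
            return 1
        return int(end) - int(start) + 1
    # insertion: count inserted residues (three-letter triplets or one-letter)
    if not inserted:
        return None
    triplets = re.findall(rf"(?:{_AA3})", inserted)
    if triplets and sum(len(t) for t in triplets) == len(inserted):
        return len(triplets)
    return len(inserted)


def is_frameshift(hgvs_p: str) -> bool:
    return bool(re.search(r"fs", hgvs_p or ""))


def is_nonsense(hgvs_p: str) -> bool:
    """Premature stop: protein change ends in ``Ter``, ``*`` or ``X``."""
    if not hgvs_p:
        return False
    p = hgvs_p.strip().rstrip(")")
    return bool(re.search(r"(Ter|\*|(?<=\d)X)$", p))


# ---------------------------------------------------------------------------
# Repeat-region indel rule
# ---------------------------------------------------------------------------


def _longest_run_covering_center(context: str, unit_length: int) -> int:
    """Longest tandem run of a ``unit_length``-mer whose span covers the
    context's central position."""
    center = len(context) // 2
    best = 0
    for phase in range(unit_length):
        chunks = [
            context[i : i + unit_length]
            for i in range(phase, len(context) - unit_length + 1, unit_length)
        ]
        run_start = 0
        for i in range(1, len(chunks) + 1):
            if i == len(chunks) or chunks[i] != chunks[run_start]:
                span_lo = phase + run_start * unit_length
                span_hi = phase + i * unit_length  # exclusive
                if span_lo <= center < span_hi and i - run_start > best:
                    best = i - run_start
                if i < len(chunks):
                    run_start = i
    return best


def repeat_indel_likely_benign(
    hgvs_p: str,
    peptide_context: str,
    indel_len_aa: int,
    config: Optional[ProjectConfig] = None,
) -> bool:
    """Likely-benign test for small in-frame indels in repeat regions.

    True iff the indel removes/adds 1–2 amino acids and the site (the centre
    of ``peptide_context``) lies inside a tandem run of at least 8 identical
    repeat units.  Frameshifts are outside this rule's domain and raise
    :class:`RuleNotApplicableError` (they route to loss-of-function logic).
    """
    if is_frameshift(hgvs_p):
        raise RuleNotApplicableError(
            f"frameshift {hgvs_p!r} is not an in-frame indel; apply LoF logic"
        )
    if not peptide_context:
        return False
    config = config or ProjectConfig()
    if not 1 <= indel_len_aa <= config.repeat_max_indel_aa:
        return False
    run = _longest_run_covering_center(
        peptide_context.upper(), config.repeat_unit_length
    )
    return run >= config.repeat_min_units


# ---------------------------------------------------------------------------
# Intronic rule
# ---------------------------------------------------------------------------


class IntronicStatus(enum.Enum):
    INTRONIC_LIKELY_BENIGN_CANDIDATE = "intronic_likely_benign_candidate"
    CANONICAL_SPLICE = "canonical_splice"
    NOT_INTRONIC = "not_intronic"
    OVERRIDDEN_BY_ASSERTION = "overridden_by_assertion"


_HGVS_C_RE = re.compile(r"^c\.[0-9*+\-_A-Za-z>\[\]();=]+$")
_OFFSET_RE = re.compile(r"\d+([+-])(\d+)")


def intronic_offsets(hgvs_c: str) -> list[int]:
    """Signed intronic offsets found in a coding-DNA description.

    ``c.1024+5G>A`` -> ``[+5]``; ``c.217T>C`` -> ``[]``.  UTR positions such
    as ``c.-12G>A`` carry no exon-anchored offset and yield nothing.
    """
    if not hgvs_c or not _HGVS_C_RE.match(hgvs_c.strip()):
        raise HgvsParseError(hgvs_c)
    return [
        int(sign + digits)
        for sign, digits in _OFFSET_RE.findall(hgvs_c.strip())
    ]


def intronic_rule(
    hgvs_c: str, pathogenic_assertions: Sequence[str] = ()
) -> IntronicStatus:
    """Classify an intronic change against the canonical-splice exception.

    Offsets of magnitude 1 or 2 are canonical splice positions.  Deeper
    intronic changes are likely-benign candidates unless a disease database
    (HGMD/ClinVar) asserts pathogenic/likely pathogenic, which overrides.
    Coding-position descriptions with no offset syntax are not intronic.
    """
    offsets = intronic_offsets(hgvs_c)
    if not offsets:
        return IntronicStatus.NOT_INTRONIC
    if any(abs(offset) <= 2 for offset in offsets):
        return IntronicStatus.CANONICAL_SPLICE
    if any(is_pathogenic_assertion(a) for a in pathogenic_assertions):
        return IntronicStatus.OVERRIDDEN_BY_ASSERTION
    return IntronicStatus.INTRONIC_LIKELY_BENIGN_CANDIDATE


# ---------------------------------------------------------------------------
# Loss-of-function detection
# ---------------------------------------------------------------------------


def is_putative_lof(hgvs_c: str = "", hgvs_p: str = "") -> bool:
    """Nonsense, frameshift, or canonical-splice change?

    These classes are assumed to disrupt gene function.  Requires at least
    one of the two nomenclature fields; raises :class:`NotEvaluableError`
    when both are missing.
    """
    if not hgvs_c and not hgvs_p:
        raise NotEvaluableError(
            "loss-of-function check needs a nucleotide or protein change"
        )
    if hgvs_p and (is_nonsense(hgvs_p) or is_frameshift(hgvs_p)):
        return True
    if hgvs_c:
        try:
            return intronic_rule(hgvs_c) is IntronicStatus.CANONICAL_SPLICE
        except HgvsParseError:
            if not hgvs_p:
                raise
    return False


# ---------------------------------------------------------------------------
# Compound-het sanity check
# ---------------------------------------------------------------------------


def compound_het_error_check(
    gene_calls: Sequence[VariantLevelCall],
    analysis_type: AnalysisType | str,
) -> bool:
    """True iff a compound-het gene holds exactly one non-benign variant.

    Two hits on opposite alleles are required for compound heterozygosity;
    a gene where only a single variant survives benign filtering is a filter
    artefact.  Only meaningful for the compound-het list: any other analysis
    type raises :class:`RuleNotApplicableError`.
    """
    if AnalysisType(analysis_type) is not AnalysisType.COMPOUND_HET:
        raise RuleNotApplicableError(
            "compound-het check applies only to the compound_het variant list"
        )
    non_benign = sum(1 for call in gene_calls if not call.is_benign_class)
    return non_benign == 1


# ---------------------------------------------------------------------------
# Call suggestion
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Suggestion:
    """A suggested variant-level call plus the rationale that triggered it.

    Suggestions never auto-commit; the reviewer records the actual call.
    """

    call: VariantLevelCall
    rationale: list[str]


def effective_population_af(
    variant: VariantRecord, bundle: AnnotationBundle
) -> Optional[float]:
    """Maximum allele frequency across population sources and the input column."""
    candidates = list(bundle.population_afs().values())
    if variant.kg_af is not None:
        candidates.append(variant.kg_af)
    return max(candidates) if candidates else None


def suggest_call(
    variant: VariantRecord,
    bundle: AnnotationBundle,
    ctx: InheritanceContext,
    config: Optional[ProjectConfig] = None,
    gene_call: Optional[GeneLevelCall] = None,
    peptide_context: str = "",
) -> Suggestion:
    """Suggest an interpretive category by rule precedence.

    Precedence: established pathogenic assertion > benign by frequency >
    repeat-region indel (likely benign) > deep-intronic (intronic-likely
    benign) > putative loss of function (likely pathogenic, or deleterious
    VUS when the gene has no/little phenotype evidence) > VUS.

    ``peptide_context`` (the peptide surrounding an in-frame indel) enables
    the repeat rule; ``gene_call``, when already known, steers the
    loss-of-function branch.  Mapping errors and compound-het errors are
    never suggested: the first needs visual read inspection, the second
    gene-set context handled by :func:`compound_het_error_check`.
    """
    config = config or ProjectConfig()

    assertions = bundle.pathogenic_assertions()
    if assertions:
        return Suggestion(
            VariantLevelCall.PATHOGENIC,
            [
                "established disease-causing change: pathogenic assertion(s) "
                + ", ".join(assertions)
            ],
        )

    af = effective_population_af(variant, bundle)
    if benign_frequency_met(
        af,
        dataclasses.replace(
            ctx, hemi_male_count=max(ctx.hemi_male_count, bundle.hemi_male_count() or 0)
        ),
        config,
    ):
        threshold = (
            config.af_threshold_recessive
            if ctx.pattern
            in (InheritancePattern.RECESSIVE, InheritancePattern.X_LINKED)
            else config.af_threshold_dominant
        )
        return Suggestion(
            VariantLevelCall.BENIGN,
            [
                f"population allele frequency {af:g} exceeds {threshold:.3%} "
                f"threshold for {ctx.pattern.value} pattern"
            ],
        )

    indel_len = parse_inframe_indel(variant.hgvs_p)
    if indel_len is not None and peptide_context:
        if repeat_indel_likely_benign(
            variant.hgvs_p, peptide_context, indel_len, config
        ):
            return Suggestion(
                VariantLevelCall.LIKELY_BENIGN,
                [
                    f"in-frame indel of {indel_len} aa inside a repeat run of >= "
                    f"{config.repeat_min_units} units"
                ],
            )

    if variant.hgvs_c:
        status = intronic_rule(variant.hgvs_c, assertions)
        if status is IntronicStatus.INTRONIC_LIKELY_BENIGN_CANDIDATE:
            return Suggestion(
                VariantLevelCall.INTRONIC_LIKELY_BENIGN,
                ["intronic change outside canonical splice positions (-1, -2, +1, +2)"],
            )

    try:
        lof = is_putative_lof(variant.hgvs_c, variant.hgvs_p)
    except NotEvaluableError:
        lof = False
    if lof:
        if gene_call is not None and gene_call.is_no_little_evidence:
            return Suggestion(
                VariantLevelCall.DELETERIOUS_VUS,
                [
                    "putative loss-of-function change in a gene with no/little "
                    "phenotype evidence"
                ],
            )
        return Suggestion(
            VariantLevelCall.LIKELY_PATHOGENIC,
            [
                "putative loss-of-function change (nonsense, frameshift, or "
                "canonical splice)"
            ],
        )

    return Suggestion(VariantLevelCall.VUS, ["no classification rule triggered"])


# ---------------------------------------------------------------------------
# Record-time call validation (footnote conditions)
# ---------------------------------------------------------------------------


def validate_call_context(
    gene_call: GeneLevelCall,
    variant_call: VariantLevelCall,
    analysis_type: AnalysisType,
    secondary_findings_consent: bool = True,
) -> None:
    """Reject call labels used outside their allowed context.

    The vocabularies carry usage restrictions: the de novo no/little-evidence
    gene call is only for the de novo list; reportable-secondary is barred
    when the patient declined secondary findings; the compound-het error
    category only applies to the compound-het list; deleterious VUS pairs
    only with no/little-evidence gene calls.
    """
    if (
        gene_call is GeneLevelCall.DE_NOVO_NO_LITTLE_EVIDENCE
        and analysis_type is not AnalysisType.DE_NOVO
    ):
        raise CallValidationError(
            "'de novo - No/little phenotypic evidence' may only be chosen for "
            f"variants from the de novo list (got {analysis_type.value})"
        )
    if gene_call is GeneLevelCall.REPORTABLE_SECONDARY and not secondary_findings_consent:
        raise CallValidationError(
            "patient declined secondary findings; 'Reportable secondary finding' "
            "is not selectable"
        )
    if (
        variant_call is VariantLevelCall.COMPOUND_HET_ERROR
        and analysis_type is not AnalysisType.COMPOUND_HET
    ):
        raise CallValidationError(
            "'CompoundHet error' may only be used for variants from the "
            f"compound-het list (got {analysis_type.value})"
        )
    if (
        variant_call is VariantLevelCall.DELETERIOUS_VUS
        and not gene_call.is_no_little_evidence
    ):
        raise CallValidationError(
            "'Deleterious VUS' may only be chosen for genes with no/little "
            f"phenotype evidence (gene call was {gene_call.label!r})"
        )
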