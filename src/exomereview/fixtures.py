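"""Synthetic case generation with controlled truth.

The generator emulates the inputs a clinical exome case produces after
upstream filtering: one variant list per inheritance-model analysis, a local
annotation store covering those variants, and simulated reviewer call files.
Every generated variant carries a hidden *truth* — the interpretive category
it was built to trigger — so classification, workflow and reporting can be
tested end-to-end without any external database.

Construction per category:

* ``pathogenic`` — missense change with disease-mutation-database and
  clinical-assertion records in the store.
* ``benign_high_af`` — population allele frequency above the benign
  threshold for the list's inheritance pattern (with hemizygous males
  reported for X-linked lists).
* ``intronic`` — deep-intronic nomenclature (offsets beyond the canonical
  +/-2 splice positions).
* ``repeat_indel`` — in-frame 1–2 aa indel with a generated peptide context
  containing a >= 8-unit repeat run.
* ``lof_no_evidence`` — nonsense / frameshift / canonical-splice change in
  a gene with no/little phenotype evidence (hence truth: deleterious VUS).
* remainder — plain VUS: rare missense with no database support.

The compound-het list is generated without benign-class variants and with
at least two variants per gene, so the two-hit requirement of compound
heterozygosity holds by construction.  Nomenclature is synthesised from
per-category templates; gene symbols and coordinates are synthetic.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import random
from typing import Optional

from .annotation import AnnotationRecord, AnnotationStore
from .config import ProjectConfig
from .decisions import decide
from .errors import FixtureSpecError
from .variant_io import CallRow, VariantKey, VariantRecord
from .vocab import (
    Action,
    AnalysisType,
    GeneLevelCall,
    InheritancePattern,
    VariantLevelCall,
)

CATEGORIES = (
    "pathogenic",
    "benign_high_af",
    "intronic",
    "repeat_indel",
    "lof_no_evidence",
    "vus",
)

#: Default per-list variant counts: the composition of a representative
#: trio-sequenced case (compound-het / recessive / de novo / secondary).
DEFAULT_COUNTS = {
    AnalysisType.COMPOUND_HET: 7,
    AnalysisType.RECESSIVE: 22,
    AnalysisType.DE_NOVO: 4,
    AnalysisType.SECONDARY: 15,
}

#: Default intended-category mix (remainder is plain VUS).
DEFAULT_FRACTIONS = {
    "pathogenic": 0.05,
    "benign_high_af": 0.25,
    "intronic": 0.15,
    "repeat_indel": 0.05,
    "lof_no_evidence": 0.10,
}

_BASES = "ACGT"
_AA1 = "ARNDCQEGHILKMFPSTWYV"
_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


@dataclasses.dataclass
class FixtureSpec:
    """Parameters of one synthetic case."""

    counts: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COUNTS)
    )
    fractions: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    reviewers: int = 2
    discordant: int = 3
    seed: int = 0
    #: Hemizygous males reported for X-linked benign variants; must reach
    #: the hemi_male_min policy or the spec is self-contradictory.
    xlinked_benign_hemi_males: int = 5
    hemi_male_min: int = 3

    def __post_init__(self) -> None:
        self.counts = {AnalysisType(k): int(v) for k, v in self.counts.items()}
        if any(v < 0 for v in self.counts.values()):
            raise FixtureSpecError("variant counts must be non-negative")
        unknown = set(self.fractions) - set(CATEGORIES[:-1])
        if unknown:
            raise FixtureSpecError(
                f"unknown category fraction(s): {', '.join(sorted(unknown))}"
            )
        total = sum(self.fractions.values())
        if any(f < 0 for f in self.fractions.values()) or total > 1.0 + 1e-9:
            raise FixtureSpecError(
                f"category fractions must be non-negative and sum to <= 1 "
                f"(got {total:g})"
            )
        if self.reviewers < 2:
            raise FixtureSpecError("at least two reviewers are required")
        if self.discordant > self.total_variants:
            raise FixtureSpecError(
                f"discordant count {self.discordant} exceeds variant count "
                f"{self.total_variants}"
            )
        if (
            self.counts.get(AnalysisType.X_LINKED, 0) > 0
            and self.fractions.get("benign_high_af", 0) > 0
            and self.xlinked_benign_hemi_males < self.hemi_male_min
        ):
            raise FixtureSpecError(
                "X-linked benign variants require at least "
                f"{self.hemi_male_min} reported hemizygous males "
                f"(got {self.xlinked_benign_hemi_males})"
            )

    @property
    def total_variants(self) -> int:
        return sum(self.counts.values())


@dataclasses.dataclass
class Truth:
    """Hidden intended interpretation of one generated variant."""

    category: str
    variant_call: VariantLevelCall
    gene_call: GeneLevelCall
    peptide_context: str = ""

    @property
    def action(self) -> Action:
        return decide(self.variant_call, self.gene_call)


@dataclasses.dataclass
class GeneratedCase:
    """A complete synthetic case: inputs plus per-variant truth."""

    spec: FixtureSpec
    case_id: str
    variants_by_type: dict[AnalysisType, list[VariantRecord]]
    store_records: list[AnnotationRecord]
    truth: dict[str, Truth]  # key token -> Truth

    @property
    def all_variants(self) -> list[VariantRecord]:
        return [v for at in sorted(self.variants_by_type) for v in self.variants_by_type[at]]

    @property
    def store(self) -> AnnotationStore:
        return AnnotationStore(list(self.store_records))

    def expected_actions(self) -> dict[str, Action]:
        return {token: truth.action for token, truth in self.truth.items()}

    def expected_reportable(self) -> set[str]:
        return {
            token
            for token, action in self.expected_actions().items()
            if action.reportable()
        }


def _allocate(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Floor allocation of n variants over categories; the rest is plain VUS."""
    counts = {c: int(n * fractions.get(c, 0.0)) for c in CATEGORIES[:-1]}
    counts["vus"] = n - sum(counts.values())
    return counts


def _gene_truth(category: str, analysis_type: AnalysisType) -> GeneLevelCall:
    if category == "pathogenic":
        return (
            GeneLevelCall.REPORTABLE_SECONDARY
            if analysis_type is AnalysisType.SECONDARY
            else GeneLevelCall.PHENOTYPE_YES
        )
    if category == "lof_no_evidence":
        return (
            GeneLevelCall.DE_NOVO_NO_LITTLE_EVIDENCE
            if analysis_type is AnalysisType.DE_NOVO
            else GeneLevelCall.NO_LITTLE_EVIDENCE
        )
    if category in ("benign_high_af", "intronic"):
        return GeneLevelCall.NO_CLEARLY_UNRELATED
    if category == "repeat_indel":
        return GeneLevelCall.UNCERTAIN_POSSIBLY
    # plain VUS
    if analysis_type is AnalysisType.DE_NOVO:
        return GeneLevelCall.DE_NOVO_NO_LITTLE_EVIDENCE
    if analysis_type is AnalysisType.SECONDARY:
        return GeneLevelCall.REPORTABLE_SECONDARY
    return GeneLevelCall.UNCERTAIN_POSSIBLY


def _repeat_context(rng: random.Random) -> str:
    unit = rng.choice(_AA1)
    run_len = rng.randint(8, 12)
    flank = "".join(rng.choice(_AA1.replace(unit, "")) for _ in range(4))
    flank2 = "".join(rng.choice(_AA1.replace(unit, "")) for _ in range(4))
    # centre of the context falls inside the run by construction
    return flank + unit * run_len + flank2


def generate_case(spec: FixtureSpec, case_id: str = "CASE-SYNTH") -> GeneratedCase:
    """Generate one synthetic case, deterministic per seed."""
    rng = random.Random(spec.seed)
    variants_by_type: dict[AnalysisType, list[VariantRecord]] = {}
    store_records: list[AnnotationRecord] = []
    truth: dict[str, Truth] = {}
    pos_counter = rng.randint(1_000_000, 2_000_000)
    gene_counter = 0
    accession_counter = 900_000

    for analysis_type in sorted(spec.counts, key=lambda a: a.value):
        n = spec.counts[analysis_type]
        if n == 0:
            variants_by_type[analysis_type] = []
            continue
        fractions = dict(spec.fractions)
        if analysis_type is AnalysisType.COMPOUND_HET:
            # no benign-class variants: a compound-het gene must keep >= 2
            # non-benign hits or it is a filter artefact, not a fixture
            for benign_cat in ("benign_high_af", "intronic", "repeat_indel"):
                fractions[benign_cat] = 0.0
        counts = _allocate(n, fractions)
        categories = [c for c in CATEGORIES for _ in range(counts[c])]
        rng.shuffle(categories)

        # gene assignment: compound-het variants share genes in groups of two
        # (three for an odd count); all other variants get unique genes
        genes: list[str] = []
        if analysis_type is AnalysisType.COMPOUND_HET:
            i = 0
            while i < n:
                gene_counter += 1
                group = 3 if n - i == 3 else 2 if n - i >= 2 else n - i
                genes.extend([f"GENE{gene_counter:04d}"] * group)
                i += group
            if n == 1:
                raise FixtureSpecError(
                    "a compound-het list needs at least two variants"
                )
        else:
            for _ in range(n):
                gene_counter += 1
                genes.append(f"GENE{gene_counter:04d}")

        pattern = InheritancePattern.X_LINKED if analysis_type is AnalysisType.X_LINKED else None
        records = []
        for category, gene in zip(categories, genes):
            pos_counter += rng.randint(1_000, 50_000)
            chrom = "X" if analysis_type is AnalysisType.X_LINKED else str(
                rng.randint(1, 22)
            )
            ref = rng.choice(_BASES)
            alt = rng.choice(_BASES.replace(ref, ""))
            cpos = rng.randint(100, 5000)
            ppos = max(1, cpos // 3)
            aa_from = rng.choice(_AA1)
            aa_to = rng.choice(_AA1.replace(aa_from, ""))
            hgvs_c = f"c.{cpos}{ref}>{alt}"
            hgvs_p = f"p.{_AA3[aa_from]}{ppos}{_AA3[aa_to]}"
            kg_af: Optional[float] = None
            peptide_context = ""
            zygosity = {
                AnalysisType.RECESSIVE: "hom",
                AnalysisType.X_LINKED: "hemi",
            }.get(analysis_type, "het")

            key = VariantKey(chrom=chrom, pos=pos_counter, ref=ref, alt=alt)
            if category == "pathogenic":
                accession_counter += rng.randint(1, 50)
                store_records.append(
                    AnnotationRecord(
                        source="HGMD", key=key, assertion=f"CM{accession_counter}"
                    )
                )
                store_records.append(
                    AnnotationRecord(
                        source="ClinVar",
                        key=key,
                        assertion=f"RCV{accession_counter:09d}.1 Pathogenic",
                    )
                )
                kg_af = round(rng.uniform(0.00001, 0.0005), 6)
            elif category == "benign_high_af":
                if pattern is InheritancePattern.X_LINKED or analysis_type in (
                    AnalysisType.RECESSIVE,
                    AnalysisType.COMPOUND_HET,
                    AnalysisType.HGMD,
                    AnalysisType.SECONDARY,
                ):
                    kg_af = round(rng.uniform(0.02, 0.20), 4)
                else:  # dominant / de novo threshold is 0.1 %
                    kg_af = round(rng.uniform(0.005, 0.05), 4)
                hemi = (
                    spec.xlinked_benign_hemi_males
                    if pattern is InheritancePattern.X_LINKED
                    else None
                )
                store_records.append(
                    AnnotationRecord(
                        source="ExAC", key=key, af=kg_af, hemi_male_count=hemi
                    )
                )
            elif category == "intronic":
                offset = rng.choice([3, 5, 7, 11, 17, 25, 40])
                sign = rng.choice("+-")
                hgvs_c = f"c.{cpos}{sign}{offset}{ref}>{alt}"
                hgvs_p = ""
                kg_af = round(rng.uniform(0.0, 0.0005), 6)
            elif category == "repeat_indel":
                indel_len = rng.choice([1, 2])
                if indel_len == 1:
                    hgvs_p = f"p.{_AA3[aa_from]}{ppos}del"
                else:
                    hgvs_p = f"p.{_AA3[aa_from]}{ppos}_{_AA3[aa_from]}{ppos + 1}del"
                hgvs_c = f"c.{cpos}_{cpos + 3 * indel_len - 1}del"
                peptide_context = _repeat_context(rng)
            elif category == "lof_no_evidence":
                flavour = rng.choice(["nonsense", "frameshift", "splice"])
                if flavour == "nonsense":
                    hgvs_p = f"p.{_AA3[aa_from]}{ppos}Ter"
                elif flavour == "frameshift":
                    hgvs_p = f"p.{_AA3[aa_from]}{ppos}{_AA3[aa_to]}fs"
                    hgvs_c = f"c.{cpos}del"
                else:
                    hgvs_c = f"c.{cpos}{rng.choice('+-')}{rng.choice([1, 2])}{ref}>{alt}"
                    hgvs_p = ""
            else:  # plain VUS: rare missense, nothing in the store
                if rng.random() < 0.5:
                    kg_af = round(rng.uniform(0.0, 0.0005), 6)

            record = VariantRecord(
                chrom=chrom,
                pos=pos_counter,
                ref=ref,
                alt=alt,
                gene=gene,
                transcript=f"NM_{100000 + gene_counter}",
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                sift=rng.choice(["tolerated", "damaging", ""]),
                polyphen=rng.choice(["benign", "possibly_damaging", "probably_damaging", ""]),
                phylop_p=round(rng.uniform(0.0, 1.0), 4),
                dbsnp_id=f"rs{rng.randint(10_000_000, 99_999_999)}"
                if rng.random() < 0.5
                else "",
                kg_af=kg_af,
                analysis_type=analysis_type,
                zygosity=zygosity,
            )
            records.append(record)
            truth[key.token()] = Truth(
                category=category,
                variant_call={
                    "pathogenic": VariantLevelCall.PATHOGENIC,
                    "benign_high_af": VariantLevelCall.BENIGN,
                    "intronic": VariantLevelCall.INTRONIC_LIKELY_BENIGN,
                    "repeat_indel": VariantLevelCall.LIKELY_BENIGN,
                    "lof_no_evidence": VariantLevelCall.DELETERIOUS_VUS,
                    "vus": VariantLevelCall.VUS,
                }[category],
                gene_call=_gene_truth(category, analysis_type),
                peptide_context=peptide_context,
            )
        variants_by_type[analysis_type] = records

    return GeneratedCase(
        spec=spec,
        case_id=case_id,
        variants_by_type=variants_by_type,
        store_records=store_records,
        truth=truth,
    )


@dataclasses.dataclass
class SimulatedReviews:
    """Reviewer call rows plus the generator's own discordance bookkeeping."""

    reviewer_ids: list[str]
    calls: dict[str, list[CallRow]]  # reviewer id -> rows
    discordant_tokens: set[str]


def simulate_reviews(
    case: GeneratedCase,
    reviewers: Optional[int] = None,
    discordant: Optional[int] = None,
    seed: Optional[int] = None,
) -> SimulatedReviews:
    """Simulate independent reviews: truth-derived calls with a controlled
    number of discordant variants.

    Exactly ``discordant`` variants receive differing call pairs (the second
    reviewer swaps the variant-level call for mapping-error or VUS); all
    other variants receive identical truth-derived calls from every
    reviewer.
    """
    spec = case.spec
    reviewers = spec.reviewers if reviewers is None else reviewers
    discordant = spec.discordant if discordant is None else discordant
    seed = spec.seed if seed is None else seed
    if reviewers < 2:
        raise FixtureSpecError("at least two reviewers are required")
    tokens = [v.key.token() for v in case.all_variants]
    if discordant > len(tokens):
        raise FixtureSpecError("discordant count exceeds variant count")
    rng = random.Random(seed + 1)
    discordant_tokens = set(rng.sample(tokens, discordant))
    reviewer_ids = [f"reviewer{i + 1:02d}" for i in range(reviewers)]
    calls: dict[str, list[CallRow]] = {r: [] for r in reviewer_ids}
    for variant in case.all_variants:
        token = variant.key.token()
        t = case.truth[token]
        for j, reviewer in enumerate(reviewer_ids):
            variant_call = t.variant_call
            if token in discordant_tokens and j == 1:
                variant_call = (
                    VariantLevelCall.MAPPING_ERROR
                    if t.variant_call is not VariantLevelCall.MAPPING_ERROR
                    else VariantLevelCall.VUS
                )
            calls[reviewer].append(
                CallRow(
                    key=variant.key,
                    gene_call=t.gene_call,
                    variant_call=variant_call,
                    comment=f"simulated review ({t.category})",
                    reviewer=reviewer,
                )
            )
    return SimulatedReviews(
        reviewer_ids=reviewer_ids, calls=calls, discordant_tokens=discordant_tokens
    )


def execute_case(
    case: GeneratedCase,
    sim: Optional[SimulatedReviews] = None,
    config: Optional[ProjectConfig] = None,
):
    """Run a generated case through the full pipeline.

    Uploads, distributes to all simulated reviewers, ingests their calls,
    merges, resolves every discussion-queue variant to its truth calls,
    confirms the whole Sanger queue and generates the report.  Returns
    ``(project, report)``.
    """
    from .reporting import generate_report
    from .workflow import CaseProject

    sim = sim or simulate_reviews(case)
    config = config or ProjectConfig(hemi_male_min=case.spec.hemi_male_min)
    project = CaseProject(case.case_id, config)
    project.upload(case.all_variants)
    deadline = _dt.date.today() + _dt.timedelta(days=14)
    project.distribute(
        sim.reviewer_ids,
        deadline,
        min_reviewers=len(sim.reviewer_ids),
        seed=case.spec.seed,
    )
    for reviewer in sim.reviewer_ids:
        project.ingest_call_rows(sim.calls[reviewer])
    project.merge_and_flag()
    for row in project.discussion_queue():
        token = row.variant.token()
        t = case.truth[token]
        project.resolve(
            row.variant,
            t.gene_call,
            t.variant_call,
            minutes="group meeting: consensus on truth-derived interpretation",
        )
    project.build_sanger_queue()
    for token in list(project.pending_validation()):
        project.record_sanger_result(VariantKey.from_token(token), confirmed=True)
    report = generate_report(project, case.store)
    return project, report
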