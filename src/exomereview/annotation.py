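"""File-backed annotation store and external-link construction.

In production a clinical lab joins each candidate variant against a battery
of population and disease databases (dbSNP, 1000 Genomes, ESP6500, UK10K,
Wellderly, ExAC, dbNSFP, HGMD, ClinVar, OMIM, GERA, biobank genotypes and an
in-house curated disease-variant collection).  This module provides the same
join against a local table of per-variant facts: allele frequencies,
hemizygous-male counts, clinical assertions/accessions, and hyperlinks back
to each source.  Lookups are pure: the store is read-only after loading.

Gene-level sources (e.g. OMIM) are keyed by gene symbol; everything else by
the (chrom, pos, ref, alt) variant key.
"""

from __future__ import annotations

import dataclasses
import json
import csv
from pathlib import Path
from typing import Optional, Union

from .config import ProjectConfig
from .errors import StoreError
from .variant_io import VariantKey, VariantRecord, normalize_chrom, parse_fraction

#: Registered annotation sources and whether each is keyed by variant or gene.
SOURCES: dict[str, str] = {
    "dbSNP": "variant",
    "1000 Genome": "variant",
    "ESP6500": "variant",
    "UK10K control": "variant",
    "Scripps Wellderly": "variant",
    "ExAC": "variant",
    "dbNSFP": "variant",
    "HGMD": "variant",
    "ClinVar": "variant",
    "OMIM": "gene",
    "UK10K disease": "variant",
    "GERA": "variant",
    "Mount Sinai Biobank": "variant",
    "VarDi": "variant",
}

#: Population sources whose allele frequencies feed the benign frequency rule.
POPULATION_AF_SOURCES = (
    "1000 Genome",
    "ESP6500",
    "ExAC",
    "UK10K control",
    "Scripps Wellderly",
)

#: Sources whose assertions carry clinical pathogenicity weight.
CLINICAL_ASSERTION_SOURCES = ("HGMD", "ClinVar")

_SOURCE_LOOKUP = {s.lower(): s for s in SOURCES}


def canonical_source(name: str) -> str:
    """Resolve a source label case-insensitively; raise StoreError if unknown."""
    try:
        return _SOURCE_LOOKUP[name.strip().lower()]
    except KeyError:
        registered = ", ".join(SOURCES)
        raise StoreError(
            f"unknown annotation source {name!r}; registered sources: {registered}"
        ) from None


@dataclasses.dataclass
class AnnotationRecord:
    """Per-source facts for one variant (or one gene, for gene-level sources)."""

    source: str
    key: Union[VariantKey, str]  # VariantKey, or gene symbol for gene-level sources
    af: Optional[float] = None
    hemi_male_count: Optional[int] = None
    assertion: str = ""
    url: str = ""

    def __post_init__(self) -> None:
        self.source = canonical_source(self.source)
        if self.af is not None and not 0.0 <= self.af <= 1.0:
            raise ValueError(f"allele frequency outside [0, 1]: {self.af}")
        if self.hemi_male_count is not None and self.hemi_male_count < 0:
            raise ValueError("hemizygous male count must be >= 0")


@dataclasses.dataclass
class AnnotationBundle:
    """Everything the store knows about one variant, grouped by source."""

    variant: VariantKey
    records: list[AnnotationRecord] = dataclasses.field(default_factory=list)
    gene_links: dict[str, str] = dataclasses.field(default_factory=dict)
    locus_link: str = ""

    def by_source(self, source: str) -> list[AnnotationRecord]:
        source = canonical_source(source)
        return [r for r in self.records if r.source == source]

    def population_afs(self) -> dict[str, float]:
        """Allele frequencies from the registered population sources."""
        return {
            r.source: r.af
            for r in self.records
            if r.source in POPULATION_AF_SOURCES and r.af is not None
        }

    def max_population_af(self) -> Optional[float]:
        afs = self.population_afs()
        return max(afs.values()) if afs else None

    def hemi_male_count(self) -> Optional[int]:
        counts = [
            r.hemi_male_count for r in self.records if r.hemi_male_count is not None
        ]
        return max(counts) if counts else None

    def pathogenic_assertions(self) -> list[str]:
        """Pathogenic / likely-pathogenic assertions from HGMD or ClinVar."""
        return [
            r.assertion
            for r in self.records
            if r.source in CLINICAL_ASSERTION_SOURCES
            and r.assertion
            and is_pathogenic_assertion(r.assertion)
        ]


def is_pathogenic_assertion(assertion: str) -> bool:
    """Does an assertion string assert (likely) pathogenicity?

    Accepts explicit significance labels ("Pathogenic", "Likely pathogenic"),
    the disease-mutation class "DM", and bare HGMD ``CM``/ClinVar ``RCV``
    accessions — a curated accession in a disease-mutation database is itself
    the assertion.
    """
    a = assertion.strip()
    low = a.lower()
    if "pathogenic" in low and "non-pathogenic" not in low:
        return True
    if low in ("dm", "dm?"):
        return True
    head = a.split(".", 1)[0]
    return (head.startswith("CM") or head.startswith("RCV")) and any(
        ch.isdigit() for ch in head
    )


STORE_COLUMNS = (
    "source",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "af",
    "hemi_male_count",
    "assertion",
)


class AnnotationStore:
    """Indexed, read-only collection of annotation records."""

    def __init__(self, records: list[AnnotationRecord]):
        self._by_variant: dict[VariantKey, list[AnnotationRecord]] = {}
        self._by_gene: dict[str, list[AnnotationRecord]] = {}
        seen: set[tuple[str, object]] = set()
        for record in records:
            pair = (record.source, record.key)
            if pair in seen:
                raise StoreError(
                    f"duplicate annotation for source={record.source!r}, "
                    f"key={record.key!r}"
                )
            seen.add(pair)
            if isinstance(record.key, VariantKey):
                self._by_variant.setdefault(record.key, []).append(record)
            else:
                self._by_gene.setdefault(record.key.upper(), []).append(record)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_variant.values()) + sum(
            len(v) for v in self._by_gene.values()
        )

    def variant_records(self, key: VariantKey) -> list[AnnotationRecord]:
        return list(self._by_variant.get(key, []))

    def gene_records(self, gene: str) -> list[AnnotationRecord]:
        return list(self._by_gene.get(gene.upper(), []))


def load_store(path: str | Path) -> AnnotationStore:
    """Load an annotation store from a TSV (or JSON list) of records.

    TSV columns: source, chrom, pos, ref, alt, gene, af, hemi_male_count,
    assertion.  Variant-level rows fill chrom/pos/ref/alt; gene-level rows
    fill gene only.  Frequencies may be fractions or percent strings.
    """
    path = Path(path)
    rows: list[dict]
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
    else:
        with path.open(newline="", encoding="utf-8") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            if reader.fieldnames is None:
                raise StoreError(f"{path}: empty store file")
            missing = set(STORE_COLUMNS) - {f.strip() for f in reader.fieldnames}
            if missing:
                raise StoreError(
                    f"{path}: missing store column(s): {', '.join(sorted(missing))}"
                )
            rows = list(reader)
    records = []
    for row in rows:
        source = canonical_source(str(row["source"]))
        gene = (row.get("gene") or "").strip()
        chrom = (row.get("chrom") or "").strip()
        key: Union[VariantKey, str]
        if SOURCES[source] == "gene":
            if not gene:
                raise StoreError(f"gene-level source {source!r} requires a gene symbol")
            key = gene
        else:
            if not chrom:
                raise StoreError(
                    f"variant-level source {source!r} requires chrom/pos/ref/alt"
                )
            key = VariantKey(
                chrom=normalize_chrom(chrom),
                pos=int(row["pos"]),
                ref=str(row["ref"]).strip(),
                alt=str(row["alt"]).strip(),
            )
        af_text = str(row.get("af") or "").strip()
        hemi_text = str(row.get("hemi_male_count") or "").strip()
        records.append(
            AnnotationRecord(
                source=source,
                key=key,
                af=parse_fraction(af_text) if af_text else None,
                hemi_male_count=int(hemi_text) if hemi_text else None,
                assertion=str(row.get("assertion") or "").strip(),
            )
        )
    return AnnotationStore(records)


def write_store(records: list[AnnotationRecord], path: str | Path) -> None:
    """Write annotation records as a TSV loadable by :func:`load_store`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(STORE_COLUMNS)
        for r in records:
            if isinstance(r.key, VariantKey):
                chrom, pos, ref, alt, gene = r.key.chrom, r.key.pos, r.key.ref, r.key.alt, ""
            else:
                chrom, pos, ref, alt, gene = "", "", "", "", r.key
            writer.writerow(
                [
                    r.source,
                    chrom,
                    pos,
                    ref,
                    alt,
                    gene,
                    "" if r.af is None else repr(r.af),
                    "" if r.hemi_male_count is None else r.hemi_male_count,
                    r.assertion,
                ]
            )


def build_url(
    source: str,
    key: VariantKey,
    config: ProjectConfig,
    *,
    gene: str = "",
    rsid: str = "",
    assertion: str = "",
) -> str:
    """Deterministic external link for one (source, variant) pair.

    Falls back to the key token when a source-specific identifier (rsid,
    accession) is absent, so the link always carries an identifying token.
    """
    template = config.link_templates.get(source, "{token}")
    token = key.token()
    return template.format(
        token=token,
        rsid=rsid or token,
        gene=gene or token,
        assertion=assertion or token,
        chrom=key.chrom,
        pos=key.pos,
    )


def annotate(
    variant: VariantRecord,
    store: AnnotationStore,
    config: Optional[ProjectConfig] = None,
) -> AnnotationBundle:
    """Assemble the annotation bundle for one variant.

    The variant's own 1000 Genomes column is merged in as a "1000 Genome"
    record when the store has none for this key, so the frequency rule sees
    the same evidence the reviewer sees in the input table.  Gene and locus
    links are always populated, even for a completely novel variant.
    """
    config = config or ProjectConfig()
    key = variant.key
    records = [dataclasses.replace(r) for r in store.variant_records(key)]
    if variant.gene:
        records.extend(dataclasses.replace(r) for r in store.gene_records(variant.gene))
    if variant.kg_af is not None and not any(
        r.source == "1000 Genome" for r in records
    ):
        records.append(AnnotationRecord(source="1000 Genome", key=key, af=variant.kg_af))
    for record in records:
        record.url = build_url(
            record.source,
            key,
            config,
            gene=variant.gene,
            rsid=variant.dbsnp_id,
            assertion=record.assertion,
        )
    if variant.dbsnp_id and not any(r.source == "dbSNP" for r in records):
        records.append(
            AnnotationRecord(
                source="dbSNP",
                key=key,
                assertion=variant.dbsnp_id,
                url=build_url("dbSNP", key, config, rsid=variant.dbsnp_id),
            )
        )
    records.sort(key=lambda r: (list(SOURCES).index(r.source), str(r.key)))
    return AnnotationBundle(
        variant=key,
        records=records,
        gene_links={
            "gene": config.gene_link.format(gene=variant.gene or key.token()),
            "literature": config.literature_link.format(gene=variant.gene or key.token()),
        },
        locus_link=config.locus_link.format(chrom=key.chrom, pos=key.pos),
    )


# ---------------------------------------------------------------------------
# Recurrence queries against the case archive
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Occurrence:
    """One prior sighting of a variant in an archived case."""

    case_id: str
    final_gene_call: str
    final_variant_call: str
    final_action: str


@dataclasses.dataclass
class RecurrenceReport:
    """All archived sightings of a variant, flagged when history disagrees."""

    key: VariantKey
    occurrences: list[Occurrence]
    consistent: bool

    def __len__(self) -> int:
        return len(self.occurrences)


def query_recurrent(key: VariantKey, archive) -> RecurrenceReport:
    """Find every archived case containing ``key`` with its final resolved call.

    ``archive`` is a :class:`exomereview.workflow.CaseArchive` (anything with
    an ``entries()`` iterable of archived cases works).  History is flagged
    inconsistent when the final variant-level calls disagree across cases.
    """
    occurrences = []
    for entry in archive.entries():
        final = entry.final_calls.get(key.token())
        if final is not None:
            occurrences.append(
                Occurrence(
                    case_id=entry.case_id,
                    final_gene_call=final["gene_call"],
                    final_variant_call=final["variant_call"],
                    final_action=final["action"],
                )
            )
    calls = {o.final_variant_call for o in occurrences}
    return RecurrenceReport(key=key, occurrences=occurrences, consistent=len(calls) <= 1)
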