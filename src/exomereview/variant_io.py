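"""Reading and writing filtered-variant tables and reviewer call files.

A clinical exome case arrives as one tab-separated variant list per upstream
inheritance-model analysis (de novo, recessive, compound heterozygous,
dominant/X-linked, disease-mutation-database hits, secondary findings).
Every list shares the same 13 columns: chromosome, coordinate, reference and
sample alleles, gene symbol, transcript, nucleotide and amino-acid
alterations, SIFT and PolyPhen-2 predictions, phyloP conservation p-value,
dbSNP identifier and 1000 Genomes allele frequency.  The analysis type is a
property of the list, not a column.

Conventions:

* UTF-8 TSV with a mandatory header row; columns are matched by name,
  case-insensitively and tolerant of punctuation/spacing, never by position.
* Coordinates are 1-based and fully closed (VCF/HGVS convention).
* Allele frequencies are held internally as fractions in [0, 1]; values
  written as percentages in source files ("0.01%") are normalised at parse
  time.
* Empty cells mean *missing*, never zero.
"""

from __future__ import annotations

import csv
import dataclasses
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import FormatError, RowError
from .vocab import AnalysisType, GeneLevelCall, VariantLevelCall, parse_gene_call, parse_variant_call

_VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y", "MT"}

_ZYGOSITIES = {"het", "hom", "hemi"}


@dataclasses.dataclass(frozen=True, order=True)
class VariantKey:
    """Site + allele identity used to join annotations and query recurrence."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def token(self) -> str:
        """Compact ``chrom-pos-ref-alt`` string used in URLs and file stores."""
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @classmethod
    def from_token(cls, token: str) -> "VariantKey":
        chrom, pos, ref, alt = token.split("-", 3)
        return cls(chrom=chrom, pos=int(pos), ref=ref, alt=alt)


@dataclasses.dataclass
class VariantRecord:
    """One filtered variant from an analysis list, plus its list's analysis type."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    hgvs_c: str
    hgvs_p: str = ""
    sift: str = ""
    polyphen: str = ""
    phylop_p: Optional[float] = None
    dbsnp_id: str = ""
    kg_af: Optional[float] = None
    analysis_type: AnalysisType = AnalysisType.DE_NOVO
    zygosity: str = ""

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.chrom not in _VALID_CHROMS:
            raise ValueError(f"invalid chromosome label: {self.chrom!r}")
        if self.pos < 1:
            raise ValueError(f"coordinate must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("reference and sample alleles are identical")
        for name in ("phylop_p", "kg_af"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {value}")
        if not isinstance(self.analysis_type, AnalysisType):
            self.analysis_type = AnalysisType(self.analysis_type)
        if self.zygosity and self.zygosity not in _ZYGOSITIES:
            raise ValueError(f"invalid zygosity: {self.zygosity!r}")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix and canonicalise case (``chrx`` -> ``X``)."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in ("X", "Y", "MT", "M"):
        return "MT" if c.upper() == "M" else c.upper()
    return c


# Canonical column headers, in the order the input format defines them.
COLUMNS = (
    "Chromosome",
    "Coordinate",
    "Reference allele",
    "Sample allele",
    "Gene symbol",
    "Transcript ID",
    "Nucleotide alteration",
    "Amino acid alteration",
    "SIFT",
    "PolyPhen-2",
    "PhyloP p-value",
    "dbSNP ID",
    "1000 Genomes frequency",
)
OPTIONAL_COLUMNS = ("Zygosity",)

# Header-name aliases, keyed by squashed form (lowercase alphanumerics only).
_ALIASES = {
    "Chromosome": ["chromosome", "chromosomenumber", "chrom", "chr"],
    "Coordinate": ["coordinate", "chromosomecoordinate", "position", "pos", "start"],
    "Reference allele": ["referenceallele", "ref", "refallele"],
    "Sample allele": ["sampleallele", "alt", "altallele", "alternateallele"],
    "Gene symbol": ["genesymbol", "gene"],
    "Transcript ID": ["transcriptid", "transcript"],
    "Nucleotide alteration": ["nucleotidealteration", "cdnachange", "hgvsc"],
    "Amino acid alteration": ["aminoacidalteration", "proteinchange", "hgvsp"],
    "SIFT": ["sift", "siftfunctionalprediction", "siftprediction"],
    "PolyPhen-2": ["polyphen2", "polyphen", "polyphen2functionalprediction"],
    "PhyloP p-value": ["phyloppvalue", "phylop", "conservationphyloppvalue"],
    "dbSNP ID": ["dbsnpid", "dbsnp", "rsid"],
    "1000 Genomes frequency": [
        "1000genomesfrequency",
        "1000genomeallelefrequency",
        "1000genomesallelefrequency",
        "kgaf",
        "1000gaf",
    ],
    "Zygosity": ["zygosity", "genotype"],
}


def _squash(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


_SQUASHED = {alias: canon for canon, aliases in _ALIASES.items() for alias in aliases}


def _resolve_header(header: Sequence[str], path: str) -> dict[str, int]:
    """Map canonical column names to indices in this file's header."""
    index: dict[str, int] = {}
    for i, raw in enumerate(header):
        canon = _SQUASHED.get(_squash(raw))
        if canon is not None and canon not in index:
            index[canon] = i
    missing = [c for c in COLUMNS if c not in index]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return index


def parse_fraction(text: str) -> float:
    """Parse an allele frequency, normalising percent notation to a fraction."""
    t = text.strip()
    if t.endswith("%"):
        return float(t[:-1]) / 100.0
    return float(t)


def _parse_row(
    row: Sequence[str], index: dict[str, int], analysis_type: AnalysisType, line: int
) -> VariantRecord:
    def cell(col: str) -> str:
        i = index.get(col)
        if i is None or i >= len(row):
            return ""
        return row[i].strip()

    pos_text = cell("Coordinate")
    try:
        pos = int(pos_text)
    except ValueError:
        raise RowError(f"non-integer coordinate: {pos_text!r}", line) from None

    def frac(col: str) -> Optional[float]:
        text = cell(col)
        if not text:
            return None
        try:
            value = parse_fraction(text)
        except ValueError:
            raise RowError(f"invalid number in {col!r}: {text!r}", line) from None
        if not 0.0 <= value <= 1.0:
            raise RowError(f"{col!r} outside [0, 1]: {value}", line)
        return value

    try:
        return VariantRecord(
            chrom=cell("Chromosome"),
            pos=pos,
            ref=cell("Reference allele"),
            alt=cell("Sample allele"),
            gene=cell("Gene symbol"),
            transcript=cell("Transcript ID"),
            hgvs_c=cell("Nucleotide alteration"),
            hgvs_p=cell("Amino acid alteration"),
            sift=cell("SIFT"),
            polyphen=cell("PolyPhen-2"),
            phylop_p=frac("PhyloP p-value"),
            dbsnp_id=cell("dbSNP ID"),
            kg_af=frac("1000 Genomes frequency"),
            analysis_type=analysis_type,
            zygosity=cell("Zygosity").lower(),
        )
    except ValueError as exc:
        raise RowError(str(exc), line) from None


def parse_variant_table(
    path: str | Path, analysis_type: AnalysisType | str
) -> list[VariantRecord]:
    """Read one analysis list; every record is tagged with ``analysis_type``.

    Raises :class:`FormatError` when a required column is absent and
    :class:`RowError` (carrying the line number) for invalid cells.
    """
    analysis_type = AnalysisType(analysis_type)
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, header row required") from None
        index = _resolve_header(header, str(path))
        records = []
        for line, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            records.append(_parse_row(row, index, analysis_type, line))
    return records


def _format_fraction(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(value)


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as a TSV that :func:`parse_variant_table` round-trips."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty variant table")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(COLUMNS + OPTIONAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.chrom,
                    r.pos,
                    r.ref,
                    r.alt,
                    r.gene,
                    r.transcript,
                    r.hgvs_c,
                    r.hgvs_p,
                    r.sift,
                    r.polyphen,
                    _format_fraction(r.phylop_p),
                    r.dbsnp_id,
                    _format_fraction(r.kg_af),
                    r.zygosity,
                ]
            )


# ---------------------------------------------------------------------------
# Reviewer call files
# ---------------------------------------------------------------------------

CALL_COLUMNS = (
    "Chromosome",
    "Coordinate",
    "Reference allele",
    "Sample allele",
    "Gene call",
    "Variant call",
    "Comment",
    "Reviewer",
)


@dataclasses.dataclass
class CallRow:
    """One line of a reviewer call file, before workflow validation."""

    key: VariantKey
    gene_call: GeneLevelCall
    variant_call: VariantLevelCall
    comment: str
    reviewer: str


def parse_call_file(path: str | Path) -> list[CallRow]:
    """Read a reviewer call file (TSV: variant key + calls + comment + reviewer)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, header row required") from None
        squashed = [_squash(h) for h in header]
        index = {}
        for canon in CALL_COLUMNS:
            target = _squash(canon)
            aliases = {target}
            if canon in _ALIASES:
                aliases |= set(_ALIASES[canon])
            aliases |= {
                "genecall" if canon == "Gene call" else target,
                "variantcall" if canon == "Variant call" else target,
                "reviewerid" if canon == "Reviewer" else target,
            }
            for i, h in enumerate(squashed):
                if h in aliases:
                    index[canon] = i
                    break
        missing = [c for c in CALL_COLUMNS if c not in index and c != "Comment"]
        if missing:
            raise FormatError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        rows = []
        for line, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue

            def cell(col: str) -> str:
                i = index.get(col)
                return row[i].strip() if i is not None and i < len(row) else ""

            try:
                key = VariantKey(
                    chrom=normalize_chrom(cell("Chromosome")),
                    pos=int(cell("Coordinate")),
                    ref=cell("Reference allele"),
                    alt=cell("Sample allele"),
                )
                rows.append(
                    CallRow(
                        key=key,
                        gene_call=parse_gene_call(cell("Gene call")),
                        variant_call=parse_variant_call(cell("Variant call")),
                        comment=cell("Comment"),
                        reviewer=cell("Reviewer"),
                    )
                )
            except ValueError as exc:
                raise RowError(str(exc), line) from None
    return rows


def write_call_file(rows: Iterable[CallRow], path: str | Path) -> None:
    """Write reviewer calls as a TSV readable by :func:`parse_call_file`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(CALL_COLUMNS)
        for r in rows:
            writer.writerow(
                [
                    r.key.chrom,
                    r.key.pos,
                    r.key.ref,
                    r.key.alt,
                    r.gene_call.value,
                    r.variant_call.value,
                    r.comment,
                    r.reviewer,
                ]
            )


def record_to_dict(record: VariantRecord) -> dict:
    """JSON-ready form of a record (used by the workflow store)."""
    d = dataclasses.asdict(record)
    d["analysis_type"] = record.analysis_type.value
    return d


def record_from_dict(d: dict) -> VariantRecord:
    return VariantRecord(**d)
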