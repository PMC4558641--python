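"""Project configuration: review policy knobs and external-link templates.

Everything a laboratory may legitimately tune lives here — minimum reviewer
count, the journal flush interval for batch clients, the hemizygous-male
minimum behind the X-linked benign rule, secondary-findings consent, and the
URL templates used to hyperlink annotations back to their source databases.
The decision matrix itself is deliberately *not* configurable: reporting
logic is frozen per release.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError

#: Default URL templates per annotation source.  Placeholders: {token} is the
#: chrom-pos-ref-alt key token, {rsid} the dbSNP id, {gene} the gene symbol,
#: {assertion} the source's accession, {chrom}/{pos} the coordinate.
DEFAULT_LINK_TEMPLATES: dict[str, str] = {
    "dbSNP": "https://www.ncbi.nlm.nih.gov/snp/{rsid}",
    "1000 Genome": "https://www.internationalgenome.org/variant/{token}",
    "ESP6500": "https://evs.gs.washington.edu/EVS/?variant={token}",
    "UK10K control": "https://www.uk10k.org/variant/{token}",
    "Scripps Wellderly": "https://genomics.scripps.edu/wellderly/variant/{token}",
    "ExAC": "https://gnomad.broadinstitute.org/variant/{token}",
    "dbNSFP": "https://sites.google.com/site/jpopgen/dbNSFP?variant={token}",
    "HGMD": "https://www.hgmd.cf.ac.uk/ac/mut.php?acc={assertion}",
    "ClinVar": "https://www.ncbi.nlm.nih.gov/clinvar/?term={assertion}",
    "OMIM": "https://omim.org/search?search={gene}",
    "UK10K disease": "https://www.uk10k.org/variant/{token}",
    "GERA": "https://www.ncbi.nlm.nih.gov/projects/gap/cgi-bin/study.cgi?id={token}",
    "Mount Sinai Biobank": "biobank://variant/{token}",
    "VarDi": "vardi://variant/{token}",
}

DEFAULT_GENE_LINK = "https://www.ncbi.nlm.nih.gov/gene/?term={gene}%5Bsym%5D"
DEFAULT_LITERATURE_LINK = "https://pubmed.ncbi.nlm.nih.gov/?term={gene}"
DEFAULT_LOCUS_LINK = (
    "https://genome.ucsc.edu/cgi-bin/hgTracks?position=chr{chrom}%3A{pos}"
)


@dataclasses.dataclass
class ProjectConfig:
    """Per-case policy configuration (YAML-serialisable)."""

    #: Minimum number of independent reviewers per variant.
    min_reviewers: int = 2
    #: Flush interval, in seconds, for batch clients buffering journal writes.
    #: The engine itself journals every call immediately; the interval only
    #: bounds how long a buffering client may hold entries.
    autosave_flush_seconds: int = 30
    #: "At least several hemizygous males" for the X-linked benign rule.
    hemi_male_min: int = 3
    #: Whether the patient consented to receive secondary findings.
    secondary_findings_consent: bool = True
    #: Allele-frequency thresholds (fractions; strict > comparisons).
    af_threshold_recessive: float = 0.01
    af_threshold_dominant: float = 0.001
    #: Repeat-region in-frame indel rule bounds.
    repeat_min_units: int = 8
    repeat_max_indel_aa: int = 2
    #: Repeat unit length in amino acids (1 = homopolymer runs).
    repeat_unit_length: int = 1
    #: URL templates, overridable per source.
    link_templates: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LINK_TEMPLATES)
    )
    gene_link: str = DEFAULT_GENE_LINK
    literature_link: str = DEFAULT_LITERATURE_LINK
    locus_link: str = DEFAULT_LOCUS_LINK

    def __post_init__(self) -> None:
        if self.min_reviewers < 2:
            raise ConfigurationError(
                f"min_reviewers must be at least 2, got {self.min_reviewers}"
            )
        if self.autosave_flush_seconds <= 0:
            raise ConfigurationError("autosave_flush_seconds must be positive")
        if self.hemi_male_min < 1:
            raise ConfigurationError("hemi_male_min must be at least 1")
        for name in ("af_threshold_recessive", "af_threshold_dominant"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {value}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Optional[dict]) -> "ProjectConfig":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}"
            )
        if "link_templates" in data and data["link_templates"] is not None:
            merged = dict(DEFAULT_LINK_TEMPLATES)
            merged.update(data["link_templates"])
            data["link_templates"] = merged
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProjectConfig":
        with Path(path).open(encoding="utf-8") as handle:
            data = yaml.safe_load(handle)
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)
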