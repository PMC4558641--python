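# Methods

## Scope and model of the process

`exomereview` models post-filtering clinical exome interpretation as a
deterministic rule-and-workflow engine.  It deliberately begins *after*
alignment, variant calling and inheritance-model filtering: its inputs are
the per-analysis variant lists such tools emit (13 columns: chromosome,
coordinate, reference/sample alleles, gene, transcript, nucleotide and
amino-acid alteration, SIFT, PolyPhen-2, phyloP p-value, dbSNP id, 1000
Genomes frequency), and its outputs are resolved interpretations, a Sanger
validation queue and clinical report tables.  Upstream pipelines, genome
browsers/IGV rendering, live database queries and copy-number analysis are
out of scope; external resources appear only as hyperlinks and as rows in a
local annotation store.

## Interpretation vocabulary and the decision matrix

Interpretation is a pair of calls: gene-level phenotype applicability (six
labels) and a variant-level interpretive category (nine labels).  The
reporting action is a total function of the pair, shipped as a 9 × 6 data
table (`data/decision_matrix.tsv`) and checked at import time for:
totality (54 cells), uniform *do-not-report* across the benign row,
error actions in every (likely) pathogenic cell under no/little-evidence
gene calls, errors never reportable, and every Sanger-requiring action
being either reportable or the explicit investigate action.  Shipping the
matrix as data rather than branching code makes it auditable cell-by-cell;
configuration cannot override cells because reporting logic is frozen per
release.  One asymmetry in the source logic — the compound-het-error row
reads *Need discussion* under reportable-secondary but *Error – not
compound het* under de novo-no/little-evidence — is encoded literally, not
smoothed.

## Classification rules

**Benign by frequency.** An allele is benign-by-frequency when its maximum
frequency across the registered population sources (1000 Genomes, ESP6500,
ExAC, UK10K control, Wellderly) plus the input table's own frequency column
strictly exceeds 1 % under a recessive or X-linked model, or 0.1 % under a
dominant or de novo model.  The comparisons are strict (`>`), on fractions
0.01 and 0.001; a frequency exactly at the threshold does not qualify, and
a missing frequency never does.  The X-linked branch additionally requires
at least `hemi_male_min` hemizygous males reported in the databases; the
source logic says "several" without a number, so the default is 3 — the
smallest count that is plausibly more than a couple — and it is
configurable.  Taking the *maximum* over sources is the one design choice
here that was genuinely open: it calls benign whenever any large population
supports it, which is the conservative direction for this rule (benign
variants are dropped from reports, so false negatives of the rule only cost
review time, while applying the rule to the minimum could suppress a real
finding seen at low frequency in one cohort).  Disease-database (HGMD) and
secondary-finding lists carry no inheritance model; they default to the
stricter recessive threshold unless the caller supplies a pattern.

**Repeat-region indels.** An in-frame insertion/deletion of 1–2 amino
acids is likely benign when it falls inside a tandem run of at least 8
identical repeat units.  The rule is a pure function of the protein-level
nomenclature, the indel length and a caller-supplied peptide context
centred on the indel; the engine does not fetch proteome sequence (in the
manual process this check is a browser inspection).  The repeat unit is a
single amino acid by default; unit length is configurable.  Frameshifts
are rejected with an explicit rule-not-applicable error and routed to the
loss-of-function logic.

**Intronic changes.** Coding-DNA nomenclature is scanned for intronic
offset syntax (`…+N`, `…−N` anchored to an exonic position).  Offsets of
magnitude 1 or 2 are canonical splice positions; deeper offsets are
intronic-likely-benign candidates unless HGMD or ClinVar asserts
pathogenic/likely pathogenic, which overrides the candidate status.  Either
database alone suffices for the override (the source logic does not say
both).  UTR positions (`c.-12…`) carry no exon-anchored offset and are not
intronic.  Strings that do not look like `c.` nomenclature raise a parse
error carrying the raw text, because upstream nomenclature is occasionally
wrong and must surface, not silently pass.

**Loss of function.** Nonsense (protein change ending in `Ter`/`*`/`X`),
frameshift (`fs`), and canonical-splice changes are treated as putative
loss of function.  Handling is pattern-based, not a full HGVS grammar: the
rules consume nomenclature *patterns*, and a full parser would add failure
modes without adding discrimination.

**Compound-het sanity check.** Within a compound-het list, a gene whose
variants include exactly one call outside the benign classes (benign,
likely benign, intronic-likely benign) cannot be compound heterozygous and
is flagged.  Zero non-benign calls is not an error (the gene simply drops
out).

**Suggestion precedence.** pathogenic assertion > benign by frequency >
repeat indel > deep intronic > loss of function > VUS.  Pathogenic
assertions outrank frequency so that a curated disease mutation is never
silently dropped by a frequency artefact; the group meeting, not the
engine, is the place to overrule curation.  Mapping error and compound-het
error are reviewer-assignable only.  Suggestions carry the triggering
rationale and never auto-commit.

## Review workflow

Every variant is assigned to at least two reviewers (policy default 2,
enforced at distribution); allocation is round-robin over a seeded shuffle,
so per-reviewer loads differ by at most one and a fixed seed reproduces the
allocation.  Reviewer calls are journaled append-only *before* the current-
call table is updated; resubmission overwrites the current call but the
journal keeps every version, and replaying the journal reconstructs the
current table exactly.  The 30-second autosave of interactive clients is
realised as this immediate journal plus a configurable flush interval
(`autosave_flush_seconds`, default 30) that only bounds buffering batch
clients — the contract is "no reviewer work lost", not a timer.

Merging flags a variant discordant when any two reviewers differ on
*either* call: a gene-level disagreement changes the decision-matrix action
just as a variant-level one does.  With more than two reviewers, any
inequality routes to group resolution; there is no majority auto-rule,
because a 2-vs-1 split is still a disagreement a clinical lab should
discuss.  Concordant variants auto-resolve unless their action is a
discussion action or a category error.  Group resolutions are recorded with
minutes, re-validated against the label-usage restrictions, re-entered
through the decision matrix, and rejected if they land on an error cell.
Deadlines mark late assignments without voiding them; an incomplete variant
is merged (flagged) only once its deadline has passed.

The Sanger queue is the set of resolved variants whose action requires
validation; a failed confirmation reopens group discussion rather than
silently dropping the variant.  Report generation is blocked while any
variant is unresolved, reopened, or pending validation (an explicit,
audited waiver exists).  Routing into report tables is by final call class
— secondary-finding actions to the secondary table, pathogenic/likely
pathogenic to primary, every other reportable resolution (including
*Report as VUS*) to supplementary — and is a configurable map, since the
primary/supplementary boundary is lab policy rather than logic.  Director
sign-off freezes the tables, audits any dropped entries (their resolutions
persist for the archive), and refuses stale drafts.  Archived cases are
idempotent, immutable, and indexed for recurrence queries, which flag
variants whose interpretation history disagrees across cases.

## Synthetic data generator

The generator emulates the post-filter inputs of one case: per-analysis
variant tables, a matching annotation store, and reviewer call files with a
controlled number of discordant reviews.  Defaults describe a
representative trio case — 7 compound-heterozygous, 22 recessive, 4 de
novo and 15 secondary variants, reviewed by 2 reviewers with 3 discordant
calls — and the intended-category mix is 5 % pathogenic-with-assertions,
25 % high-frequency benign, 15 % deep intronic, 5 % repeat-region indel,
10 % loss-of-function in no-evidence genes, remainder plain VUS, roughly
the triage composition a mostly-negative clinical exome presents.  Each
variant carries a hidden truth label consistent with its generated
frequency, nomenclature and store records, and each is built to trigger
exactly one rule, so the suggestion engine is expected to recover truth
exactly on this corpus.  Two constructions keep the truth well-defined:
compound-het lists contain no benign-class variants and at least two
variants per gene (otherwise the generator would manufacture compound-het
filter artefacts), and X-linked benign variants carry a reported
hemizygous-male count at or above `hemi_male_min` — a spec that forces it
lower is rejected as self-contradictory.

What the generator does *not* emulate: real linkage structure, transcript
models (nomenclature is synthesised from per-category templates),
ambiguous variants that trigger several rules at once, mapping artefacts,
or annotation conflicts between databases.  Passing tests therefore
demonstrate that the rules, workflow and bookkeeping are implemented as
specified — not that the rules themselves have any particular sensitivity
or specificity on real patient data, where most interpretive difficulty
lives in exactly the ambiguous cases the generator excludes.  Real-data
behaviour is instead pinned by a small hand-written regression fixture of
published case variants (a homozygous porphyria-causing missense with
database assertions; five trio missense changes of uncertain significance).

## Numerical and representational choices

Allele frequencies are held as fractions in [0, 1]; percent strings in
input files are normalised at parse time, so thresholds are applied in one
unit.  Coordinates are 1-based, fully closed.  Empty cells are missing
values, never zero — a missing frequency must not look like a novel
variant with frequency 0 when the benign rule runs (both evaluate
not-benign here, but they are displayed and serialised differently).
Variant identity is (chromosome, position, reference, sample allele);
`chr` prefixes are stripped on input.  Table columns are matched by name,
case- and punctuation-insensitively, never by position.  Round-trip
fidelity (parse ∘ write = identity) is property-tested.  External-link
URLs are deterministic templates over (source, key) and always embed an
identifying token, falling back to the `chrom-pos-ref-alt` token when a
source-specific accession is absent.

## Problem sizes

The test suite and the acceptance script run entirely on generated or
hand-written fixtures: the 48-variant default case for end-to-end checks, a
1,000-variant corpus (spread across six analysis types) for
suggestion-truth recovery and the precedence oracle, exhaustive enumeration
for the 54-cell matrix and the repeat/compound-het rule bounds, and
60-step bisection for the frequency thresholds.  These sizes make every
check exact rather than statistical; nothing in the engine is
scale-sensitive, since all operations are per-variant or per-case.

## Known limitations

* HGVS handling is pattern-based; legal but exotic descriptions (complex
  delins, mosaic/uncertain syntax) raise rather than classify.
* The annotation store is a frozen local table; production deployments
  would point the same interface at live or versioned database mirrors,
  and stored facts can go stale.
* Gene-level calls are entirely human judgements here; the engine only
  validates their usage restrictions, it does not suggest them.
* Reviewer identity is an opaque id; authentication, roles and
  concurrent-editing conflicts are out of scope.
* No probabilistic combination of evidence (e.g. full ACMG criteria
  scoring); the engine automates exactly the mechanical rules and leaves
  the rest to reviewers by design.
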