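# exomereview

Variant triage, interpretation and multi-reviewer workflow for clinical
whole-exome sequencing (WES) laboratories.

## The problem

After a clinical exome is sequenced, aligned and filtered by inheritance
model, a lab is left with a handful of candidate variants per analysis —
de novo, autosomal recessive, compound heterozygous, dominant/X-linked,
known disease-mutation hits, and secondary (incidental) findings.  Turning
those lists into a signed clinical report is a process problem as much as a
science problem: each variant must be annotated against a battery of
population and disease databases, interpreted independently by at least two
reviewers, discordant interpretations resolved in a group meeting,
candidate findings confirmed by Sanger sequencing, and the survivors routed
into the right section of the report — with an audit trail for every step.

`exomereview` implements that pipeline as a library plus a thin CLI, for
laboratory directors, clinical molecular geneticists and the engineers who
support them.

## The core logic

Interpretation is split into two calls per variant:

* a **gene-level call** — is the phenotype of this patient applicable to
  the disease associated with this gene?  Six options: *Yes*,
  *Uncertain/possibly*, *No (clearly unrelated)*, *No/little phenotypic
  evidence available*, *de novo – no/little evidence* (de novo list only),
  and *Reportable secondary finding* (consent-gated);
* a **variant-level call** — the interpretive category: *Benign*, *Likely
  benign*, *Intronic-likely benign*, *VUS*, *Deleterious VUS* (reserved for
  putative loss-of-function changes in no-evidence genes), *Likely
  pathogenic*, *Pathogenic*, *Mapping error*, *CompoundHet error*.

A frozen 9 × 6 **decision matrix** maps every (variant-level, gene-level)
pair to one of eleven actions: report (with or without Sanger validation),
report as VUS or as a secondary finding, do not report, send to group
discussion, investigate via Sanger, or bounce the call back as a category
error.  The matrix ships as a data table and is validated for totality (54
cells) at import.

The mechanical part of the variant-level call is automated as a suggestion
engine with a fixed precedence:

1. established pathogenic assertion (HGMD/ClinVar) → *Pathogenic*;
2. allele frequency > 1 % for recessive or X-linked patterns (X-linked
   additionally requires ≥ `hemi_male_min` reported hemizygous males), or
   > 0.1 % for dominant or de novo patterns → *Benign*;
3. in-frame indel of 1–2 aa inside a repeat run of ≥ 8 units → *Likely
   benign*;
4. intronic change outside the canonical splice positions (−1, −2, +1, +2),
   absent a pathogenic assertion → *Intronic-likely benign*;
5. putative loss of function (nonsense, frameshift, canonical splice) →
   *Likely pathogenic*, or *Deleterious VUS* in a no-evidence gene;
6. otherwise → *VUS*.

Suggestions never auto-commit; reviewers see the triggering rationale and
decide.  *Mapping error* is never suggested (it requires visual read
inspection), and a compound-het gene left with exactly one non-benign
variant is flagged as a filter artefact.

## Worked example

```python
from exomereview import *
from exomereview.annotation import AnnotationRecord, AnnotationStore, annotate
from exomereview.rules import InheritanceContext, suggest_call

v = VariantRecord(chrom="10", pos=127477177, ref="A", alt="G", gene="UROS",
                  transcript="NM_000375", hgvs_c="c.217T>C", hgvs_p="p.C73R",
                  dbsnp_id="rs121908012", kg_af=0.0001,
                  analysis_type="recessive", zygosity="hom")
store = AnnotationStore([
    AnnotationRecord(source="HGMD", key=v.key, assertion="CM900225"),
    AnnotationRecord(source="ClinVar", key=v.key, assertion="RCV000003948.2"),
])
s = suggest_call(v, annotate(v, store),
                 InheritanceContext.from_analysis_type(v.analysis_type))
print("suggestion:", s.call.label)
print("rationale: ", s.rationale[0])
a = decide(s.call, GeneLevelCall.PHENOTYPE_YES)
print("action:    ", a.label, "| reportable:", a.reportable(),
      "| Sanger:", a.sanger_required())
```

prints

```
suggestion: Pathogenic
rationale:  established disease-causing change: pathogenic assertion(s) CM900225, RCV000003948.2
action:     Report & Sanger | reportable: True | Sanger: True
```

— a well-established disease mutation in a phenotype-matching gene is
reported after Sanger confirmation.  A whole synthetic case (a
representative trio composition: 7 compound-het, 22 recessive, 4 de novo
and 15 secondary variants, with 3 deliberately discordant reviews) runs
end-to-end in a few lines:

```python
from exomereview.fixtures import FixtureSpec, generate_case, simulate_reviews, execute_case

case = generate_case(FixtureSpec(seed=1))
project, report = execute_case(case, simulate_reviews(case))
print("variants:", len(project.variants),
      "| discordant:", sum(r.discordant for r in project.merged.values()),
      "| Sanger queue:", len(project.sanger_queue))
print("report counts:", report.counts)
```

```
variants: 48 | discordant: 3 | Sanger queue: 22
report counts: {'primary_findings': 1, 'supplementary_findings': 24, 'secondary_findings': 0}
```

The three discordant variants were routed through group resolution, every
Sanger-requiring action was confirmed, and the report tables split the
reportable set into primary (pathogenic/likely pathogenic), supplementary
(uncertain and likely-benign classes) and secondary findings.

The same workflow is scriptable from a shell via the `exomereview` CLI
(`init`, `upload`, `assign`, `call`, `merge`, `resolve`, `sanger`,
`report`, `archive`, `history`, `recurrent`, `fixtures generate`).

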