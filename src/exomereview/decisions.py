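"""The reporting/validation decision matrix.

Once a reviewer has made a gene-level call (phenotype applicability) and a
variant-level call (interpretive category), the lab's action — report it,
confirm it by Sanger first, discuss it, or send it back as a
mis-categorisation — is a pure function of the two calls.  The full 9 x 6
matrix is shipped as a data table, not branching code, so it can be audited
cell-by-cell and validated for totality at import time.  Configuration may
not override cells: reporting logic is frozen per release.

Notable structure of the matrix:

* Benign variants are never reported, whatever the gene call.
* (Likely) pathogenic variants in genes with no/little phenotype evidence
  are a contradiction — the reviewer is told to re-categorise as
  deleterious VUS, the label reserved for exactly that situation.
* Deleterious VUS under any phenotype-informative gene call is likewise a
  category error.
* Mapping-error and compound-het-error calls on phenotype-matching genes are
  not discarded but investigated further via Sanger.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Mapping

from .errors import MatrixValidationError
from .vocab import Action, GeneLevelCall, VariantLevelCall

#: Gene-call column order used in shipped tables and reports.
GENE_CALL_ORDER = (
    GeneLevelCall.PHENOTYPE_YES,
    GeneLevelCall.NO_CLEARLY_UNRELATED,
    GeneLevelCall.REPORTABLE_SECONDARY,
    GeneLevelCall.UNCERTAIN_POSSIBLY,
    GeneLevelCall.NO_LITTLE_EVIDENCE,
    GeneLevelCall.DE_NOVO_NO_LITTLE_EVIDENCE,
)

#: Variant-call row order used in shipped tables and reports.
VARIANT_CALL_ORDER = (
    VariantLevelCall.BENIGN,
    VariantLevelCall.LIKELY_BENIGN,
    VariantLevelCall.INTRONIC_LIKELY_BENIGN,
    VariantLevelCall.VUS,
    VariantLevelCall.DELETERIOUS_VUS,
    VariantLevelCall.LIKELY_PATHOGENIC,
    VariantLevelCall.PATHOGENIC,
    VariantLevelCall.MAPPING_ERROR,
    VariantLevelCall.COMPOUND_HET_ERROR,
)

Cell = tuple[VariantLevelCall, GeneLevelCall]


def _load_matrix() -> dict[Cell, Action]:
    text = (
        resources.files("exomereview").joinpath("data/decision_matrix.tsv").read_text()
    )
    reader = csv.reader(text.splitlines(), delimiter="\t")
    header = next(reader)
    gene_calls = [GeneLevelCall(h) for h in header[1:]]
    matrix: dict[Cell, Action] = {}
    for row in reader:
        if not row or not row[0].strip():
            continue
        variant_call = VariantLevelCall(row[0])
        for gene_call, cell in zip(gene_calls, row[1:]):
            matrix[(variant_call, gene_call)] = Action(cell)
    return matrix


MATRIX: Mapping[Cell, Action] = _load_matrix()


def decide(variant_call: VariantLevelCall, gene_call: GeneLevelCall) -> Action:
    """Look up the action for a (variant-level, gene-level) call pair."""
    return MATRIX[(VariantLevelCall(variant_call), GeneLevelCall(gene_call))]


def validate_matrix(matrix: Mapping[Cell, Action] = MATRIX) -> dict:
    """Audit the matrix for totality and structural consistency.

    Checks: all 54 cells present, none spurious; the benign row is uniformly
    do-not-report; every (likely) pathogenic cell under a no/little-evidence
    gene call is an error action; error actions are never reportable; every
    Sanger-requiring action is reportable or the investigate action.

    Returns a summary dict; raises :class:`MatrixValidationError` listing the
    offending cells otherwise.
    """
    problems: list[str] = []
    expected = {
        (v, g) for v in VariantLevelCall for g in GeneLevelCall
    }
    missing = expected - set(matrix)
    for v, g in sorted(missing, key=lambda c: (c[0].value, c[1].value)):
        problems.append(f"missing cell ({v.label!r}, {g.label!r})")
    spurious = set(matrix) - expected
    for v, g in sorted(spurious, key=lambda c: (str(c[0]), str(c[1]))):
        problems.append(f"unexpected cell ({v!r}, {g!r})")

    for g in GeneLevelCall:
        cell = matrix.get((VariantLevelCall.BENIGN, g))
        if cell is not None and cell is not Action.DO_NOT_REPORT:
            problems.append(
                f"benign row must be 'Do not report' everywhere; "
                f"({g.label!r}) is {cell.label!r}"
            )

    for v in (VariantLevelCall.LIKELY_PATHOGENIC, VariantLevelCall.PATHOGENIC):
        for g in GeneLevelCall:
            if not g.is_no_little_evidence:
                continue
            cell = matrix.get((v, g))
            if cell is not None and not cell.is_error():
                problems.append(
                    f"({v.label!r}, {g.label!r}) must be an error action, "
                    f"got {cell.label!r}"
                )

    for (v, g), action in matrix.items():
        if action.is_error() and action.reportable():
            problems.append(f"error action {action.label!r} is reportable")
        if (
            action.sanger_required()
            and not action.reportable()
            and action is not Action.INVESTIGATE_VIA_SANGER
        ):
            problems.append(
                f"({v.label!r}, {g.label!r}): Sanger-requiring action "
                f"{action.label!r} is neither reportable nor investigative"
            )

    if problems:
        raise MatrixValidationError(problems)
    return {
        "cells": len(matrix),
        "variant_calls": len(VariantLevelCall),
        "gene_calls": len(GeneLevelCall),
        "benign_row_uniform": True,
    }


# Fail fast if the shipped resource was edited into inconsistency.
validate_matrix()
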