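"""Case lifecycle: distribution, journaling, merge/discordance, resolution,
Sanger queue, archive."""

import datetime as dt
import itertools

import pytest

from exomereview.config import ProjectConfig
from exomereview.decisions import decide
from exomereview.errors import (
    AuthorizationError,
    CallValidationError,
    ConfigurationError,
    WorkflowError,
)
from exomereview.variant_io import VariantKey, VariantRecord
from exomereview.vocab import Action, AnalysisType, GeneLevelCall, VariantLevelCall
from exomereview.workflow import (
    CaseArchive,
    CaseProject,
    ReviewCall,
    archive_case,
    distribute,
    replay_journal,
)
from exomereview.annotation import query_recurrent
from exomereview.reporting import generate_report

G = GeneLevelCall
V = VariantLevelCall


def _records(n: int, analysis_type=AnalysisType.COMPOUND_HET) -> list[VariantRecord]:
    records = []
    for i in range(n):
        records.append(
            VariantRecord(
                chrom=str((i % 22) + 1),
                pos=1000 + 100 * i,
                ref="A",
                alt="G",
                # compound-het genes hold two variants each
                gene=f"GENE{i // 2:03d}" if analysis_type is AnalysisType.COMPOUND_HET
                else f"GENE{i:03d}",
                transcript=f"NM_{i:06d}",
                hgvs_c=f"c.{100 + i}A>G",
                hgvs_p=f"p.Lys{34 + i}Arg",
                analysis_type=analysis_type,
            )
        )
    return records


def _project(n=7, reviewers=("r1", "r2"), deadline=None, analysis_type=AnalysisType.COMPOUND_HET):
    project = CaseProject("CASE-T")
    project.upload(_records(n, analysis_type))
    deadline = deadline or dt.date.today() + dt.timedelta(days=7)
    project.distribute(list(reviewers), deadline, min_reviewers=len(reviewers), seed=0)
    return project


def _call(project, token, reviewer, gene_call, variant_call, comment=""):
    project.record_call(
        ReviewCall(
            variant=VariantKey.from_token(token),
            reviewer=reviewer,
            gene_call=gene_call,
            variant_call=variant_call,
            comment=comment,
        )
    )


class TestDistribute:
    def test_balanced_assignment(self, deadline):
        assignments = distribute(_records(10), ["a", "b", "c", "d"], 2, deadline, seed=1)
        assert len(assignments) == 20
        loads = {}
        for a in assignments:
            loads[a.reviewer] = loads.get(a.reviewer, 0) + 1
        assert set(loads.values()) == {5}
        per_variant = {}
        for a in assignments:
            per_variant.setdefault(a.variant.token(), set()).add(a.reviewer)
        assert all(len(r) == 2 for r in per_variant.values())

    def test_two_reviewers_get_everything(self, deadline):
        assignments = distribute(_records(7), ["a", "b"], 2, deadline)
        per_reviewer = {}
        for a in assignments:
            per_reviewer.setdefault(a.reviewer, []).append(a.variant)
        assert all(len(v) == 7 for v in per_reviewer.values())

    def test_fewer_reviewers_than_minimum_rejected(self, deadline):
        with pytest.raises(ConfigurationError):
            distribute(_records(3), ["only-one"], 2, deadline)

    def test_single_review_policy_rejected(self, deadline):
        with pytest.raises(ConfigurationError, match="at least 2"):
            distribute(_records(3), ["a", "b"], 1, deadline)

    def test_deterministic_under_fixed_seed(self, deadline):
        records = _records(9)
        a1 = distribute(records, ["a", "b", "c"], 2, deadline, seed=5)
        a2 = distribute(records, ["a", "b", "c"], 2, deadline, seed=5)
        assert a1 == a2

    def test_load_balance_property(self, deadline):
        # max-min per-reviewer load <= 1 across many shapes
        for n, m, k in [(7, 3, 2), (11, 5, 3), (13, 4, 2), (5, 5, 4)]:
            assignments = distribute(
                _records(n), [f"r{i}" for i in range(m)], k, deadline, seed=n
            )
            loads: dict[str, int] = {}
            for a in assignments:
                loads[a.reviewer] = loads.get(a.reviewer, 0) + 1
            assert max(loads.values()) - min(loads.values()) <= 1, (n, m, k)


class TestRecordCall:
    def test_valid_call_journals_and_submits(self):
        project = _project()
        token = next(iter(project.variants))
        before = len(project.journal)
        _call(project, token, "r1", G.UNCERTAIN_POSSIBLY, V.VUS)
        assert len(project.journal) == before + 1
        assert project.assignment_for(VariantKey.from_token(token), "r1").status == "submitted"

    def test_unassigned_reviewer_rejected(self):
        project = _project()
        token = next(iter(project.variants))
        with pytest.raises(AuthorizationError):
            _call(project, token, "intruder", G.UNCERTAIN_POSSIBLY, V.VUS)

    def test_footnote_labels_validated_at_record_time(self):
        project = _project(analysis_type=AnalysisType.RECESSIVE)
        token = next(iter(project.variants))
        with pytest.raises(CallValidationError):
            _call(project, token, "r1", G.DE_NOVO_NO_LITTLE_EVIDENCE, V.VUS)
        with pytest.raises(CallValidationError):
            _call(project, token, "r1", G.PHENOTYPE_YES, V.COMPOUND_HET_ERROR)

    def test_resubmission_keeps_journal_history(self):
        project = _project()
        token = next(iter(project.variants))
        _call(project, token, "r1", G.UNCERTAIN_POSSIBLY, V.VUS)
        _call(project, token, "r1", G.UNCERTAIN_POSSIBLY, V.LIKELY_PATHOGENIC)
        entries = [e for e in project.journal if e["payload"]["variant"] == token]
        assert len(entries) == 2
        assert project.current_calls[(token, "r1")].variant_call is V.LIKELY_PATHOGENIC

    def test_journal_replay_reconstructs_current_calls(self):
        project = _project()
        tokens = sorted(project.variants)
        _call(project, tokens[0], "r1", G.UNCERTAIN_POSSIBLY, V.VUS)
        _call(project, tokens[0], "r1", G.PHENOTYPE_YES, V.VUS)  # resubmission
        _call(project, tokens[0], "r2", G.UNCERTAIN_POSSIBLY, V.MAPPING_ERROR)
        _call(project, tokens[1], "r1", G.UNCERTAIN_POSSIBLY, V.VUS)
        table = replay_journal(project.journal)
        assert set(table) == set(project.current_calls)
        for (token, reviewer), payload in table.items():
            current = project.current_calls[(token, reviewer)]
            assert payload["gene_call"] == current.gene_call.value
            assert payload["variant_call"] == current.variant_call.value

    def test_save_load_round_trip_preserves_state(self, tmp_path):
        project = _project()
        token = next(iter(project.variants))
        _call(project, token, "r1", G.UNCERTAIN_POSSIBLY, V.VUS)
        path = tmp_path / "project.json"
        project.save(path)
        back = CaseProject.load(path)
        assert back.to_dict() == project.to_dict()


def _review_all(project, pairs):
    """pairs: token -> ((g1, v1), (g2, v2))."""
    for token, ((g1, v1), (g2, v2)) in pairs.items():
        _call(project, token, "r1", g1, v1)
        _call(project, token, "r2", g2, v2)


class TestMergeAndFlag:
    def test_case_with_three_discordant_of_seven(self):
        # seven compound-het variants; two VUS-vs-mapping-error pairs and one
        # likely-pathogenic-vs-VUS pair are discordant
        project = _project(7)
        tokens = sorted(project.variants)
        pairs = {}
        discordant_pairs = [
            ((G.UNCERTAIN_POSSIBLY, V.VUS), (G.UNCERTAIN_POSSIBLY, V.MAPPING_ERROR)),
            ((G.UNCERTAIN_POSSIBLY, V.VUS), (G.UNCERTAIN_POSSIBLY, V.MAPPING_ERROR)),
            ((G.UNCERTAIN_POSSIBLY, V.LIKELY_PATHOGENIC), (G.UNCERTAIN_POSSIBLY, V.VUS)),
        ]
        for token, pair in zip(tokens[:3], discordant_pairs):
            pairs[token] = pair
        for token in tokens[3:]:
            pairs[token] = (
                (G.UNCERTAIN_POSSIBLY, V.VUS), (G.UNCERTAIN_POSSIBLY, V.VUS)
            )
        _review_all(project, pairs)
        rows = project.merge_and_flag()
        flagged = [r for r in rows if r.discordant]
        assert len(flagged) == 3
        assert {r.variant.token() for r in flagged} == set(tokens[:3])

    def test_identical_calls_auto_resolve(self):
        project = _project(2)
        tokens = sorted(project.variants)
        _review_all(
            project,
            {t: ((G.UNCERTAIN_POSSIBLY, V.VUS), (G.UNCERTAIN_POSSIBLY, V.VUS))
             for t in tokens},
        )
        rows = project.merge_and_flag()
        assert all(r.status == "auto_resolved" for r in rows)
        for token in tokens:
            resolution = project.resolutions[token]
            assert resolution.resolved_by == "concordant_auto"
            assert resolution.final_action is decide(V.VUS, G.UNCERTAIN_POSSIBLY)

    def test_gene_call_difference_alone_flags(self):
        project = _project(2)
        tokens = sorted(project.variants)
        _review_all(
            project,
            {
                tokens[0]: ((G.PHENOTYPE_YES, V.VUS), (G.UNCERTAIN_POSSIBLY, V.VUS)),
                tokens[1]: ((G.UNCERTAIN_POSSIBLY, V.VUS), (G.UNCERTAIN_POSSIBLY, V.VUS)),
            },
        )
        rows = {r.variant.token(): r for r in project.merge_and_flag()}
        assert rows[tokens[0]].discordant and not rows[tokens[1]].discordant

    def test_pairwise_combinations_match_any_field_differs_predicate(self):
        # enumerate gene/variant call pairs for two reviewers against the
        # literal inequality predicate
        gene_calls = [G.PHENOTYPE_YES, G.UNCERTAIN_POSSIBLY]
        variant_calls = [V.VUS, V.MAPPING_ERROR, V.LIKELY_PATHOGENIC]
        combos = list(itertools.product(gene_calls, variant_calls))
        for c1, c2 in itertools.product(combos, repeat=2):
            project = _project(2)
            token = sorted(project.variants)[0]
            other = sorted(project.variants)[1]
            _review_all(project, {
                token: (c1, c2),
                other: ((G.UNCERTAIN_POSSIBLY, V.VUS), (G.UNCERTAIN_POSSIBLY, V.VUS)),
            })
            row = {r.variant.token(): r for r in project.merge_and_flag()}[token]
            assert row.discordant is (c1 != c2), (c1, c2)

    def test_discordance_is_symmetric(self):
        c1 = (G.PHENOTYPE_YES, V.VUS)
        c2 = (G.UNCERTAIN_POSSIBLY, V.MAPPING_ERROR)
        flags = []
        for first, second in [(c1, c2), (c2, c1)]:
            project = _project(2)
            tokens = sorted(project.variants)
            _review_all(project, {
                tokens[0]: (first, second),
                tokens[1]: (c1, c1),
            })
            row = {r.variant.token(): r for r in project.merge_and_flag()}
            flags.append(row[tokens[0]].discordant)
        assert flags == [True, True]

    def test_merge_is_idempotent(self):
        project = _project(4)
        tokens = sorted(project.variants)
        pairs = {t: ((G.UNCERTAIN_POSSIBLY, V.VUS), (G.UNCERTAIN_POSSIBLY, V.VUS))
                 for t in tokens}
        pairs[tokens[0]] = (
            (G.UNCERTAIN_POSSIBLY, V.VUS), (G.UNCERTAIN_POSSIBLY, V.MAPPING_ERROR)
        )
        _review_all(project, pairs)
        rows1 = project.merge_and_flag()
        resolutions1 = dict(project.resolutions)
        rows2 = project.merge_and_flag()
        assert rows1 == rows2
        assert project.resolutions == resolutions1

    def test_incomplete_variant_held_until_deadline_passes(self):
        deadline = dt.date.today() + dt.timedelta(days=7)
        project = _project(2, deadline=deadline)
        tokens = sorted(project.variants)
        _review_all(project, {tokens[0]: (
            (G.UNCERTAIN_POSSIBLY, V.VUS), (G.UNCERTAIN_POSSIBLY, V.VUS))})
        _call(project, tokens[1], "r1", G.UNCERTAIN_POSSIBLY, V.VUS)  # r2 missing
        rows = {r.variant.token(): r for r in project.merge_and_flag()}
        assert tokens[1] not in rows  # within deadline: not merged yet
        late_rows = {
            r.variant.token(): r
            for r in project.merge_and_flag(as_of=deadline + dt.timedelta(days=1))
        }
        assert late_rows[tokens[1]].status == "incomplete"
        assert late_rows[tokens[1]].late

    def test_discussion_actions_are_not_auto_resolved(self):
        project = _project(2)
        tokens = sorted(project.variants)
        # concordant mapping-error under phenotype-yes -> investigate via Sanger
        _review_all(project, {
            tokens[0]: ((G.PHENOTYPE_YES, V.MAPPING_ERROR), (G.PHENOTYPE_YES, V.MAPPING_ERROR)),
            tokens[1]: ((G.UNCERTAIN_POSSIBLY, V.VUS), (G.UNCERTAIN_POSSIBLY, V.VUS)),
        })
        rows = {r.variant.token(): r for r in project.merge_and_flag()}
        assert rows[tokens[0]].status == "needs_discussion"
        assert tokens[0] not in project.resolutions


class TestResolve:
    def _discordant_project(self):
        project = _project(2)
        tokens = sorted(project.variants)
        _review_all(project, {
            tokens[0]: ((G.UNCERTAIN_POSSIBLY, V.VUS),
                        (G.UNCERTAIN_POSSIBLY, V.MAPPING_ERROR)),
            tokens[1]: ((G.UNCERTAIN_POSSIBLY, V.VUS), (G.UNCERTAIN_POSSIBLY, V.VUS)),
        })
        project.merge_and_flag()
        return project, tokens

    def test_group_resolution_recomputes_action(self):
        project, tokens = self._discordant_project()
        resolution = project.resolve(
            VariantKey.from_token(tokens[0]), G.UNCERTAIN_POSSIBLY, V.VUS,
            minutes="group meeting: agreed VUS",
        )
        assert resolution.final_action is Action.REPORT_AND_SANGER
        assert resolution.resolved_by == "group_meeting"
        assert any(e["event"] == "group_resolution" for e in project.audit_log)

    def test_resolution_landing_on_error_cell_rejected(self):
        project, tokens = self._discordant_project()
        with pytest.raises(WorkflowError, match="re-categorise"):
            project.resolve(
                VariantKey.from_token(tokens[0]), G.NO_LITTLE_EVIDENCE,
                V.PATHOGENIC, minutes="",
            )

    def test_auto_resolved_variant_needs_override(self):
        project, tokens = self._discordant_project()
        key = VariantKey.from_token(tokens[1])
        with pytest.raises(WorkflowError, match="override"):
            project.resolve(key, G.UNCERTAIN_POSSIBLY, V.BENIGN, minutes="")
        resolution = project.resolve(
            key, G.UNCERTAIN_POSSIBLY, V.BENIGN, minutes="override", override=True
        )
        assert resolution.final_action is Action.DO_NOT_REPORT
        assert any(
            e["event"] == "group_resolution" and e.get("override")
            for e in project.audit_log
        )

    def test_every_resolution_action_matches_decide(self):
        project, tokens = self._discordant_project()
        project.resolve(
            VariantKey.from_token(tokens[0]), G.UNCERTAIN_POSSIBLY, V.VUS, minutes="m"
        )
        for resolution in project.resolutions.values():
            assert resolution.final_action is decide(
                resolution.final_variant_call, resolution.final_gene_call
            )


class TestSangerQueue:
    def _resolved_project(self):
        project = _project(9)
        tokens = sorted(project.variants)
        calls = {
            tokens[0]: (G.PHENOTYPE_YES, V.VUS),          # report & Sanger
            tokens[1]: (G.PHENOTYPE_YES, V.VUS),          # report & Sanger
            tokens[2]: (G.UNCERTAIN_POSSIBLY, V.VUS),     # report & Sanger
            tokens[3]: (G.NO_LITTLE_EVIDENCE, V.VUS),     # report, no Sanger
        }
        for t in tokens[4:]:
            calls[t] = (G.NO_CLEARLY_UNRELATED, V.VUS)    # do not report
        _review_all(project, {t: (c, c) for t, c in calls.items()})
        project.merge_and_flag()
        return project, tokens

    def test_queue_filters_on_sanger_requirement(self):
        project, tokens = self._resolved_project()
        queue = project.build_sanger_queue()
        assert len(queue) == 3
        assert {e.variant.token() for e in queue} == set(tokens[:3])
        assert all(e.status == "pending" for e in queue)

    def test_report_without_sanger_not_queued(self):
        project, tokens = self._resolved_project()
        project.build_sanger_queue()
        assert tokens[3] not in project.sanger_queue

    def test_queue_requires_full_resolution(self):
        project = _project(2)
        tokens = sorted(project.variants)
        _review_all(project, {tokens[0]: (
            (G.UNCERTAIN_POSSIBLY, V.VUS), (G.UNCERTAIN_POSSIBLY, V.VUS))})
        project.merge_and_flag()
        with pytest.raises(WorkflowError, match="unresolved"):
            project.build_sanger_queue()

    def test_confirmation_recorded(self):
        project, tokens = self._resolved_project()
        project.build_sanger_queue()
        entry = project.record_sanger_result(VariantKey.from_token(tokens[0]), True)
        assert entry.status == "confirmed"

    def test_failed_confirmation_reopens_discussion(self):
        project, tokens = self._resolved_project()
        project.build_sanger_queue()
        project.record_sanger_result(VariantKey.from_token(tokens[0]), False)
        assert tokens[0] in project.reopened
        queue_tokens = {r.variant.token() for r in project.discussion_queue()}
        assert tokens[0] in queue_tokens
        # resolving again (e.g. as mapping error after inspection) is allowed
        project.resolve(
            VariantKey.from_token(tokens[0]), G.NO_CLEARLY_UNRELATED, V.MAPPING_ERROR,
            minutes="group: not confirmed, artefact",
        )
        assert tokens[0] not in project.reopened


class TestArchive:
    def _completed(self):
        project, tokens = TestSangerQueue()._resolved_project()
        project.build_sanger_queue()
        for token in project.pending_validation():
            project.record_sanger_result(VariantKey.from_token(token), True)
        generate_report(project)
        return project, tokens

    def test_completed_case_feeds_recurrence_and_history(self):
        project, tokens = self._completed()
        archive = CaseArchive()
        archive_case(project, archive)
        assert project.archived
        result = query_recurrent(VariantKey.from_token(tokens[0]), archive)
        assert len(result) == 1
        assert result.occurrences[0].case_id == "CASE-T"
        assert archive.reviewer_history("r1") == ["CASE-T"]

    def test_double_archive_is_idempotent(self):
        project, _ = self._completed()
        archive = CaseArchive()
        archive_case(project, archive)
        archive_case(project, archive)
        assert len(archive) == 1

    def test_unreported_case_cannot_be_archived(self):
        project = _project(2)
        with pytest.raises(WorkflowError, match="report"):
            archive_case(project, CaseArchive())

    def test_recurrent_variant_surfaces_across_cases(self):
        project, tokens = self._completed()
        archive = CaseArchive()
        archive_case(project, archive)
        # a second case sees the same variant, resolved differently
        project2, tokens2 = TestSangerQueue()._resolved_project()
        project2.case_id = "CASE-U"
        project2.build_sanger_queue()
        for token in project2.pending_validation():
            project2.record_sanger_result(VariantKey.from_token(token), True)
        project2.resolutions[tokens2[0]].final_variant_call = V.LIKELY_PATHOGENIC
        generate_report(project2)
        archive_case(project2, archive)
        result = query_recurrent(VariantKey.from_token(tokens[0]), archive)
        assert len(result) == 2
        assert not result.consistent
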