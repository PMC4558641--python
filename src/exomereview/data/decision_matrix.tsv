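variant_call	phenotype_yes	no_clearly_unrelated	reportable_secondary	uncertain_possibly	no_little_evidence	de_novo_no_little_evidence
benign	do_not_report	do_not_report	do_not_report	do_not_report	do_not_report	do_not_report
likely_benign	report_and_sanger	do_not_report	do_not_report	report_and_sanger	report	report_and_sanger
intronic_likely_benign	report_and_sanger	do_not_report	do_not_report	report_and_sanger	do_not_report	do_not_report
vus	report_and_sanger	do_not_report	do_not_report	report_and_sanger	report	report_and_sanger
deleterious_vus	error_change_category	error_change_category	error_change_category	error_change_category	report_as_vus	report_as_vus_and_sanger
likely_pathogenic	report_and_sanger	need_discussion	report_as_secondary_and_sanger	report_and_sanger	error_change_to_deleterious_vus	error_change_to_deleterious_vus
pathogenic	report_and_sanger	need_discussion	report_as_secondary_and_sanger	report_and_sanger	error_change_to_deleterious_vus	error_change_to_deleterious_vus
mapping_error	investigate_via_sanger	do_not_report	do_not_report	need_discussion	do_not_report	do_not_report
compound_het_error	investigate_via_sanger	do_not_report	need_discussion	need_discussion	do_not_report	error_not_compound_het
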