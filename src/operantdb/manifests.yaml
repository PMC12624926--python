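# Header-name manifests for the standardized metadata templates.
# Matching is case-insensitive on the normalized header (lowercase, spaces
# and hyphens collapsed to underscores); column order is free. Users may
# override this file to track local template edits.
cohort_info:
  subject_id: [subject_id, subject, animal_id]
  rfid: [rfid]
  sex: [sex]
  cohort: [cohort, cohort_designation]
  experiment_group: [experiment_group, experimental_group, group]
  drug_group: [drug_group, drug]
  date_of_birth: [date_of_birth, dob]
  coat_color: [coat_color]
  ear_marks: [ear_marks, ear_mark]
  parentage: [parentage, dam_sire]
  dissection_group: [dissection_group]
  technician_ids: [technician_ids, technicians, tech_ids]
issues:
  subject_id: [subject_id, animal_id, subject]
  rfid: [rfid]
  date: [date, session_date]
  session_id: [session_id, session]
  issue_code: [issue_code, issue, code]
  keep: [keep, keep_discard, keep_decision]
  decision_type: [decision_type]
  notes: [notes, note, comments]
exit:
  subject_id: [subject_id, animal_id, subject]
  rfid: [rfid]
  cohort: [cohort]
  exit_date: [exit_date, date]
  last_good_session: [last_good_session, last_session]
  exit_code: [exit_code, code]
  decision_type: [decision_type]
  behavioral_testing_status: [behavioral_testing_status, behavior_status]
  tissue_collection_status: [tissue_collection_status, tissue_status]
  notes: [notes, comments]
  replaced: [replaced, replacement]
vonfrey:
  rfid: [rfid]
  subject_id: [subject_id, animal_id]
tail_immersion:
  rfid: [rfid]
  subject_id: [subject_id, animal_id]
  latency_presha_nodrug: [latency_presha_nodrug, pre_sha_no_drug, before_sha_without_drug]
  latency_presha_drug: [latency_presha_drug, pre_sha_drug, before_sha_with_drug]
  latency_postlga_drug: [latency_postlga_drug, post_lga_drug, after_lga_with_drug]
  latency_diff: [latency_diff, difference, diff]
irritability:
  rfid: [rfid]
  subject_id: [subject_id, animal_id]
  cohort: [cohort]
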