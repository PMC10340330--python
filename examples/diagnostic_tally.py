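"""Diagnostic detection tallies on the packaged 25-patient cohort.

Loads the per-patient diagnostic alterations (SNVs and CNAs that established
each tumor's molecular diagnosis) with their CSF cfDNA detection status and
tallies how often the diagnosis could have been made from CSF alone.
"""

from csfcfdna import evaluate_patient, load_cohort_fixture, tally_cohort

records = load_cohort_fixture()
tally = tally_cohort(records)

print(f"patients: {tally.n_patients}")
print(f"diagnostic SNV or CNA detected in CSF cfDNA: {tally.n_diagnostic_detected}/{tally.n_patients}")
print(f"patients with >=1 CNA detected in CSF:       {tally.n_cna_in_csf}/{tally.n_patients}")
print(f"patients with >=1 SNV detected in CSF:       {tally.n_snv_in_csf}/{tally.n_patients}")

print("\nsubgroup-defining drivers:")
for entity, label in [("MB_WNT", "WNT MB driver mutations (CTNNB1/APC)"),
                      ("ATRT", "ATRT SMARCB1 mutation/deletion"),
                      ("ETMR", "ETMR C19MC amplification")]:
    det, tot = tally_cohort(records, entity).per_entity[entity]
    print(f"  {label}: {det}/{tot}")

print("\nper-patient verdicts (first five):")
for rec in records[:5]:
    v = evaluate_patient(rec)
    print(f"  patient {rec.patient_id} ({rec.entity}): diagnostic_in_csf={v.any_diagnostic_in_csf}")
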