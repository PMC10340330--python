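"""Tumor vs CSF copy-number concordance matrix.

Simulates paired tumor/CSF segment calls for six patients (four shared
alterations, two tumor-private, one CSF-private per patient), matches
segments by class direction and reciprocal overlap, and prints the
alteration x patient status matrix with per-alteration frequencies.
"""

from csfcfdna import SimCNAParams, cohort_cna_matrix, match_segments, simulate_cna_cohort

cohort, truth = simulate_cna_cohort(6, SimCNAParams(seed=3))
concordances = [match_segments(t, c, patient_id=pid) for pid, (t, c) in cohort.items()]

for conc in concordances[:2]:
    print(conc.patient_id, conc.status_counts())

matrix = cohort_cna_matrix(concordances)
print("\nalteration x patient status matrix (top rows by frequency):")
print(matrix.head(10).to_string())
print("\n'both' = alteration seen in tumor and CSF cfDNA; private statuses reveal")
print("compartment-restricted copy-number changes; 'frequency' counts carriers.")
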