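"""Generate a synthetic primary-care cohort and write the five input tables.

The generator plants a known ground truth (follow-up, coverage days,
co-prescription days) computed by day-level enumeration, so downstream
results can be checked against it.
"""

from coprescribe import default_codelists, generate, scenario_library, write_codelists, write_tables

params = scenario_library("typical", n_patients=1000, seed=42)
tables, truth = generate(params)

out = "scratch/example_inputs"
write_tables(tables, out)
write_codelists(default_codelists(), out)

ref = truth.reference
print(f"patients: {len(tables.patients)}, prescriptions: {len(tables.therapy)}, "
      f"clinical events: {len(tables.clinical)}")
print(f"written to {out}/")
print(f"planted truth: {len(ref.followup)} people with eligible follow-up, "
      f"{len(ref.co_day_sets)} ever co-prescribed, "
      f"overall prevalence {truth.prevalence_per_1000py():.1f} per 1000 person-years")
# The last line is the target the pipeline should recover: people with >= 1
# day covered by both an opioid and an antidepressant, per 1000 py follow-up.
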