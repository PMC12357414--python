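"""Context of incident co-prescription: ordering, long-term opioid use,
prior antidepressant indications, and the cohort characteristics table.
"""

from coprescribe import default_codelists, generate, run, scenario_library

tables, _ = generate(scenario_library("typical", n_patients=1500, seed=9))
res = run(tables, default_codelists())
ctx = res.incident_context

print(f"{len(ctx)} people with incident co-prescription")
print("\nwhich class was started first (full history, incl. pre-entry):")
print((ctx["order"].value_counts(normalize=True) * 100).round(1).to_string())

opioid_first = ctx[ctx["order"] == "opioid_first"]
if len(opioid_first):
    pct = 100 * opioid_first["long_term_opioid"].mean()
    print(f"\nof the opioid-first group, {pct:.1f}% were long-term opioid users "
          "(>= 365 days of history, gaps <= 90 days) at first co-prescription")

print("\nantidepressant indications recorded on or before the event:")
for cat in ("depression", "anxiety_phobia", "neuropathic_pain", "any_indication"):
    print(f"  {cat}: {100 * ctx[cat].mean():.1f}%")

print("\ncharacteristics of the cohort by co-prescription status (sex rows):")
t1 = res.table1
print(t1[t1["characteristic"] == "sex"].round(1).to_string(index=False))
# Percentages are within-column; the 'yes' column describes the
# co-prescribed group, mirroring a standard baseline-characteristics table.
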