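"""Generate a synthetic milestone knowledge base, validate and export it.

The generator emits a screening KB with the documented shape: months 1-36,
108 questions split 3/32/48/25 across the four language domains, 3-6
questions per month, hearing items only in the first year.  The export is
the graph form (one node per month, question and suggestion type).
"""

from milescreen import validate_kb, export_graph
from milescreen.simulate import KbGenConfig, gen_kb

kb = gen_kb(KbGenConfig(seed=7))

print(f"coverage: months {kb.coverage_range[0]}-{kb.coverage_range[1]}")
print(f"questions: {kb.n_questions}")
print("per-domain quotas:",
      {d.value: n for d, n in kb.quotas.items()})
print(f"violations: {validate_kb(kb)}")

month14 = kb.months[14]
print(f"month 14 asks {len(month14.question_ids)} questions:",
      month14.question_ids)

graph = export_graph(kb)
lines = graph.splitlines()
print(f"graph export: {len(lines)} statements; first three:")
for line in lines[:3]:
    print(" ", line)

# An empty violation list means every structural rule holds: each month
# carries 3-6 resolvable questions, domain counts equal the quotas, and
# sensory (hearing) items never appear after month 12.
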