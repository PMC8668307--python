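"""Build a procedure's dependency matrix and find its rework loops.

Uses the packaged 9-activity laparoscopic-cholecystectomy structure: a
chain of steps with one mutual dependency between the cystic-artery
dissection (A6) and cutting (A7) steps, which rework each other when
bleeding occurs.
"""

from dsmsim import make_amis_fixture, partition

dsm = make_amis_fixture()
print(f"{dsm.n} activities, {len(dsm.edges)} dependencies")
for a in dsm.activities:
    print(f"  {a.id}: {a.label}  (MLV {a.duration.mlv:.2f} min, RI {a.rework_impact})")

part = partition(dsm)
print("\nexecution order:", " ".join(part.order))
print("rework loops:", [" <-> ".join(loop) for loop in part.loops] or "none")
for k, s in enumerate(part.active_sets, 1):
    print(f"active set {k}:", " ".join(s))

# The loop {A6, A7} is the strongly connected component of the dependency
# graph; the active sets show where execution pauses on a feedback
# dependency (A6 waits on A7's first execution).
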