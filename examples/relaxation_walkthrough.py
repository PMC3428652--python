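"""Reassigning a concept whose intersection type fell below threshold.

A concept carrying exactly {Organic Chemical, Hormone, Immunologic
Factor} loses its type whenever N > 1 (only one concept has that
combination).  The two strategies resolve it differently: the
largest-extent strategy picks the biggest maximal sub-signature type,
while the relax strategy generalises one functional member at a time
until an existing type is reached.
"""

import cssn

net = cssn.load_bundled_network()
namer = cssn.Namer(net)
pairs = cssn.iter_pairs(cssn.paper_extent_spec(), net)
table = cssn.restrict_to_chemical(pairs, net.subtree("Chemical"))
index = cssn.build_index(table)

built = cssn.build(index, net, cssn.BuildConfig(threshold=50))
orphan = cssn.Signature(
    net.resolve(n) for n in ("Organic Chemical", "Hormone", "Immunologic Factor")
)
sizes = {s: t.extent_size for s, t in built.types.items()}

print("candidates (maximal sub-signature types):")
for cand in sorted(cssn.candidates(orphan, built.signatures), key=sorted):
    print(f"  {namer.intersection_label(cand)}  extent={sizes[cand]}")

largest = cssn.reassign_largest(orphan, built.signatures, sizes)
print(f"\nlargest-extent strategy -> {namer.intersection_label(largest)}")

trace = cssn.reassign_relax(orphan, built.signatures, net)
print("relax strategy:")
for step in trace.steps:
    print(f"  relaxed {net.name_of(step.relaxed)} -> {net.name_of(step.replacement)}: "
          f"{namer.intersection_label(step.result)}")
print(f"  result -> {namer.intersection_label(trace.result)} "
      f"(extent {sizes[trace.result]})")
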