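"""Find small intersection types worth an auditor's attention.

Builds a threshold-1 network over a random synthetic assignment table
and lists intersection types with six or fewer concepts — in real
terminologies such tiny combinations often betray inconsistent
semantic-type assignments rather than genuine categories.
"""

import io

import cssn

net = cssn.load_bundled_network()
namer = cssn.Namer(net)
spec = cssn.random_spec(seed=2026, n_concepts=160, n_signatures=45, net=net)
text = cssn.generate(spec, net)
table = cssn.restrict_to_chemical(cssn.read_mrsty(io.StringIO(text)),
                                  net.subtree("Chemical"))
built = cssn.build(cssn.build_index(table), net, cssn.BuildConfig(threshold=1))

rows = cssn.audit_candidates(built, max_extent=6)
print(f"{len(rows)} intersection types with extent <= 6 "
      f"(of {len(built.ists)} total):")
for sig, size, cuis in rows:
    print(f"  {size}\t{namer.intersection_label(sig)}\t{','.join(sorted(cuis))}")
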