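"""How the threshold trades network size against concept coverage.

Sweeps the published extent-size fixture across the threshold values
used in the original study.  The type count includes all 25 pure types;
coverage is the percentage of concepts whose exact signature survives
as a type (100% at N=1 by construction).
"""

import cssn

net = cssn.load_bundled_network()
pairs = cssn.iter_pairs(cssn.paper_extent_spec(), net)
table = cssn.restrict_to_chemical(pairs, net.subtree("Chemical"))
index = cssn.build_index(table)

print("N\ttypes\tcoverage")
for n, count, cov in cssn.sweep(index, net, [500, 300, 100, 50, 1]):
    print(f"{n}\t{count}\t{100 * cov:.1f}%")
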