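"""Build a specialty network from the published extent sizes and list it.

Uses the bundled extent-size fixture (the per-signature concept counts
published for the 2009AA release) at threshold 300, then prints the
indented type listing.  Each row shows the formal intersection label,
the exact extent size, and the renamed type indented under its
placement parent; one asterisk per additional parent.
"""

import cssn

net = cssn.load_bundled_network()
pairs = cssn.iter_pairs(cssn.paper_extent_spec(), net)
table = cssn.restrict_to_chemical(pairs, net.subtree("Chemical"))
index = cssn.build_index(table)

built = cssn.build(index, net, cssn.BuildConfig(threshold=300))
print(f"{built.type_count} types "
      f"({len(built.psts)} pure, {len(built.ists)} intersection); "
      f"coverage {100 * built.coverage():.1f}%\n")
print(cssn.format_listing(cssn.render_listing(built)))
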