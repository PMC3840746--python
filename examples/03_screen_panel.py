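"""Specificity screen of a sequence panel against the marker.

One row per sequence: classification, span, primer-variant annotations
(mismatching bases bracketed, the plain-text analogue of bolding them in a
table), restriction-site flag and percent identity against a reference
marker.
"""

from ardra import FixtureSpec, extract_marker, make_aefb_like, screen_panel
from ardra.seqio import SequenceSet

members = [
    make_aefb_like(FixtureSpec(seed=0), seq_id="type_strain")[0],
    make_aefb_like(FixtureSpec(seed=0, n_marker_substitutions=12),
                   seq_id="related_sp")[0],
    make_aefb_like(FixtureSpec(seed=2, ablate_rev_site=True),
                   seq_id="outgroup_sp")[0],
]
panel = SequenceSet("demo_panel", members)

reference = extract_marker(panel[0]).amplicon.residues
table = screen_panel(panel, reference_marker=reference)
print(table.to_string(index=False))
print("\npositive = exactly one product; percent identity is the marker's "
      "integer-rounded identity to the reference (type-strain) marker")
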