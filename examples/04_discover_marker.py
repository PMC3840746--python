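"""De novo diagnostic-fragment discovery on a synthetic cohort.

Generalizes the marker-finding procedure: digest a target set and an
outgroup, bin fragment lengths, and keep bins prevalent in targets but not
in the outgroup.  The cohort plants a 463 bp HaeIII fragment in every
target, so the procedure must recover exactly that bin.
"""

from ardra import FixtureSpec, discover_marker, make_cohort

targets, outgroup, _ = make_cohort(FixtureSpec(seed=7), n_target=10,
                                   n_outgroup=10, divergence=5)
candidates = discover_marker(targets, outgroup, length_window=(200, 800),
                             min_target_prev=0.9, max_outgroup_prev=0.1)

print(f"{len(candidates)} candidate bin(s)\n")
for c in candidates:
    print(f"bin ~{c.bin_center} bp: target prevalence "
          f"{c.target_prevalence:.2f}, outgroup {c.outgroup_prevalence:.2f}")
    sid, spans = next(iter(sorted(c.spans.items())))
    print(f"  e.g. {sid}: fragment at {spans[0][0]}-{spans[0][1]}")
    if c.primer_proposals:
        p = c.primer_proposals[0]
        print(f"  proposed primers: fwd 5'-{p.fwd}-3' (Tm {p.tm_fwd:.1f} C), "
              f"rev 5'-{p.rev}-3' (Tm {p.tm_rev:.1f} C)")
print("\nprevalences of 1.0 / 0.0 mean the fragment-length bin separates "
      "the sets perfectly")
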