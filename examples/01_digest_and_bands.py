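"""In silico HaeIII digestion of a synthetic 16S-like gene.

Builds the standard marker-bearing sequence, digests it with HaeIII
(GG^CC) and prints the fragments and the gel-like band pattern.  The
463 bp fragment between the upstream flanking cut and the cut inside the
reverse-primer site is the diagnostic marker band.
"""

from ardra import (
    FixtureSpec, HAEIII, band_pattern, digest, has_diagnostic_band,
    make_aefb_like,
)

seq, truth = make_aefb_like(FixtureSpec(seed=0))
print(f"template: {seq.id}, {len(seq)} bp")

fragments = digest(seq, HAEIII)
print("\nfragments (1-based spans):")
for f in fragments:
    tag = "  <- diagnostic" if (f.start, f.end) == truth.diagnostic_fragment else ""
    print(f"  {f.start:>5}-{f.end:<5} {f.length:>4} bp{tag}")

pattern = band_pattern(fragments, bin_tolerance=10, min_visible_length=60)
print("\ngel-like bands (center, count); fragments < 60 bp run off:")
for center, count in pattern.bands:
    print(f"  ~{center} bp  x{count}")

print("\ndiagnostic ~460 bp band present:",
      has_diagnostic_band(pattern, target=460, tolerance=15))
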