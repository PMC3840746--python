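# ardra

In silico ARDRA (Amplified Ribosomal DNA Restriction Analysis) toolkit for
the diagnostic 16S rDNA marker of aerobic endospore-forming bacilli (AEFB:
*Bacillus* and related genera such as *Lysinibacillus*, *Brevibacillus*,
*Geobacillus*, *Virgibacillus*, *Terribacillus*, *Jeotgalibacillus*).

## The problem and the marker

HaeIII (GG↓CC) digestion of the amplified 16S rRNA gene yields, across AEFB
genera, a fragment of roughly 460 bp at a conserved position near the 3'
end of the gene — a fragment largely absent at that size in other bacterial
lineages, which makes it a simple identification and classification marker.
The fragment's exact extent is 461–463 bp; it is delimited by a HaeIII cut
site upstream of position ~905 and by the GGCC inside the sense-strand
segment `AATACGTTCCCGGGCCTT` that the reverse primer anneals to.  The marker
is amplifiable with the primer pair

```
463F  5'-CTGAAACTCAAAGGAATTGACG-3'
463R  5'-AAGGCCCGGGAACGTATT-3'      (sense-strand site AATACGTTCCCGGGCCTT)
```

(463F is also circulated in a `CTA...` form differing at the third base;
both constants ship and either can be selected.)

This package reimplements the whole computational side of that marker
system and generalizes it:

* **restriction** — IUPAC-aware cut-site finding, linear digestion,
  gel-like band patterns (fragments < 60 bp run off; lengths within 10 bp
  merge into one band), diagnostic-band test at 460 ± 15 bp;
* **amplify** — mismatch-tolerant primer-site search (Hamming, exact
  3'-anchor) and in silico PCR with outer-span coordinates;
* **marker** — marker extraction/classification, panel screening with
  primer-variant annotation and integer percent identity, de novo
  diagnostic-fragment discovery for arbitrary target/outgroup sets, and a
  simplified consensus/GC-Tm primer designer;
* **phylo** — pairwise p/Jukes–Cantor distances, Saitou–Nei neighbor
  joining, Newick I/O, tree cutting into k groups;
* **fixtures** — a synthetic 16S-like sequence generator that plants the
  marker geometry with a full coordinate truth record.

All coordinates anywhere in the toolkit are 1-based and inclusive on the
sense strand.

## Worked example

```python
from ardra import (FixtureSpec, make_aefb_like, extract_marker,
                   digest, band_pattern)

seq, truth = make_aefb_like(FixtureSpec(seed=0))   # synthetic 1550 bp 16S-like gene
call = extract_marker(seq)
print(call.classification)                  # positive
print(call.amplicon.start, call.amplicon.end, call.amplicon.length)
                                            # 909 1371 463
print(call.digest_fragment.length)          # 463
print(call.internal_site_present)           # True
print(band_pattern(digest(seq)).bands)
# [(105, 1), (118, 1), (183, 1), (463, 1), (659, 1)]
```

The marker screen classifies the sequence positive with the amplicon at
909–1371 (463 bp, the canonical marker position), finds the HaeIII digest
fragment carrying it (463 bp — the ~460 bp diagnostic gel band) and flags
the restriction site inside the amplified span.  The `examples/` directory
holds one short script per capability (digestion/bands, in silico PCR,
panel screening, marker discovery, marker trees, and an optional networked
accession screen); each prints the numbers it computes and what they mean.

A thin command line mirrors the library:

```
ardra pcr --fasta panel.fa --tsv products.tsv
ardra digest --fasta panel.fa --tsv fragments.tsv
ardra discover --targets t.fa --outgroup o.fa --json candidates.json
ardra tree --fasta markers.fa --model p --newick tree.nwk
ardra fixtures --seed 5 --out-dir fx/
```

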