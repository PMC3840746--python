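"""OPTIONAL, needs internet: screen a real 16S record fetched from NCBI.

Fetches one nucleotide accession (default AF483624, a Bacillus marisflavi
16S gene whose marker spans positions 909-1371), runs the marker screen
and prints the predicted span, which should match the published
coordinates.  All core operations work on local files; this helper is the
only networked code path in the package.
"""

import sys
import tempfile
from pathlib import Path

from ardra import extract_marker, read_fasta
from ardra.seqio import fetch_accession

accession = sys.argv[1] if len(sys.argv) > 1 else "AF483624"
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / f"{accession}.fasta"
    fetch_accession(accession, path)
    seq = read_fasta(path)[0]
    print(f"{accession}: {len(seq)} bp")
    call = extract_marker(seq)
    print(f"classification: {call.classification}")
    if call.amplicon:
        print(f"marker span {call.amplicon.start}-{call.amplicon.end} "
              f"({call.amplicon.length} bp), "
              f"site flag {'+' if call.internal_site_present else '-'}")
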