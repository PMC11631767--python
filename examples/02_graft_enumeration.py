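"""Enumerate threadings of a sensing motif into a latch helix.

Threads 7-11-residue prefixes of a (synthetic) binding motif into every
start offset of a 35-residue latch window (residues 610-644) and writes the
candidates to FASTA.  Each start offset presents the motif on a different
face of the helix; the heptad class (offset mod 7) labels that face.
"""

from collections import Counter
from pathlib import Path

from lockrkit.graft import (
    BindingMotif,
    LatchSegment,
    enumerate_placements,
    write_candidates_fasta,
)

# synthetic stand-ins: an idealised helical latch and an 11-mer motif
latch = LatchSegment("AEKLLKELEKLAKELQELAKKLEELAKKLSEESGS", 610, 644)
motif = BindingMotif("WDTAGQEKYRL", min_len=7, max_len=11)

candidates = enumerate_placements(latch, motif)
print(f"{len(candidates)} candidates "
      "(29+28+27+26+25 placements for lengths 7..11 on a 35-residue span)")

by_register = Counter(c.register_class for c in candidates)
print("candidates per heptad register class:", dict(sorted(by_register.items())))

out = Path("scratch_candidates.fasta")
n = write_candidates_fasta(candidates, latch, out)
first = candidates[0]
print(f"wrote {n} FASTA records to {out}")
print("first candidate:", first.threaded_sequence,
      f"(motif at residues {first.start_residue(latch)}-"
      f"{first.start_residue(latch) + first.motif_len - 1})")
out.unlink()  # tidy up
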