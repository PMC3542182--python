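"""De novo consensus discovery: over-represented 6-mers within a set,
differential 6-mers between two sets, and the one-nucleotide merge that
produces a degenerate consensus.

This is how the CEE motif arises: ATTTCC enriched in one analysis, ATTGCC
in another, merged to ATT[TG]CC (IUPAC ATTKCC).
"""

import numpy as np

from crmscan.kmers import differential_kmers, merge_consensi, overrepresented_kmers
from crmscan.motifs import ConsensusMotif, train_markov
from crmscan.seqio import SequenceRecord
from crmscan.simulate import generate_background, plant_motif

rng = np.random.default_rng(2)
bg = train_markov([SequenceRecord("r", "".join(rng.choice(list("ACGT"), 100_000)))], 3)

# plant AGATAC (the GATA-factor core) at 3/kb in 50 sequences
seqs = []
for i in range(50):
    rec = generate_background(1000, bg, seed=rng, id=f"s{i}")
    rec, _ = plant_motif(rec, ConsensusMotif("g", "AGATAC"), 3.0, seed=rng)
    seqs.append(rec)
top = overrepresented_kmers(seqs, 6, bg)[0]
print(f"most enriched 6-mer: {top.kmer} (observed {top.observed}, "
      f"expected {top.expected:.1f}, corrected p = {top.corrected_pvalue:.2e})")

# differential discovery between a "cardiac-like" set and a background set
A, B = [], []
for i in range(40):
    rec = generate_background(1000, bg, seed=rng, id=f"a{i}")
    occupied = []
    rec, _ = plant_motif(rec, ConsensusMotif("x", "ATTTCC"), 1.5, seed=rng, occupied=occupied)
    rec, _ = plant_motif(rec, ConsensusMotif("y", "ATTGCC"), 1.5, seed=rng, occupied=occupied)
    A.append(rec)
    B.append(generate_background(1000, bg, seed=rng, id=f"b{i}"))
top5 = differential_kmers(A, B, 6)[:5]
print("top differential 6-mers (A over B):", [s.kmer for s in top5])

merged = merge_consensi("ATTTCC", "ATTGCC", id="CEE")
print(f"merged consensus: {merged.pattern}  (= ATT[TG]CC)")
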