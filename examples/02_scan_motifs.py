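"""Scan sequences with a PWM (log-odds vs a Markov background) and an IUPAC
consensus, and turn hits into per-kb densities.

A PWM hit is a window whose natural-log odds of PWM vs background exceeds a
threshold (4.6 is the convention for classification scans); a consensus hit
is an exact match of the degenerate pattern on either strand.
"""

import numpy as np

from crmscan.motifs import (
    ConsensusMotif, build_pwm, hit_density, scan_consensus, scan_pwm, train_markov,
)
from crmscan.seqio import SequenceRecord

rng = np.random.default_rng(0)
background_seq = SequenceRecord("ref", "".join(rng.choice(list("ACGT"), 50_000)))
bg = train_markov([background_seq], order=2)

# a toy Tin-like PWM from aligned binding sites
pwm = build_pwm(["TCAAGTG", "TCAAGTG", "TTAAGTG", "TCAAGTC", "GCAAGTG"], id="tin")
region = SequenceRecord("enh1", "".join(rng.choice(list("ACGT"), 400)) + "TCAAGTG"
                        + "".join(rng.choice(list("ACGT"), 400)))

hits = scan_pwm(region, pwm, bg, threshold=4.6)
print(f"PWM hits above log-odds 4.6: {len(hits)}")
for h in hits:
    print(f"  offset {h.offset} strand {h.strand} score {h.score:.2f}")

cee = ConsensusMotif("CEE", "ATTKCC")  # ATT[TG]CC
chits = scan_consensus(SequenceRecord("enh2", "ATTGCCATTTCCGGCAAT"), cee)
print(f"consensus hits: {[(h.offset, h.strand) for h in chits]}")
print(f"density: {hit_density(hits, len(region)):.2f} hits/kb "
      "(the classifier's feature for this enhancer/motif pair)")
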