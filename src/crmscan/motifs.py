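"""Motif models and sequence scanning.

Two motif representations are supported: position weight matrices (PWMs)
built from aligned binding sites and scored by natural-log log-odds against
an order-m Markov background, and IUPAC consensus strings matched exactly
with degenerate codes expanded. Hit densities (hits per kb) are the feature
the downstream classifier consumes.

Log-odds scores use the natural log; the conventional significance
thresholds used in this package (4.6 for classification scans, 4.5 for
positional profiling) are interpreted on that scale.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .seqio import PathLike, SequenceRecord, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_CODE = {frozenset(v): k for k, v in IUPAC_CODES.items()}
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def iupac_complement(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (degenerate codes mapped setwise)."""
    out = []
    for code in reversed(pattern.upper()):
        bases = IUPAC_CODES.get(code)
        if bases is None:
            raise ValueError(f"invalid IUPAC code {code!r}")
        out.append(_SET_TO_CODE[frozenset(b.translate(_DNA_COMPLEMENT) for b in bases)])
    return "".join(out)


def expand_iupac(pattern: str) -> list[str]:
    """All concrete DNA words matching an IUPAC pattern."""
    words = [""]
    for code in pattern.upper():
        bases = IUPAC_CODES.get(code)
        if bases is None:
            raise ValueError(f"invalid IUPAC code {code!r}")
        words = [w + b for w in words for b in bases]
    return words


@dataclass
class PWM:
    """Position weight matrix over {A,C,G,T}.

    `counts` is a width x 4 array of non-negative site tallies; probabilities
    are derived with a symmetric pseudocount:
        probs[i, b] = (counts[i, b] + pseudocount) / (sum_b counts[i, b] + 4 * pseudocount)
    """

    id: str
    counts: np.ndarray
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4 or self.counts.shape[0] < 1:
            raise ValueError("PWM counts must be a width x 4 matrix with width >= 1")
        if (self.counts < 0).any():
            raise ValueError("PWM counts must be non-negative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def probs(self) -> np.ndarray:
        num = self.counts + self.pseudocount
        return num / num.sum(axis=1, keepdims=True)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.id, self.counts[::-1, ::-1].copy(), self.pseudocount)


@dataclass
class ConsensusMotif:
    """IUPAC consensus motif, e.g. ATTKCC for ATT[TG]CC."""

    id: str
    pattern: str

    def __post_init__(self) -> None:
        bad = [c for c in self.pattern.upper() if c not in IUPAC_CODES]
        if bad or not self.pattern:
            raise ValueError(f"invalid IUPAC pattern {self.pattern!r}")
        self.pattern = self.pattern.upper()

    @property
    def width(self) -> int:
        return len(self.pattern)


Motif = Union[PWM, ConsensusMotif]


@dataclass
class MotifHit:
    """A located motif occurrence within a region (offset is 0-based, forward coords)."""

    motif_id: str
    region_id: str
    offset: int
    strand: str
    width: int
    score: Optional[float] = None


def build_pwm(sites: Sequence[str], pseudocount: float = 0.5, id: str = "pwm") -> PWM:
    """Tally a PWM from equal-length aligned binding sites."""
    if not sites:
        raise ValueError("need at least one site to build a PWM")
    width = len(sites[0])
    counts = np.zeros((width, 4))
    for site in sites:
        site = site.upper()
        if len(site) != width:
            raise ValueError("all sites must have equal length")
        for i, base in enumerate(site):
            if base not in _BASE_INDEX:
                raise ValueError(f"non-ACGT character {base!r} in site")
            counts[i, _BASE_INDEX[base]] += 1
    return PWM(id, counts, pseudocount)


class MarkovBackground:
    """Order-m Markov chain over {A,C,G,T} trained from sequence counts.

    Conditional probabilities are maximum-likelihood ratios of (m+1)-mer to
    m-mer counts. Contexts shorter than the order (region edges) fall back to
    the marginal lower-order tables, which are always trained alongside.
    A (context, base) pair never observed in training is given the add-one
    floor 1/(total+4) so log-odds scores stay finite.
    """

    def __init__(self, order: int, counts: dict[int, dict[str, float]]):
        if order < 0:
            raise ValueError("Markov order must be >= 0")
        self.order = order
        # counts[k] maps k-mers (k = 1 .. order+1) to occurrence counts
        self.counts = counts

    @property
    def cond(self) -> dict[tuple[str, str], float]:
        """Conditional probability map over observed full-order contexts."""
        out = {}
        kmers = self.counts[self.order + 1]
        for ctx in {kmer[:-1] for kmer in kmers}:
            tot = sum(kmers.get(ctx + b, 0.0) for b in BASES)
            for b in BASES:
                out[(ctx, b)] = kmers.get(ctx + b, 0.0) / tot
        return out

    def prob(self, base: str, context: str = "") -> float:
        """P(base | context); context longer than the order is truncated from the left."""
        base = base.upper()
        if base not in _BASE_INDEX:
            raise ValueError(f"cannot score base {base!r}")
        ctx = context.upper()[-self.order :] if self.order else ""
        while True:
            table = self.counts[len(ctx) + 1]
            tot = sum(table.get(ctx + b, 0.0) for b in BASES)
            if tot > 0:
                cnt = table.get(ctx + base, 0.0)
                return cnt / tot if cnt > 0 else 1.0 / (tot + 4.0)
            if not ctx:
                return 0.25
            ctx = ctx[1:]  # back off if the marginal context itself is unseen

    def word_prob(self, word: str, left_context: str = "") -> float:
        """Probability of a word under the chain, conditioning within the word."""
        p = 1.0
        history = left_context.upper()
        for c in word.upper():
            p *= self.prob(c, history)
            history += c
        return p


def train_markov(seqs: Sequence[SequenceRecord], order: int, both_strands: bool = True) -> MarkovBackground:
    """Count k-mers (k = 1..order+1) over the unmasked portions of `seqs`.

    Masked (lowercase) and N positions break words. By default both strands
    are counted so the background is strand-symmetric.
    """
    if order < 0:
        raise ValueError("Markov order must be >= 0")
    counts: dict[int, dict[str, float]] = {k: {} for k in range(1, order + 2)}
    total = 0
    for rec in seqs:
        runs = re.findall(r"[ACGT]+", rec.seq)
        if both_strands:
            runs = runs + [reverse_complement(r) for r in runs]
        for run in runs:
            total += len(run)
            for k in counts:
                table = counts[k]
                for i in range(len(run) - k + 1):
                    kmer = run[i : i + k]
                    table[kmer] = table.get(kmer, 0.0) + 1.0
    if total == 0:
        raise ValueError("no unmasked sequence to train on")
    return MarkovBackground(order, counts)


def logodds_score(pwm: PWM, bg: MarkovBackground, window: str, left_context: str = "") -> float:
    """Natural-log odds of `window` under the PWM versus the background.

    The background conditions each position on up to `bg.order` preceding
    bases drawn from `left_context` and the window itself.
    """
    window = window.upper()
    if len(window) != pwm.width:
        raise ValueError("window length must equal PWM width")
    if "N" in window:
        return float("nan")
    probs = pwm.probs
    history = left_context.upper()
    score = 0.0
    for i, base in enumerate(window):
        score += math.log(probs[i, _BASE_INDEX[base]] / bg.prob(base, history))
        history += base
    return score


def _forward_pwm_hits(seq: str, pwm: PWM, bg: MarkovBackground, threshold: float,
                      region_id: str, strand: str, region_len: int) -> list[MotifHit]:
    w = pwm.width
    m = bg.order
    hits = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if any(c not in _BASE_INDEX for c in window):
            continue
        score = logodds_score(pwm, bg, window, seq[max(0, i - m) : i])
        if score > threshold:
            offset = i if strand == "+" else region_len - i - w
            hits.append(MotifHit(pwm.id, region_id, offset, strand, w, score))
    return hits


def scan_pwm(region: SequenceRecord, pwm: PWM, bg: MarkovBackground,
             threshold: float, strands: str = "both") -> list[MotifHit]:
    """All windows scoring strictly above `threshold`, overlaps kept, sorted by offset.

    Windows containing N are skipped; lowercase bases are scanned as their
    uppercase counterparts (apply a mask policy upstream to exclude them).
    Reverse-strand hits are reported at their forward-strand offsets.
    """
    if strands not in {"both", "forward"}:
        raise ValueError(f"unknown strands option {strands!r}")
    seq = region.seq.upper()
    hits = _forward_pwm_hits(seq, pwm, bg, threshold, region.id, "+", len(seq))
    if strands == "both":
        rc = reverse_complement(seq)
        hits += _forward_pwm_hits(rc, pwm, bg, threshold, region.id, "-", len(seq))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_consensus(region: SequenceRecord, motif: ConsensusMotif, strands: str = "both") -> list[MotifHit]:
    """All exact (degenerate-code-expanded) matches of an IUPAC consensus.

    Overlapping matches are all reported; with strands="both" the reverse
    complement of the pattern is also matched on the forward sequence and
    reported on the "-" strand at its forward offset.
    """
    if strands not in {"both", "forward"}:
        raise ValueError(f"unknown strands option {strands!r}")
    seq = region.seq.upper()
    patterns = [(motif.pattern, "+")]
    if strands == "both":
        patterns.append((iupac_complement(motif.pattern), "-"))
    hits = []
    for pattern, strand in patterns:
        regex = re.compile("(?=(" + "".join(
            b if len(IUPAC_CODES[b]) == 1 else "[" + IUPAC_CODES[b] + "]" for b in pattern
        ) + "))")
        for match in regex.finditer(seq):
            hits.append(MotifHit(motif.id, region.id, match.start(), strand, motif.width))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_motif(region: SequenceRecord, motif: Motif, bg: Optional[MarkovBackground] = None,
               threshold: float = 4.6, strands: str = "both") -> list[MotifHit]:
    """Dispatch to scan_pwm or scan_consensus depending on the motif type."""
    if isinstance(motif, PWM):
        if bg is None:
            raise ValueError("PWM scanning requires a background model")
        return scan_pwm(region, motif, bg, threshold, strands)
    return scan_consensus(region, motif, strands)


def hit_density(hits: Sequence[MotifHit], region_length: int) -> float:
    """Motif hits per kb of sequence."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    return len(hits) * 1000.0 / region_length


# ---------------------------------------------------------------------------
# text formats: PWMs as tab-separated A/C/G/T count rows under a "#id" header
# (JASPAR-style matrices transpose to this layout); consensi as id<TAB>IUPAC.

def read_pwms(path: PathLike, pseudocount: float = 0.5) -> list[PWM]:
    pwms = []
    current_id = None
    rows: list[list[float]] = []

    def flush():
        if current_id is not None:
            if not rows:
                raise ValueError(f"PWM {current_id!r} has no count rows")
            pwms.append(PWM(current_id, np.array(rows), pseudocount))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#") or line.startswith(">"):
                flush()
                current_id = line.lstrip("#>").strip()
                rows = []
            else:
                values = [float(v) for v in line.split()]
                if len(values) != 4:
                    raise ValueError(f"PWM row must have 4 columns (A C G T): {line!r}")
                rows.append(values)
    flush()
    return pwms


def write_pwms(pwms: Iterable[PWM], path: PathLike) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"#{pwm.id}\n")
            for row in pwm.counts:
                fh.write("\t".join(f"{v:g}" for v in row) + "\n")


def read_consensi(path: PathLike) -> list[ConsensusMotif]:
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"consensus line must be id<TAB>IUPAC: {line!r}")
            motifs.append(ConsensusMotif(fields[0], fields[1]))
    return motifs


def write_hits_bed(hits: Iterable[MotifHit], path: PathLike) -> None:
    """Hits as BED6 (chrom column = region id; score column = log-odds or .)."""
    with open(path, "w") as fh:
        for h in hits:
            score = f"{h.score:.4f}" if h.score is not None else "."
            fh.write(f"{h.region_id}\t{h.offset}\t{h.offset + h.width}\t{h.motif_id}\t{score}\t{h.strand}\n")
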