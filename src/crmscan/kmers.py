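"""K-mer over-representation and consensus merging.

A lightweight analog of oligonucleotide-analysis motif discovery: k-mers are
counted with overlaps, compared against a Markov-background expectation by a
binomial upper-tail test (within one set) or an exact two-sample binomial
test (between two sets), and similar consensus sequences differing in one
nucleotide are merged into an IUPAC-degenerate consensus. P-values are
controlled by Bonferroni over the canonical k-mer space by default
(Benjamini-Hochberg available by flag); the contract on clear planted
signals is rank agreement, not p-value equality with any external tool.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .motifs import ConsensusMotif, MarkovBackground, _SET_TO_CODE
from .seqio import SequenceRecord, reverse_complement


@dataclass
class KmerStats:
    kmer: str
    observed: int
    expected: float
    pvalue: float
    corrected_pvalue: float
    set_label: str = ""
    significant: bool = False


def _scannable_words(rec: SequenceRecord) -> list[str]:
    """Maximal runs of unmasked bases; masked (lowercase) and N break words."""
    return re.findall(r"[ACGT]+", rec.seq)


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return min(kmer, rc)


def n_canonical_kmers(k: int) -> int:
    n_pal = 4 ** (k // 2) if k % 2 == 0 else 0
    return (4**k + n_pal) // 2


def count_windows(seqs: Sequence[SequenceRecord], k: int) -> int:
    """Total scannable forward windows of width k."""
    return sum(max(0, len(run) - k + 1) for rec in seqs for run in _scannable_words(rec))


def count_kmers(seqs: Sequence[SequenceRecord], k: int, strands: str = "both") -> dict[str, int]:
    """Overlapping k-mer counts over unmasked runs.

    With strands="both" every forward window is tallied under the canonical
    representative of {kmer, revcomp}, so counts still sum to the number of
    forward windows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if strands not in {"both", "forward"}:
        raise ValueError(f"unknown strands option {strands!r}")
    counts: dict[str, int] = {}
    for rec in seqs:
        for run in _scannable_words(rec):
            for i in range(len(run) - k + 1):
                kmer = run[i : i + k]
                if strands == "both":
                    kmer = canonical(kmer)
                counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _kmer_prob(kmer: str, bg: MarkovBackground, strands: str) -> float:
    p = bg.word_prob(kmer)
    if strands == "both":
        rc = reverse_complement(kmer)
        if rc != kmer:
            p += bg.word_prob(rc)
    return p


def overrepresented_kmers(
    seqs: Sequence[SequenceRecord],
    k: int,
    bg: MarkovBackground,
    alpha: float = 0.05,
    strands: str = "both",
    correction: str = "bonferroni",
) -> list[KmerStats]:
    """Binomial upper-tail test of each observed k-mer against its background expectation.

    Expected counts are n_windows * P(kmer) under the background chain (both
    orientations pooled when strands="both"). Returned sorted by p-value.
    """
    if bg.order >= k:
        raise ValueError("background order must be smaller than k")
    counts = count_kmers(seqs, k, strands)
    n_windows = count_windows(seqs, k)
    n_tests = n_canonical_kmers(k) if strands == "both" else 4**k
    out = []
    for kmer, obs in counts.items():
        p = _kmer_prob(kmer, bg, strands)
        pval = float(stats.binom.sf(obs - 1, n_windows, p))
        out.append(KmerStats(kmer, obs, n_windows * p, pval, pval, set_label="set"))
    _correct(out, n_tests, alpha, correction)
    out.sort(key=lambda s: (s.pvalue, -s.observed, s.kmer))
    return out


def differential_kmers(
    setA: Sequence[SequenceRecord],
    setB: Sequence[SequenceRecord],
    k: int,
    alpha: float = 0.05,
    strands: str = "both",
    correction: str = "bonferroni",
) -> list[KmerStats]:
    """K-mers enriched in A over B, ranked by an exact two-sample binomial test.

    For each k-mer with pooled count c_A + c_B, the A-count is tested against
    Binomial(c_A + c_B, w_A / (w_A + w_B)) where w are scannable window
    totals, one-sided for enrichment in A.
    """
    if not setA or not setB:
        raise ValueError("both sequence sets must be non-empty")
    countsA = count_kmers(setA, k, strands)
    countsB = count_kmers(setB, k, strands)
    wA, wB = count_windows(setA, k), count_windows(setB, k)
    if wA == 0 or wB == 0:
        raise ValueError("both sets need scannable windows")
    p0 = wA / (wA + wB)
    n_tests = n_canonical_kmers(k) if strands == "both" else 4**k
    out = []
    for kmer in set(countsA) | set(countsB):
        cA, cB = countsA.get(kmer, 0), countsB.get(kmer, 0)
        pval = float(stats.binom.sf(cA - 1, cA + cB, p0))
        expected = (cA + cB) * p0
        out.append(KmerStats(kmer, cA, expected, pval, pval, set_label="A_vs_B"))
    _correct(out, n_tests, alpha, correction)
    out.sort(key=lambda s: (s.pvalue, -s.observed, s.kmer))
    return out


def _correct(entries: list[KmerStats], n_tests: int, alpha: float, method: str) -> None:
    if method == "bonferroni":
        for e in entries:
            e.corrected_pvalue = min(1.0, e.pvalue * n_tests)
    elif method == "bh":
        from statsmodels.stats.multitest import multipletests

        if entries:
            _, corrected, _, _ = multipletests([e.pvalue for e in entries], method="fdr_bh")
            for e, q in zip(entries, corrected):
                e.corrected_pvalue = float(q)
    else:
        raise ValueError(f"unknown correction {method!r}")
    for e in entries:
        e.significant = e.corrected_pvalue <= alpha


def merge_consensi(a: str, b: str, id: str = "merged") -> Optional[ConsensusMotif]:
    """Merge two consensus k-mers differing in at most one nucleotide.

    The differing position becomes the IUPAC code for the union of the two
    bases (ATTTCC + ATTGCC -> ATTKCC, i.e. ATT[TG]CC). Returns None when the
    Hamming distance is 2 or more (no merge).
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("consensus sequences must have equal length")
    diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    if len(diffs) > 1:
        return None
    if not diffs:
        return ConsensusMotif(id, a)
    i = diffs[0]
    code = _SET_TO_CODE[frozenset({a[i], b[i]})]
    return ConsensusMotif(id, a[:i] + code + a[i + 1 :])


def kmer_table(entries: Sequence[KmerStats]) -> pd.DataFrame:
    """KmerStats as a tidy frame (the module's TSV output schema)."""
    return pd.DataFrame(
        [
            {
                "kmer": e.kmer,
                "observed": e.observed,
                "expected": e.expected,
                "pvalue": e.pvalue,
                "corrected_pvalue": e.corrected_pvalue,
                "set_label": e.set_label,
                "significant": e.significant,
            }
            for e in entries
        ]
    )
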