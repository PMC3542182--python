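"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emulates a small enhancer study: 61 variable-length sequences
(24 positive-class "cardiac", 37 negative) drawn from an order-2 Markov
background trained on a 200 kb synthetic reference (GC 43%, fly-like), with
motif instances planted at class-specific densities — by default the CEE
consensus ATTKCC at 2.86/kb in the positive class versus 1.52/kb in the
negative, plus 30 non-degenerate noise 6-mers planted at equal density in
both classes so feature selection faces a realistic null pool. Planted
counts are Poisson (densities are expectations, as in real sequence), with
an exact-count mode for deterministic fixtures. Positions are uniform or
center-biased (Beta(5,5) of the relative position) for positional-profile
controls. A gene-landscape generator produces non-overlapping gene models
and peaks planted in known genomic categories for the annotation stage.

Every output is reproducible bit-for-bit from the design seed.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classify import EnhancerSet
from .annotate import GeneModel, PeakCall, peak_area
from .motifs import (
    BASES,
    ConsensusMotif,
    MarkovBackground,
    Motif,
    PWM,
    expand_iupac,
    train_markov,
)
from .seqio import GenomicInterval, PathLike, SequenceRecord, reverse_complement, write_fasta

CEE = ConsensusMotif("CEE", "ATTKCC")  # ATT[TG]CC
GATA = ConsensusMotif("GATA", "AGATAC")

# positive-class (cardiac-like) vs negative-class planted CEE densities, per kb
DEFAULT_POSITIVE_DENSITY = 2.86
DEFAULT_NEGATIVE_DENSITY = 1.52


@dataclass
class PlantSpec:
    motif: Motif
    density_positive: float  # planted instances per kb, positive class
    density_negative: float
    positional_mode: str = "uniform"  # or "center"

    def __post_init__(self) -> None:
        if self.density_positive < 0 or self.density_negative < 0:
            raise ValueError("densities must be >= 0")
        if self.positional_mode not in {"uniform", "center"}:
            raise ValueError(f"unknown positional mode {self.positional_mode!r}")


@dataclass
class StudyDesign:
    """Parameters of one synthetic enhancer study."""

    n_positive: int = 24
    n_negative: int = 37
    length_range: tuple[int, int] = (500, 1500)
    bg_order: int = 2
    planted: Optional[list[PlantSpec]] = None  # None -> cardiac default panel
    n_noise_motifs: int = 30
    noise_density: float = 0.5  # per kb, both classes
    gc_content: float = 0.43
    genome_length: int = 200_000
    seed: int = 0
    exact_counts: bool = False

    def __post_init__(self) -> None:
        if self.n_positive < 2 or self.n_negative < 2:
            raise ValueError("need at least 2 enhancers per class")


def cardiac_design(seed: int = 0, **overrides) -> StudyDesign:
    """The default study: CEE planted at 2.86 vs 1.52 per kb, uniform positions."""
    design = StudyDesign(
        planted=[PlantSpec(CEE, DEFAULT_POSITIVE_DENSITY, DEFAULT_NEGATIVE_DENSITY)],
        seed=seed,
    )
    return replace(design, **overrides)


def null_design(seed: int = 0, density: float = 2.0, **overrides) -> StudyDesign:
    """Null control: the same motif panel planted at equal density in both classes."""
    design = StudyDesign(planted=[PlantSpec(CEE, density, density)], seed=seed)
    return replace(design, **overrides)


@dataclass
class StudyResult:
    enhancers: EnhancerSet
    truth: pd.DataFrame  # one row per (sequence, motif): planted count + positions
    motifs: list[ConsensusMotif]  # full feature panel (planted + noise)
    background: MarkovBackground
    design: StudyDesign


def generate_background(length: int, bg: MarkovBackground,
                        seed: Union[int, np.random.Generator] = 0,
                        id: str = "bg") -> SequenceRecord:
    """Sample a sequence of the given length from the Markov chain."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = bg.order
    # precompute cumulative conditionals for every context length 0..m
    cum: dict[str, list[float]] = {}

    def cumulative(ctx: str) -> list[float]:
        if ctx not in cum:
            probs = np.array([bg.prob(b, ctx) for b in BASES])
            probs = probs / probs.sum()
            cum[ctx] = np.cumsum(probs).tolist()
        return cum[ctx]

    uniforms = rng.random(length)
    out = []
    for i in range(length):
        ctx = "".join(out[-m:]) if m else ""
        out.append(BASES[min(3, bisect_right(cumulative(ctx), uniforms[i]))])
    return SequenceRecord(id, "".join(out))


def sample_motif_instance(motif: Motif, rng: np.random.Generator) -> str:
    """A concrete DNA word: uniform over an IUPAC pattern's expansion, or
    per-position sampling from a PWM's probabilities."""
    if isinstance(motif, ConsensusMotif):
        words = expand_iupac(motif.pattern)
        return words[rng.integers(0, len(words))]
    probs = motif.probs
    return "".join(BASES[rng.choice(4, p=probs[i])] for i in range(motif.width))


class PlacementError(RuntimeError):
    """Raised when planted instances cannot be placed without overlap."""


def plant_motif(
    seq: SequenceRecord,
    motif: Motif,
    density_per_kb: float,
    positional_mode: str = "uniform",
    seed: Union[int, np.random.Generator] = 0,
    exact_count: Optional[int] = None,
    occupied: Optional[list[tuple[int, int]]] = None,
    max_tries: int = 1000,
) -> tuple[SequenceRecord, list[tuple[int, str]]]:
    """Write motif instances into a sequence at non-overlapping positions.

    The number of instances is Poisson(density x length / 1000) unless
    `exact_count` is given. Uniform mode draws positions uniformly; center
    mode draws the relative position from Beta(5,5). `occupied` carries
    already-planted intervals across calls so successive plantings never
    overwrite each other. Returns the new record and the (offset, word)
    placements.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(seq)
    w = motif.width
    n = exact_count if exact_count is not None else int(rng.poisson(density_per_kb * L / 1000.0))
    if occupied is None:
        occupied = []
    chars = list(seq.seq)
    placements = []
    for _ in range(n):
        for attempt in range(max_tries):
            if positional_mode == "center":
                frac = rng.beta(5.0, 5.0)
                pos = int(round(frac * (L - w)))
            else:
                pos = int(rng.integers(0, L - w + 1))
            if all(pos + w <= s or pos >= e for s, e in occupied):
                break
        else:
            raise PlacementError(
                f"could not place {motif.id} instance after {max_tries} tries in {seq.id}"
            )
        word = sample_motif_instance(motif, rng)
        chars[pos : pos + w] = word
        occupied.append((pos, pos + w))
        placements.append((pos, word))
    placements.sort()
    return SequenceRecord(seq.id, "".join(chars)), placements


def _noise_motifs(n: int, width: int, rng: np.random.Generator,
                  exclude: set[str]) -> list[ConsensusMotif]:
    """Random non-degenerate consensi avoiding the planted words (either strand)."""
    forbidden = set(exclude) | {reverse_complement(w) for w in exclude}
    out: list[ConsensusMotif] = []
    seen: set[str] = set()
    while len(out) < n:
        word = "".join(BASES[i] for i in rng.integers(0, 4, width))
        if word in forbidden or word in seen or reverse_complement(word) in seen:
            continue
        seen.add(word)
        out.append(ConsensusMotif(f"noise{len(out) + 1:02d}", word))
    return out


def generate_study(design: StudyDesign) -> StudyResult:
    """Generate one full labeled study from a design (seeded, reproducible)."""
    rng = np.random.default_rng(design.seed)
    p_gc = design.gc_content / 2
    p_at = (1 - design.gc_content) / 2
    base_probs = {("", b): p for b, p in zip(BASES, (p_at, p_gc, p_gc, p_at))}
    genome_chars = rng.choice(list(BASES), size=design.genome_length,
                              p=[p_at, p_gc, p_gc, p_at])
    genome = SequenceRecord("ref", "".join(genome_chars))
    bg = train_markov([genome], design.bg_order)

    planted = design.planted
    if planted is None:
        planted = [PlantSpec(CEE, DEFAULT_POSITIVE_DENSITY, DEFAULT_NEGATIVE_DENSITY)]
    exclude = set()
    for spec in planted:
        if isinstance(spec.motif, ConsensusMotif):
            exclude |= set(expand_iupac(spec.motif.pattern))
    exclude |= set(expand_iupac(GATA.pattern))
    noise = _noise_motifs(design.n_noise_motifs, 6, rng, exclude)
    all_specs = planted + [
        PlantSpec(m, design.noise_density, design.noise_density) for m in noise
    ]

    records: list[tuple[SequenceRecord, int]] = []
    truth_rows = []
    labels = [+1] * design.n_positive + [-1] * design.n_negative
    lo, hi = design.length_range
    for i, label in enumerate(labels):
        length = int(rng.integers(lo, hi + 1))
        name = f"enh{i + 1:03d}"
        rec = generate_background(length, bg, seed=rng, id=name)
        occupied: list[tuple[int, int]] = []
        for spec in all_specs:
            density = spec.density_positive if label > 0 else spec.density_negative
            exact = None
            if design.exact_counts:
                exact = int(round(density * length / 1000.0))
            rec, placements = plant_motif(
                rec, spec.motif, density, spec.positional_mode,
                seed=rng, exact_count=exact, occupied=occupied,
            )
            truth_rows.append(
                {
                    "sequence": name,
                    "label": label,
                    "length": length,
                    "motif": spec.motif.id,
                    "planted_count": len(placements),
                    "planted_density_per_kb": len(placements) * 1000.0 / length,
                    "positions": ",".join(str(p) for p, _ in placements),
                    "words": ",".join(w for _, w in placements),
                }
            )
        records.append((rec, label))

    planted_consensi = [s.motif for s in planted if isinstance(s.motif, ConsensusMotif)]
    truth = pd.DataFrame(truth_rows)
    enhancers = EnhancerSet(records, provenance=f"synthetic study seed={design.seed}")
    return StudyResult(enhancers, truth, planted_consensi + noise, bg, design)


def write_study(result: StudyResult, out_dir: PathLike) -> dict[str, Path]:
    """Write FASTA + label TSV + truth TSV + motif panel to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "enhancers.fa",
        "labels": out / "labels.tsv",
        "truth": out / "truth.tsv",
        "motifs": out / "motifs.tsv",
    }
    write_fasta(result.enhancers.sequences, paths["fasta"])
    with open(paths["labels"], "w") as fh:
        for rec, label in result.enhancers.records:
            fh.write(f"{rec.id}\t{label:+d}\n")
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["motifs"], "w") as fh:
        for m in result.motifs:
            fh.write(f"{m.id}\t{m.pattern}\n")
    return paths


# ---------------------------------------------------------------------------
# gene landscape fixtures for the annotation stage


def generate_gene_landscape(
    n_genes: int = 20,
    chrom_length: int = 1_000_000,
    seed: int = 0,
    n_peaks: int = 100,
    chrom: str = "chrS",
    promoter_span: int = 2000,
) -> tuple[list[GeneModel], list[PeakCall], pd.DataFrame]:
    """Non-overlapping two-exon genes plus peaks planted in known categories.

    Genes are laid out with wide intergenic gaps so every planted peak's
    category and nearest gene are unambiguous by construction; the truth
    table records both. Peak areas come from triangular signal contours.
    """
    rng = np.random.default_rng(seed)
    spacing = chrom_length // (n_genes + 1)
    if spacing < 2 * promoter_span + 12_000:
        raise ValueError("chromosome too short for the requested gene count")
    genes = []
    for i in range(n_genes):
        anchor = spacing * (i + 1) - 3000
        strand = "+" if rng.random() < 0.5 else "-"
        exon1 = GenomicInterval(chrom, anchor, anchor + 800)
        intron_len = int(rng.integers(1500, 3000))
        exon2_start = anchor + 800 + intron_len
        exon2 = GenomicInterval(chrom, exon2_start, exon2_start + 600)
        if strand == "+":
            cds_start = anchor + 300  # 300 bp 5'UTR at the head of exon 1
        else:
            cds_start = exon2.end - 300
        genes.append(GeneModel(f"g{i + 1:03d}", chrom, strand, [exon1, exon2], cds_start))

    categories = ["promoter", "exon", "5utr", "intron", "intergenic"]
    peaks, truth_rows = [], []
    for j in range(n_peaks):
        gene = genes[int(rng.integers(0, n_genes))]
        category = categories[j % len(categories)]
        sign = 1 if gene.strand == "+" else -1
        if category == "promoter":
            offset = int(rng.integers(200, promoter_span - 100))
            summit = gene.tss - sign * offset
            truth_gene = gene.id
        elif category == "exon":
            # CDS portion of exon 2 (+) / exon 1 (-): never 5'UTR
            exon = gene.exons[1] if gene.strand == "+" else gene.exons[0]
            summit = int(rng.integers(exon.start + 50, exon.end - 50))
            truth_gene = gene.id
        elif category == "5utr":
            if gene.strand == "+":
                summit = int(rng.integers(gene.exons[0].start + 10, gene.cds_start - 10))
            else:
                summit = int(rng.integers(gene.cds_start + 10, gene.exons[1].end - 10))
            truth_gene = gene.id
        elif category == "intron":
            summit = int(rng.integers(gene.exons[0].end + 50, gene.exons[1].start - 50))
            truth_gene = gene.id
        else:  # intergenic: past the 3' end, outside any promoter window
            offset = int(rng.integers(promoter_span + 500, spacing // 2 - 3500))
            summit = gene.end + offset if gene.strand == "+" else gene.start - offset
            truth_gene = gene.id  # still the nearest boundary by construction
        half_width = int(rng.integers(150, 400))
        start = max(0, summit - half_width)
        end = min(chrom_length, summit + half_width)
        height = float(rng.uniform(1.0, 10.0))
        signal = np.concatenate([
            np.linspace(0, height, summit - start + 1),
            np.linspace(height, 0, end - summit)[1:],
        ])
        peak = PeakCall(GenomicInterval(chrom, start, end), summit, peak_area(signal), f"pk{j + 1:04d}")
        peaks.append(peak)
        truth_rows.append({"peak_id": peak.id, "category": category, "gene_id": truth_gene})
    return genes, peaks, pd.DataFrame(truth_rows)
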