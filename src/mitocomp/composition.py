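"""Nucleotide composition, strand skews, codon usage and start/stop codons.

Skew conventions follow the standard strand-asymmetry measures
AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), computed on the
majority (J) strand unless a feature's coding strand dictates otherwise.
Codon statistics use the invertebrate mitochondrial genetic code
(translation table 5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from .model import MitoGenome, ValidationError
from .vocab import (
    AA_FAMILIES,
    CANONICAL_START_CODONS,
    CODON_TO_AA,
    ROLE_CR,
    ROLE_PCG,
    ROLE_RRNA,
    ROLE_TRNA,
    SENSE_CODONS,
    STOP_CODONS,
)


@dataclass(frozen=True)
class CompositionStats:
    """Base counts with AT/GC percentages and skews (N never counted)."""

    a: int
    c: int
    g: int
    t: int
    n: int
    at_percent: float
    gc_percent: float
    at_skew: float | None
    gc_skew: float | None


def composition_stats(seq: str) -> CompositionStats:
    """Counts, AT%/GC% and skews of one sequence; skews are None when the
    respective base pair is absent."""
    if not seq:
        raise ValidationError("empty sequence")
    a = seq.count("A")
    c = seq.count("C")
    g = seq.count("G")
    t = seq.count("T")
    n = seq.count("N")
    acgt = a + c + g + t
    at_pct = 100.0 * (a + t) / acgt if acgt else 0.0
    gc_pct = 100.0 * (g + c) / acgt if acgt else 0.0
    at_skew = (a - t) / (a + t) if (a + t) else None
    gc_skew = (g - c) / (g + c) if (g + c) else None
    return CompositionStats(a=a, c=c, g=g, t=t, n=n,
                            at_percent=at_pct, gc_percent=gc_pct,
                            at_skew=at_skew, gc_skew=gc_skew)


def _concat_role(genome: MitoGenome, role: str) -> str:
    return "".join(
        genome.feature_sequence(f)
        for f in genome.features
        if f.role == role and f.warning is None
    )


def class_composition(genome: MitoGenome) -> dict[str, CompositionStats]:
    """Composition of the whole genome and each functional class.

    PCG/tRNA/rRNA classes use concatenated coding-strand sequences; whole
    genome and control region are measured on the J strand.
    """
    out: dict[str, CompositionStats] = {
        "whole_genome": composition_stats(genome.sequence)
    }
    for label, role in (("PCGs", ROLE_PCG), ("tRNAs", ROLE_TRNA),
                        ("rRNAs", ROLE_RRNA)):
        seq = _concat_role(genome, role)
        if seq:
            out[label] = composition_stats(seq)
        else:
            warnings.warn(f"no {label} annotated; class omitted", stacklevel=2)
    cr = [f for f in genome.features if f.role == ROLE_CR and f.warning is None]
    if cr:
        out["control_region"] = composition_stats(genome.slice_circular(
            cr[0].start, cr[0].end))
    else:
        warnings.warn("no control region annotated; class omitted", stacklevel=2)
    return out


def _pcg_coding_seqs(genome: MitoGenome, trim_stops: bool = True) -> dict[str, str]:
    """Coding sequences of all PCGs, with (possibly incomplete) stops trimmed."""
    out = {}
    for f in genome.features:
        if f.role != ROLE_PCG or f.warning is not None:
            continue
        seq = genome.feature_sequence(f)
        if trim_stops:
            rem = len(seq) % 3
            if rem:
                # incomplete terminal codon (T or TA completed by polyadenylation)
                seq = seq[:-rem]
            elif seq[-3:] in STOP_CODONS:
                seq = seq[:-3]
        if len(seq) % 3:
            warnings.warn(
                f"{f.name}: length not divisible by 3 after stop trimming; "
                "trailing bases dropped", stacklevel=3)
            seq = seq[: len(seq) - len(seq) % 3]
        out[f.name] = seq
    return out


def codon_position_composition(genome: MitoGenome) -> dict:
    """Per-codon-position composition of the concatenated PCGs.

    Stop codons (complete or incomplete) are excluded before splitting by
    codon position.  Also reports the nucleotide frequency ranking at each
    position separately for J- and N-strand genes.
    """
    seqs = _pcg_coding_seqs(genome)
    if not seqs:
        raise ValidationError("no protein-coding genes annotated")
    strand_of = {f.name: f.strand for f in genome.features}
    pos_seq = {1: [], 2: [], 3: []}
    strand_pos_seq = {("J", p): [] for p in (1, 2, 3)}
    strand_pos_seq.update({("N", p): [] for p in (1, 2, 3)})
    for name, seq in seqs.items():
        for p in (1, 2, 3):
            sub = seq[p - 1 :: 3]
            pos_seq[p].append(sub)
            strand_pos_seq[(strand_of[name], p)].append(sub)
    result = {
        "positions": {
            p: composition_stats("".join(chunks))
            for p, chunks in pos_seq.items()
        },
        "strand_rankings": {},
    }
    for (strand, p), chunks in strand_pos_seq.items():
        joined = "".join(chunks)
        if not joined:
            continue
        stats = composition_stats(joined)
        ranking = "".join(sorted("TACG", key=lambda b: -getattr(stats, b.lower())))
        result["strand_rankings"][f"{strand}{p}"] = ranking
    return result


@dataclass
class CodonUsageTable:
    """Per-codon counts and RSCU over the 62 sense codons of table 5."""

    strand: str
    counts: dict[str, int]
    rscu_values: dict[str, float | None]

    def aa_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for codon, cnt in self.counts.items():
            aa = CODON_TO_AA[codon]
            totals[aa] = totals.get(aa, 0) + cnt
        return totals


def rscu(counts: dict[str, int]) -> dict[str, float | None]:
    """Relative synonymous codon usage.

    RSCU(c) = count(c) * degeneracy / family total; families with zero
    total get None for all members.  Rejects stop-codon keys.
    """
    for codon in counts:
        if codon in STOP_CODONS:
            raise ValidationError(f"stop codon {codon} in usage counts")
        if codon not in CODON_TO_AA:
            raise ValidationError(f"unknown codon {codon!r}")
    out: dict[str, float | None] = {}
    for aa, family in AA_FAMILIES.items():
        total = sum(counts.get(c, 0) for c in family)
        deg = len(family)
        for c in family:
            out[c] = deg * counts.get(c, 0) / total if total else None
    return out


def codon_usage(genome: MitoGenome) -> dict[str, CodonUsageTable]:
    """Codon usage and RSCU for J-strand genes, N-strand genes and combined.

    Counts are over in-frame sense codons of the coding sequences, stop
    codons excluded.  Internal in-frame stop codons trigger a warning.
    """
    seqs = _pcg_coding_seqs(genome)
    if not seqs:
        raise ValidationError("no protein-coding genes annotated")
    strand_of = {f.name: f.strand for f in genome.features}
    counts = {"J": {c: 0 for c in SENSE_CODONS},
              "N": {c: 0 for c in SENSE_CODONS},
              "both": {c: 0 for c in SENSE_CODONS}}
    for name, seq in seqs.items():
        strand = strand_of[name]
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                continue
            if codon in STOP_CODONS:
                warnings.warn(
                    f"{name}: internal stop codon {codon} at codon {i // 3 + 1}",
                    stacklevel=2)
                continue
            counts[strand][codon] += 1
            counts["both"][codon] += 1
    return {
        s: CodonUsageTable(strand=s, counts=cnts, rscu_values=rscu(cnts))
        for s, cnts in counts.items()
    }


@dataclass(frozen=True)
class CodonAssignment:
    """Start/stop codon classification of one protein-coding gene."""

    gene: str
    start_codon: str
    start_class: str  # canonical-ATN | non-canonical
    stop_codon: str   # TAA | TAG | TA | T
    stop_class: str   # complete | incomplete


def classify_start_stop(genome: MitoGenome) -> list[CodonAssignment]:
    """Classify start and stop codons of every annotated PCG.

    The start is the first in-frame triplet (canonical iff ATN); the stop is
    read from the annotated 3' end: a full in-frame TAA/TAG when the length
    is a multiple of three, otherwise the trailing T/TA is an incomplete
    stop presumed completed by post-transcriptional polyadenylation.
    """
    out = []
    for f in genome.features:
        if f.role != ROLE_PCG or f.warning is not None:
            continue
        seq = genome.feature_sequence(f)
        if len(seq) < 6:
            raise ValidationError(f"{f.name}: too short ({len(seq)} bp) for a PCG")
        start = seq[:3]
        start_class = ("canonical-ATN" if start in CANONICAL_START_CODONS
                       else "non-canonical")
        rem = len(seq) % 3
        if rem == 0:
            stop = seq[-3:]
            if stop not in STOP_CODONS:
                warnings.warn(f"{f.name}: no stop codon at annotated end",
                              stacklevel=2)
            stop_class = "complete"
        else:
            stop = seq[-rem:]
            stop_class = "incomplete"
        out.append(CodonAssignment(gene=f.name, start_codon=start,
                                   start_class=start_class, stop_codon=stop,
                                   stop_class=stop_class))
    return out


def most_frequent_codons(table: CodonUsageTable, k: int = 4) -> list[str]:
    """The k most used sense codons (ties broken alphabetically)."""
    return [c for c, _ in sorted(table.counts.items(),
                                 key=lambda kv: (-kv[1], kv[0]))[:k]]
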