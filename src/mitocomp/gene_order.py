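"""Gene order as a signed circular permutation; breakpoint comparison.

The mitogenome's gene arrangement is modelled as a circular ordered list of
(name, strand) pairs.  Rearrangements (e.g. the tRNA-Trp/tRNA-Cys
transposition found in derived lacewings) are detected and quantified with
the directed, strand-signed breakpoint (adjacency) distance: the number of
gene adjacencies of one order that are absent from the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .model import MitoGenome, ValidationError
from .vocab import IUPAC, revcomp

#: Putative ancestral insect arrangement: 37 genes + control region,
#: clockwise from tRNA-Ile, with J/N strand assignments.
_ANCESTRAL: tuple[tuple[str, str], ...] = (
    ("trnI", "J"), ("trnQ", "N"), ("trnM", "J"), ("ND2", "J"),
    ("trnW", "J"), ("trnC", "N"), ("trnY", "N"), ("COI", "J"),
    ("trnL2", "J"), ("COII", "J"), ("trnK", "J"), ("trnD", "J"),
    ("ATP8", "J"), ("ATP6", "J"), ("COIII", "J"), ("trnG", "J"),
    ("ND3", "J"), ("trnA", "J"), ("trnR", "J"), ("trnN", "J"),
    ("trnS1", "J"), ("trnE", "J"), ("trnF", "N"), ("ND5", "N"),
    ("trnH", "N"), ("ND4", "N"), ("ND4L", "N"), ("trnT", "J"),
    ("trnP", "N"), ("ND6", "J"), ("CytB", "J"), ("trnS2", "J"),
    ("ND1", "N"), ("trnL1", "N"), ("rrnL", "N"), ("trnV", "N"),
    ("rrnS", "N"), ("CR", "J"),
)


@dataclass(frozen=True)
class GeneOrder:
    """Circular ordered list of (gene name, strand) pairs."""

    elements: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.elements]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate gene names in order: {dup}")

    def __len__(self) -> int:
        return len(self.elements)

    def names(self) -> set[str]:
        return {n for n, _ in self.elements}

    def rotated_to(self, name: str) -> "GeneOrder":
        idx = [n for n, _ in self.elements].index(name)
        return GeneOrder(self.elements[idx:] + self.elements[:idx])

    def __eq__(self, other: object) -> bool:
        """Rotation-invariant equality with identical strand signs."""
        if not isinstance(other, GeneOrder):
            return NotImplemented
        if len(self) != len(other):
            return False
        if len(self) == 0:
            return True
        anchor = self.elements[0][0]
        if anchor not in other.names():
            return False
        return self.elements == other.rotated_to(anchor).elements

    def __hash__(self) -> int:  # canonical rotation: start at min name
        anchor = min(n for n, _ in self.elements)
        return hash(self.rotated_to(anchor).elements)

    def restricted_to(self, names: set[str]) -> "GeneOrder":
        return GeneOrder(tuple(e for e in self.elements if e[0] in names))


def ancestral_insect_order() -> GeneOrder:
    """The putative ancestral insect mitogenome arrangement (37 genes + CR)."""
    return GeneOrder(_ANCESTRAL)


def gene_order_of(genome: MitoGenome) -> GeneOrder:
    """Read the circular gene order off a genome's annotations.

    Features are taken in order of circularly-normalized start; ties are
    broken by span, longest first.
    """
    feats = [f for f in genome.features if f.warning is None]
    key_seen: set[tuple[int, int]] = set()
    for f in feats:
        key = (f.start % genome.length, f.span)
        if key in key_seen:
            raise ValidationError(
                f"features with identical start and span at {key}"
            )
        key_seen.add(key)
    feats.sort(key=lambda f: (f.start % genome.length, -f.span))
    return GeneOrder(tuple((f.name, f.strand) for f in feats))


Adjacency = tuple[tuple[str, str], tuple[str, str]]


def adjacency_set(order: GeneOrder) -> set[Adjacency]:
    """Directed, strand-signed adjacencies of a circular order.

    One adjacency per circular neighbour pair; |set| == number of elements.
    """
    if len(order) < 2:
        raise ValidationError("adjacency_set requires at least two elements")
    elems = order.elements
    return {
        (elems[i], elems[(i + 1) % len(elems)]) for i in range(len(elems))
    }


def _common(a: GeneOrder, b: GeneOrder) -> tuple[GeneOrder, GeneOrder]:
    shared = a.names() & b.names()
    if not shared:
        raise ValidationError("gene orders share no element names")
    if shared != a.names() or shared != b.names():
        warnings.warn(
            "gene orders have unequal element sets; comparison restricted "
            f"to the {len(shared)} shared genes",
            stacklevel=3,
        )
        return a.restricted_to(shared), b.restricted_to(shared)
    return a, b


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of adjacencies of ``a`` absent from ``b`` (symmetric).

    Zero iff the orders are equal up to rotation.
    """
    a, b = _common(a, b)
    return len(adjacency_set(a) - adjacency_set(b))


def diff_adjacencies(a: GeneOrder, b: GeneOrder) -> list[tuple[Adjacency, str]]:
    """Adjacencies unique to each order; empty iff breakpoint distance is 0."""
    a, b = _common(a, b)
    sa, sb = adjacency_set(a), adjacency_set(b)
    out = [(adj, "a") for adj in sorted(sa - sb)]
    out += [(adj, "b") for adj in sorted(sb - sa)]
    return out


@dataclass(frozen=True)
class JunctionRecord:
    """Gap between two circularly consecutive features.

    gap < 0 is an overlap of |gap| bp, gap > 0 an intergenic spacer,
    gap == 0 abutting genes.  junction_sequence holds the overlapped or
    spacer bases (forward strand), empty when abutting.
    """

    upstream: str
    downstream: str
    gap: int
    junction_sequence: str


def junction_table(genome: MitoGenome) -> list[JunctionRecord]:
    """One record per circular junction between consecutive features."""
    feats = [f for f in genome.features if f.warning is None]
    feats.sort(key=lambda f: (f.start % genome.length, -f.span))
    n = genome.length
    records = []
    for i, up in enumerate(feats):
        down = feats[(i + 1) % len(feats)]
        down_start = down.start
        if i == len(feats) - 1:
            down_start += n  # wrap to the first feature
        gap = down_start - up.end
        if gap < 0:
            seq = genome.slice_circular(down_start % n, (down_start % n) - gap)
        elif gap > 0:
            seq = genome.slice_circular(up.end % n, (up.end % n) + gap)
        else:
            seq = ""
        records.append(
            JunctionRecord(upstream=up.name, downstream=down.name,
                           gap=gap, junction_sequence=seq)
        )
    return records


def overlap_spacer_totals(genome: MitoGenome) -> dict[str, int]:
    """Summary of junction gaps: overlap/spacer totals and region counts.

    The control region is an order element but its flanking spacers are
    excluded from the intergenic totals, which count non-coding sequence
    outside the control region only.
    """
    recs = junction_table(genome)
    overlaps = [r for r in recs if r.gap < 0]
    spacers = [r for r in recs if r.gap >= 1 and "CR" not in (r.upstream, r.downstream)]
    return {
        "n_overlap_junctions": len(overlaps),
        "total_overlap_bp": sum(-r.gap for r in overlaps),
        "n_spacer_regions": len(spacers),
        "total_spacer_bp": sum(r.gap for r in spacers),
    }


def _degenerate_match(seq: str, pattern: str, offset: int) -> bool:
    if offset < 0 or offset + len(pattern) > len(seq):
        return False
    return all(
        seq[offset + i] in IUPAC[sym] for i, sym in enumerate(pattern)
    )


def find_junction_motif(
    genome: MitoGenome,
    pattern: str,
    junctions: list[tuple[str, str]],
    flank: int = 10,
) -> list[dict]:
    """Search named junctions (overlap/spacer region +- flank) for an IUPAC motif.

    Returns one record per requested junction with the match offset relative
    to the start of the searched window (-1 if absent).
    """
    for sym in pattern:
        if sym not in IUPAC:
            raise ValueError(f"unknown IUPAC symbol {sym!r} in pattern")
    recs = {(r.upstream, r.downstream): r for r in junction_table(genome)}
    n = genome.length
    out = []
    for pair in junctions:
        if pair not in recs:
            raise KeyError(f"unknown junction {pair[0]}->{pair[1]}")
        r = recs[pair]
        up = genome.feature_by_name(pair[0])
        # window: junction region plus flank on both sides
        center = up.end % n
        lo = center - max(0, -r.gap) - flank
        hi = center + max(0, r.gap) + flank
        window = genome.slice_circular(lo % n, (lo % n) + (hi - lo))
        offset, strand = -1, "J"
        for candidate, s in ((window, "J"), (revcomp(window), "N")):
            for i in range(len(candidate) - len(pattern) + 1):
                if _degenerate_match(candidate, pattern, i):
                    offset, strand = i, s
                    break
            if offset >= 0:
                break
        out.append({
            "junction": f"{pair[0]}/{pair[1]}",
            "gap": r.gap,
            "match": offset >= 0,
            "offset": offset,
            "strand": strand,
            "window_start": lo % n,
        })
    return out
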