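"""Conservation profiling over multiple alignments.

%INUC is the percentage of alignment columns at which every taxon carries
the same unambiguous nucleotide; columns containing gaps or N count toward
the denominator but can never be identical.  Site classes follow the usual
phylogenetic definitions: a variable site has >= 2 distinct bases among
its gap-free states, and a parsimony-informative site has >= 2 states each
present in >= 2 taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import AlignmentBlock, ValidationError

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class ConservationProfile:
    region: str
    n_cols: int
    n_identical_cols: int
    inuc_percent: float
    strand: str | None = None


def _column(alignment: AlignmentBlock, c: int) -> list[str]:
    return [row[c] for row in alignment.rows]


def inuc(alignment: AlignmentBlock, region: tuple[int, int] | None = None,
         name: str = "alignment", strand: str | None = None,
         ) -> ConservationProfile:
    """Percent identical nucleotides over an alignment (or column range)."""
    if alignment.n_taxa < 2:
        raise ValidationError("need >= 2 rows for conservation profiling")
    lo, hi = (0, alignment.n_cols) if region is None else region
    if hi <= lo or lo < 0 or hi > alignment.n_cols:
        raise ValidationError(f"empty or invalid column range [{lo}, {hi})")
    n_ident = 0
    for c in range(lo, hi):
        col = _column(alignment, c)
        if col[0] in _BASES and all(x == col[0] for x in col):
            n_ident += 1
    total = hi - lo
    return ConservationProfile(
        region=name, n_cols=total, n_identical_cols=n_ident,
        inuc_percent=100.0 * n_ident / total, strand=strand)


def inuc_by_gene(
    alignments: dict[str, AlignmentBlock],
    strands: dict[str, str] | None = None,
) -> list[ConservationProfile]:
    """Per-gene conservation profiles, ranked most conserved first.

    Ties are broken alphabetically by gene name."""
    profiles = [
        inuc(block, name=gene,
             strand=(strands or {}).get(gene))
        for gene, block in alignments.items()
    ]
    profiles.sort(key=lambda p: (-p.inuc_percent, p.region))
    return profiles


@dataclass(frozen=True)
class SiteClassCounts:
    n_cols: int
    constant: int
    variable: int
    parsimony_informative: int


def site_classes(alignment: AlignmentBlock) -> SiteClassCounts:
    """Constant / variable / parsimony-informative column counts.

    Columns whose gap-free states number < 2 bases are neither constant nor
    variable in the usual sense; here a column with one distinct base among
    its gap-free states counts as constant, and fully gapped columns count
    only toward n_cols.
    """
    constant = variable = informative = 0
    for c in range(alignment.n_cols):
        states = [x for x in _column(alignment, c) if x in _BASES]
        distinct = set(states)
        if len(distinct) >= 2:
            variable += 1
            multi = [b for b in distinct if states.count(b) >= 2]
            if len(multi) >= 2:
                informative += 1
        elif len(distinct) == 1:
            constant += 1
    return SiteClassCounts(n_cols=alignment.n_cols, constant=constant,
                           variable=variable,
                           parsimony_informative=informative)
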