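"""Base-compositional and branch-length heterogeneity assessment.

The disparity index of a sequence pair measures the excess of the observed
composition distance

    Dc = 1/2 * sum_x |count_x(a) - count_x(b)|      (x in {A,C,G,T})

over its expectation under a homogeneity null in which, at every observed
variable site, the direction of substitution is symmetric: which sequence
carries which of the two observed bases is resolved by a fair coin.  The
index is calibrated by Monte-Carlo resampling of that null; under
homogeneous (direction-symmetric) evolution ID = Dc - E[Dc | null] has
expectation ~0 and the test rejects at roughly its nominal level.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np

from .model import AlignmentBlock, ValidationError

PARTITION_NAMES = ("PCG123", "PCG12", "PCG12R", "PCG1", "PCG2", "PCG3")

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
# unordered base pairs and their +/- incidence on the 4 base counts
_PAIRS = [(x, y) for x, y in combinations(range(4), 2)]
_INCIDENCE = np.zeros((len(_PAIRS), 4))
for _k, (_x, _y) in enumerate(_PAIRS):
    _INCIDENCE[_k, _x] = 1.0
    _INCIDENCE[_k, _y] = -1.0


def complete_deletion(alignment: AlignmentBlock) -> AlignmentBlock:
    """Drop every column containing a gap, N, or other non-ACGT state."""
    if alignment.n_taxa == 0:
        raise ValidationError("empty alignment")
    cols = [
        c for c in range(alignment.n_cols)
        if all(row[c] in _BASES for row in alignment.rows)
    ]
    if not cols:
        raise ValidationError("complete deletion removed every column")
    return alignment.select_columns(cols)


@dataclass(frozen=True)
class PartitionSpec:
    """Named column-selection rule over a codon-aware concatenation.

    The position map assigns each column its codon position (1/2/3);
    PCG12R additionally appends an rRNA alignment supplied separately.
    """

    name: str

    def __post_init__(self) -> None:
        if self.name not in PARTITION_NAMES:
            raise ValidationError(
                f"unknown partition {self.name!r}; expected one of {PARTITION_NAMES}"
            )


def select_partition(
    alignment: AlignmentBlock,
    position_map: list[int],
    spec: PartitionSpec | str,
    rrna: AlignmentBlock | None = None,
) -> AlignmentBlock:
    """Restrict a codon-aware alignment to the columns of one partition."""
    if isinstance(spec, str):
        spec = PartitionSpec(spec)
    if len(position_map) != alignment.n_cols:
        raise ValidationError("position map length != alignment width")
    wanted = {
        "PCG123": {1, 2, 3}, "PCG12": {1, 2}, "PCG12R": {1, 2},
        "PCG1": {1}, "PCG2": {2}, "PCG3": {3},
    }[spec.name]
    cols = [c for c, p in enumerate(position_map) if p in wanted]
    block = alignment.select_columns(cols)
    if spec.name == "PCG12R":
        if rrna is None:
            raise ValidationError("PCG12R requires an rRNA alignment")
        if rrna.taxa != alignment.taxa:
            raise ValidationError("rRNA alignment taxa differ from PCG alignment")
        block = AlignmentBlock(
            taxa=list(block.taxa),
            rows=[a + b for a, b in zip(block.rows, rrna.rows)],
        )
    return block


def composition_distance(a: str, b: str) -> tuple[float, int]:
    """(Dc, Nd) for two equal-length gap-free sequences.

    Nd is the number of differing sites; Dc is half the L1 distance between
    the two base-count vectors.  Dc <= Nd, with equality when every
    difference pushes composition the same way.
    """
    if len(a) != len(b):
        raise ValidationError("sequences have unequal lengths")
    nd = sum(1 for x, y in zip(a, b) if x != y)
    dc = 0.5 * sum(abs(a.count(x) - b.count(x)) for x in _BASES)
    return dc, nd


@dataclass(frozen=True)
class DisparityResult:
    """Disparity index and Monte-Carlo homogeneity test for one pair."""

    pair: tuple[str, str]
    usable_sites: int
    nd: int
    dc: float
    e_dc_null: float
    id: float
    p_value: float
    replicates: int
    seed: int
    significant: bool


def _pair_type_counts(a: str, b: str) -> np.ndarray:
    """Counts of differing sites per unordered base pair (6-vector)."""
    counts = np.zeros(len(_PAIRS))
    idx = {frozenset(p): k for k, p in enumerate(_PAIRS)}
    for x, y in zip(a, b):
        if x != y:
            counts[idx[frozenset((_BASE_IDX[x], _BASE_IDX[y]))]] += 1
    return counts


def _null_dc_samples(m: np.ndarray, replicates: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo Dc under the direction-symmetric null.

    At each differing site the two observed bases are assigned to the two
    sequences by a fair coin; grouping sites by unordered base pair reduces
    the draw to one binomial per pair type per replicate.
    """
    k = rng.binomial(m.astype(np.int64), 0.5, size=(replicates, len(m)))
    net = 2 * k - m  # signed excess per pair type
    d = net @ _INCIDENCE  # (replicates, 4) count differences
    return 0.5 * np.abs(d).sum(axis=1)


def id_test(a: str, b: str, replicates: int = 1000, seed: int = 0,
            alpha: float = 0.01, pair: tuple[str, str] = ("a", "b"),
            ) -> DisparityResult:
    """Disparity index with Monte-Carlo homogeneity test for one pair.

    p-value uses the add-one permutation estimator
    (1 + #{Dc_rep >= Dc_obs}) / (replicates + 1).
    """
    if replicates < 100:
        raise ValidationError("replicates must be >= 100")
    for seq in (a, b):
        bad = set(seq) - set(_BASES)
        if bad:
            raise ValidationError(f"gap/ambiguity characters {sorted(bad)}; "
                                  "apply complete_deletion first")
    dc, nd = composition_distance(a, b)
    if nd == 0:
        return DisparityResult(pair=pair, usable_sites=len(a), nd=0, dc=0.0,
                               e_dc_null=0.0, id=0.0, p_value=1.0,
                               replicates=replicates, seed=seed,
                               significant=False)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    m = _pair_type_counts(a, b)
    samples = _null_dc_samples(m, replicates, rng)
    e_null = float(samples.mean())
    p = (1.0 + float((samples >= dc).sum())) / (replicates + 1)
    return DisparityResult(pair=pair, usable_sites=len(a), nd=nd, dc=dc,
                           e_dc_null=e_null, id=dc - e_null, p_value=p,
                           replicates=replicates, seed=seed,
                           significant=p < alpha)


def _pair_seed(seed: int, t1: str, t2: str) -> int:
    """Stable per-pair substream seed, symmetric in taxon order."""
    key = "|".join(sorted((t1, t2)))
    return (seed * 1_000_003 + zlib.crc32(key.encode())) % (2**31)


def pairwise_id_matrix(
    alignment: AlignmentBlock,
    replicates: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
    position_map: list[int] | None = None,
    spec: PartitionSpec | str | None = None,
    rrna: AlignmentBlock | None = None,
) -> dict[tuple[str, str], DisparityResult]:
    """All unordered pairwise disparity tests after partition selection and
    complete deletion.  n taxa -> n(n-1)/2 results; per-pair random
    substreams are derived from the sorted taxon pair so the matrix is
    invariant under taxon-order permutation."""
    if alignment.n_taxa < 2:
        raise ValidationError("need at least two taxa")
    if spec is not None:
        if position_map is None:
            raise ValidationError("partition selection requires a position map")
        alignment = select_partition(alignment, position_map, spec, rrna=rrna)
    alignment = complete_deletion(alignment)
    rows = dict(zip(alignment.taxa, alignment.rows))
    out: dict[tuple[str, str], DisparityResult] = {}
    for t1, t2 in combinations(sorted(alignment.taxa), 2):
        out[(t1, t2)] = id_test(
            rows[t1], rows[t2], replicates=replicates,
            seed=_pair_seed(seed, t1, t2), alpha=alpha, pair=(t1, t2))
    return out


@dataclass(frozen=True)
class TaxonIDSummary:
    taxon: str
    sum_id: float
    mean_id: float
    n_pairs: int
    n_significant: int


def taxon_id_summary(
    matrix: dict[tuple[str, str], DisparityResult]
) -> list[TaxonIDSummary]:
    """Per-taxon sum and mean of its pairwise disparity indices."""
    taxa = sorted({t for pair in matrix for t in pair})
    out = []
    for taxon in taxa:
        ids = [r.id for pair, r in matrix.items() if taxon in pair]
        nsig = sum(1 for pair, r in matrix.items()
                   if taxon in pair and r.significant)
        out.append(TaxonIDSummary(taxon=taxon, sum_id=sum(ids),
                                  mean_id=sum(ids) / len(ids),
                                  n_pairs=len(ids), n_significant=nsig))
    return out


def rank_partitions(
    summaries: dict[str, list[TaxonIDSummary]]
) -> list[tuple[str, float, bool]]:
    """Partitions ordered best (most homogeneous) to worst by grand-mean ID.

    Returns (partition, grand_mean_id, tied_with_previous)."""
    grand = {
        name: (sum(s.mean_id for s in rows) / len(rows) if rows else 0.0)
        for name, rows in summaries.items()
    }
    ordered = sorted(grand, key=lambda nm: (grand[nm], list(grand).index(nm)))
    out: list[tuple[str, float, bool]] = []
    for i, name in enumerate(ordered):
        tied = i > 0 and grand[name] == grand[ordered[i - 1]]
        out.append((name, grand[name], tied))
    return out


# ---------------------------------------------------------------------------
# Branch-length heterogeneity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TipDepth:
    taxon: str
    depth: float


def tip_depths(newick: str, root_on: str | None = None) -> list[TipDepth]:
    """Root-to-tip path lengths (substitutions/site) for every tip.

    The tree must be rooted (bifurcating basal node) or an outgroup taxon
    must be named via ``root_on``, in which case the tree is re-rooted on
    that tip's edge first.  Missing branch lengths are an error.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    if root_on is not None:
        node = None
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is not None and leaf.taxon.label == root_on:
                node = leaf
                break
        if node is None:
            raise ValidationError(f"outgroup taxon {root_on!r} not in tree")
        if node.edge.length is None:
            raise ValidationError(f"edge above {root_on!r} has no length")
        tree.reroot_at_edge(node.edge, length1=node.edge.length / 2.0,
                            length2=node.edge.length / 2.0,
                            update_bipartitions=False)
    root = tree.seed_node
    if len(root.child_nodes()) > 2:
        raise ValidationError(
            "tree appears unrooted (basal polytomy); re-root or pass root_on")
    out = []
    for leaf in tree.leaf_node_iter():
        depth = 0.0
        node = leaf
        while node is not root:
            if node.edge.length is None:
                label = (node.taxon.label if node.taxon else "<internal>")
                raise ValidationError(f"edge above {label!r} has no length")
            if node.edge.length < 0:
                raise ValidationError("negative branch length")
            depth += node.edge.length
            node = node.parent_node
        label = leaf.taxon.label if leaf.taxon else "?"
        out.append(TipDepth(taxon=label, depth=depth))
    out.sort(key=lambda t: t.taxon)
    return out


def depth_heterogeneity(
    depths: list[TipDepth],
    groups: dict[str, str] | None = None,
) -> dict:
    """Mean/SD/CV and max-min ratio of root-to-tip depths, with optional
    per-clade group means (taxon -> clade map)."""
    if len(depths) < 2:
        raise ValidationError("need at least two tips")
    vals = np.array([t.depth for t in depths], dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    out = {
        "n_tips": len(depths),
        "mean": mean,
        "sd": sd,
        "cv": sd / mean if mean > 0 else 0.0,
        "max_min_ratio": float(vals.max() / vals.min()) if vals.min() > 0
        else float("inf"),
    }
    if groups is not None:
        by_group: dict[str, list[float]] = {}
        for t in depths:
            clade = groups.get(t.taxon)
            if clade is not None:
                by_group.setdefault(clade, []).append(t.depth)
        for clade in set(groups.values()):
            if clade not in by_group:
                import warnings
                warnings.warn(f"group {clade!r} has zero members", stacklevel=2)
        out["group_means"] = {
            clade: sum(v) / len(v) for clade, v in sorted(by_group.items())
        }
    return out
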