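"""Stage orchestration: single-genome profiling and multi-taxon comparison.

Both entry points aggregate module outputs into a deterministic report
bundle (an ordered mapping of report name -> list of row dicts) that the
CLI serializes; no number in a report is recomputed here.
"""

from __future__ import annotations

from pathlib import Path

from . import composition, conservation, gene_order, heterogeneity, repeats
from .genome_io import write_report
from .model import AlignmentBlock, MitoGenome


def _comp_row(label: str, st: composition.CompositionStats) -> dict:
    return {
        "region": label, "A": st.a, "C": st.c, "G": st.g, "T": st.t,
        "N": st.n,
        "at_percent": round(st.at_percent, 1),
        "gc_percent": round(st.gc_percent, 1),
        "at_skew": "NA" if st.at_skew is None else round(st.at_skew, 3),
        "gc_skew": "NA" if st.gc_skew is None else round(st.gc_skew, 3),
    }


def profile(genome: MitoGenome, reference: gene_order.GeneOrder | None = None,
            ) -> dict[str, list[dict]]:
    """Full single-genome report bundle.

    Covers gene order vs the reference arrangement (ancestral insect order
    by default), the junction table with overlap/spacer totals, per-class
    and codon-position composition, codon usage with RSCU, start/stop
    classification and control-region repeat analytics.
    """
    if reference is None:
        reference = gene_order.ancestral_insect_order()
    bundle: dict[str, list[dict]] = {}

    order = gene_order.gene_order_of(genome)
    bd = gene_order.breakpoint_distance(order, reference)
    diffs = gene_order.diff_adjacencies(order, reference)
    bundle["gene_order"] = [{
        "n_elements": len(order),
        "breakpoint_distance": bd,
        "matches_reference": bd == 0,
    }]
    bundle["rearrangements"] = [
        {"adjacency": f"{a[0][0]}({a[0][1]})->{a[1][0]}({a[1][1]})",
         "present_in": "genome" if side == "a" else "reference"}
        for a, side in diffs
    ]
    bundle["junctions"] = [
        {"upstream": r.upstream, "downstream": r.downstream, "gap": r.gap,
         "junction_sequence": r.junction_sequence}
        for r in gene_order.junction_table(genome)
    ]
    totals = gene_order.overlap_spacer_totals(genome)
    bundle["junction_totals"] = [totals]

    bundle["composition"] = [
        _comp_row(label, st)
        for label, st in composition.class_composition(genome).items()
    ]
    pos = composition.codon_position_composition(genome)
    bundle["codon_positions"] = [
        _comp_row(f"position_{p}", st) for p, st in pos["positions"].items()
    ]
    bundle["strand_rankings"] = [
        {"strand_position": k, "ranking": v}
        for k, v in sorted(pos["strand_rankings"].items())
    ]
    tables = composition.codon_usage(genome)
    bundle["codon_usage"] = [
        {"strand": strand, "codon": c,
         "aa": composition.CODON_TO_AA[c],
         "count": tbl.counts[c],
         "rscu": "NA" if tbl.rscu_values[c] is None
         else round(tbl.rscu_values[c], 3)}
        for strand, tbl in tables.items()
        for c in sorted(tbl.counts)
    ]
    bundle["start_stop"] = [
        {"gene": a.gene, "start_codon": a.start_codon,
         "start_class": a.start_class, "stop_codon": a.stop_codon,
         "stop_class": a.stop_class}
        for a in composition.classify_start_stop(genome)
    ]

    cr = [f for f in genome.features if f.role == "control_region"]
    if cr:
        cr_seq = genome.slice_circular(cr[0].start, cr[0].end)
        bundle["cr_motifs"] = [
            {"motif": m, "count": repeats.count_motif(cr_seq, m)}
            for m in ("AT", "AAT", "AATT", "AATTT", "AATTTTT", "TTATATAT")
        ]
        bundle["cr_microsatellites"] = [_hit_row(h) for h in
                                        repeats.find_microsatellites(cr_seq)]
        bundle["cr_tandem_repeats"] = [_hit_row(h) for h in
                                       repeats.find_tandem_repeats(cr_seq)]
        bundle["cr_repeat_pairs"] = [
            _hit_row(h) for h in repeats.find_approximate_repeat_pairs(cr_seq)
        ]
    return bundle


def _hit_row(h: repeats.RepeatHit) -> dict:
    return {
        "kind": h.kind, "unit": h.unit, "period": h.period,
        "copies": round(h.copies, 2),
        "spans": ";".join(f"{s}-{e}" for s, e in h.spans),
        "identity": round(h.identity, 3),
    }


def compare(
    pcg_alignment: AlignmentBlock,
    position_map: list[int],
    gene_alignments: dict[str, AlignmentBlock] | None = None,
    rrna_alignment: AlignmentBlock | None = None,
    tree_newick: str | None = None,
    partitions: tuple[str, ...] = ("PCG123", "PCG12", "PCG1", "PCG2", "PCG3"),
    replicates: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    groups: dict[str, str] | None = None,
) -> dict[str, list[dict]]:
    """Multi-taxon report: disparity-index matrices per partition with
    per-taxon summaries and partition ranking, conservation profiles and
    site classes for per-gene alignments, and tip-depth heterogeneity."""
    bundle: dict[str, list[dict]] = {}
    summaries: dict[str, list[heterogeneity.TaxonIDSummary]] = {}
    for part in partitions:
        matrix = heterogeneity.pairwise_id_matrix(
            pcg_alignment, replicates=replicates, seed=seed, alpha=alpha,
            position_map=position_map, spec=part, rrna=rrna_alignment)
        bundle[f"id_matrix_{part}"] = [
            {"taxon_a": p[0], "taxon_b": p[1], "usable_sites": r.usable_sites,
             "nd": r.nd, "dc": r.dc, "e_dc_null": round(r.e_dc_null, 4),
             "id": round(r.id, 4), "p_value": round(r.p_value, 5),
             "significant": r.significant}
            for p, r in sorted(matrix.items())
        ]
        summaries[part] = heterogeneity.taxon_id_summary(matrix)
    # Table-style per-taxon summary: one row per taxon, Sum/Mean per partition
    taxa = sorted({s.taxon for rows in summaries.values() for s in rows})
    table_rows = []
    for taxon in taxa:
        row: dict = {"taxon": taxon}
        for part in partitions:
            entry = next(s for s in summaries[part] if s.taxon == taxon)
            row[f"{part}_sum"] = round(entry.sum_id, 2)
            row[f"{part}_mean"] = round(entry.mean_id, 2)
        table_rows.append(row)
    bundle["taxon_id_summary"] = table_rows
    bundle["partition_ranking"] = [
        {"rank": i + 1, "partition": name, "grand_mean_id": round(gm, 4),
         "tied_with_previous": tied}
        for i, (name, gm, tied) in enumerate(
            heterogeneity.rank_partitions(summaries))
    ]

    if gene_alignments:
        bundle["conservation"] = [
            {"gene": p.region, "n_cols": p.n_cols,
             "n_identical": p.n_identical_cols,
             "inuc_percent": round(p.inuc_percent, 1),
             "strand": p.strand or "NA"}
            for p in conservation.inuc_by_gene(gene_alignments)
        ]
        bundle["site_classes"] = [
            {"gene": gene, **vars(conservation.site_classes(block))}
            for gene, block in sorted(gene_alignments.items())
        ]

    if tree_newick is not None:
        depths = heterogeneity.tip_depths(tree_newick)
        bundle["tip_depths"] = [
            {"taxon": t.taxon, "depth": round(t.depth, 6)} for t in depths
        ]
        het = heterogeneity.depth_heterogeneity(depths, groups=groups)
        flat = {k: (round(v, 6) if isinstance(v, float) else v)
                for k, v in het.items() if k != "group_means"}
        bundle["depth_heterogeneity"] = [flat]
        if "group_means" in het:
            bundle["depth_group_means"] = [
                {"group": g, "mean_depth": round(m, 6)}
                for g, m in het["group_means"].items()
            ]
    return bundle


def write_bundle(bundle: dict[str, list[dict]], outdir: str | Path,
                 format: str = "tsv", seed: int | None = None) -> list[Path]:
    """Write each report of a bundle to <outdir>/<name>.<ext>; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    ext = "json" if format == "json" else "tsv"
    for name, rows in bundle.items():
        path = outdir / f"{name}.{ext}"
        write_report(rows, path, format=format)
        written.append(path)
    if seed is not None:
        write_report([{"seed": seed}], outdir / f"run_info.{ext}", format=format)
        written.append(outdir / f"run_info.{ext}")
    return written
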