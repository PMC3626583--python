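"""Summary tables: RGH class counts, cluster characteristics, map statistics.

All report arithmetic is pure aggregation over its inputs: totals are sums,
the mean adjacent-marker spacing is total cM divided by the number of
adjacent intervals (total loci minus the number of linkage groups), coverage
is anchored length over genome length.  Rounding follows the conventions of
the tables being emulated: cM and densities to 1 decimal, percentages to 1
decimal, spacing to 2 decimals.
"""

from __future__ import annotations

import pandas as pd

from .rgh import RGH_CLASSES, class_counts, cluster_stats


def union_locus_count(*id_collections) -> int:
    """Number of unique marker ids across collections (provenance accounting:
    combining maps adds exactly the new markers)."""
    out: set[str] = set()
    for coll in id_collections:
        out |= set(coll)
    return len(out)


def mean_marker_spacing(total_cm: float, total_loci: int, n_lgs: int) -> float:
    """Average distance between adjacent markers.

    The denominator counts adjacent intervals: total loci minus one per
    linkage group.
    """
    intervals = total_loci - n_lgs
    if intervals <= 0:
        raise ValueError("need more loci than linkage groups")
    return total_cm / intervals


def summarize_classes(genes) -> pd.DataFrame:
    """Class-count table over the six NB-LRR architecture classes."""
    counts = class_counts(genes)
    rows = [{"class": c, "n_genes": counts.get(c, 0)} for c in RGH_CLASSES]
    rows.append({"class": "Total", "n_genes": sum(counts.values())})
    return pd.DataFrame(rows)


def summarize_clusters(clusters, n_genes_total: int,
                       map_positions: dict[str, float] | None = None) -> pd.DataFrame:
    """Cluster table (members, physical span, density, genetic span) plus a
    totals row with the clustered-gene percentage."""
    rows = []
    clustered = 0
    for c in clusters:
        s = cluster_stats(c, map_positions)
        s["chromosome"] = c.chromosome
        s["scaffolds"] = ",".join(c.scaffold_ids)
        rows.append(s)
        clustered += len(c.members)
    pct = round(100.0 * clustered / n_genes_total, 1) if n_genes_total else 0.0
    rows.append({
        "cluster_id": "Total", "n_members": clustered, "span_kb": None,
        "density_per_100kb": None, "genetic_span_cm": None,
        "chromosome": f"{len(clusters)} clusters", "scaffolds": f"{pct}% of {n_genes_total}",
    })
    return pd.DataFrame(rows)


def summarize_map_table(per_lg_rows: list[dict]) -> pd.DataFrame:
    """Per-linkage-group map table with a totals row and mean spacing.

    Each input row needs ``lg``, ``n_loci`` and ``length_cm``; optional
    columns (``n_shared``, ``n_scaffolds_anchored``, ``anchored_mb``) are
    summed when present.
    """
    df = pd.DataFrame(per_lg_rows)
    total = {"lg": "Total", "n_loci": int(df["n_loci"].sum()),
             "length_cm": round(float(df["length_cm"].sum()), 1)}
    for col in ("n_shared", "n_scaffolds_anchored", "anchored_mb"):
        if col in df.columns:
            total[col] = round(float(df[col].sum()), 1)
    spacing = mean_marker_spacing(float(df["length_cm"].sum()), int(df["n_loci"].sum()), len(df))
    df = df.copy()
    df["mean_spacing_cm"] = (df["length_cm"] / (df["n_loci"] - 1)).round(2)
    total["mean_spacing_cm"] = round(spacing, 2)
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def consensus_map_rows(consensus, anchor_report=None) -> list[dict]:
    """Build per-lg summary rows from a consensus map (and optional anchors)."""
    anchored_by_lg: dict[str, tuple[int, float]] = {}
    if anchor_report is not None:
        for a in anchor_report.scaffolds:
            if a.anchored:
                n, mb = anchored_by_lg.get(a.lg, (0, 0.0))
                anchored_by_lg[a.lg] = (n + 1, mb)
    rows = []
    for lg, loci in consensus.linkage_groups:
        row = {"lg": lg, "n_loci": len(loci),
               "length_cm": round(loci[-1].cm - loci[0].cm, 1) if loci else 0.0}
        if anchor_report is not None:
            row["n_scaffolds_anchored"] = anchored_by_lg.get(lg, (0, 0.0))[0]
        rows.append(row)
    return rows
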