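"""Readers and writers for the plain-text interchange formats.

Maps are TSV (marker, LG, cM [, flags]); genotypes are the delimited matrix
handled by :mod:`cucumap.genotypes`; primers, annotations, synteny blocks and
report tables are TSV; sequences are FASTA (Bio.SeqIO).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .linkage import ComponentMap, LinkageGroupMap, Locus


def write_map(cmap: ComponentMap, path) -> None:
    rows = []
    for lg in cmap.linkage_groups:
        for loc in lg.loci:
            flags = []
            if loc.is_rgh_tag:
                flags.append("rgh_tag")
            if loc.is_gene:
                flags.append("gene")
            rows.append({"marker": loc.marker_id, "LG": lg.name,
                         "cM": round(loc.cm, 4), "flags": ",".join(flags)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_map(path, name: str | None = None) -> ComponentMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "LG": str})
    lgs = []
    for lg_name, sub in df.groupby("LG", sort=True):
        sub = sub.sort_values(["cM", "marker"])
        base = float(sub["cM"].iloc[0])
        loci = []
        for _, row in sub.iterrows():
            flags = str(row.get("flags", "")) if "flags" in df.columns else ""
            loci.append(Locus(str(row["marker"]), float(row["cM"]) - base,
                              "rgh_tag" in flags, "gene" in flags))
        lgs.append(LinkageGroupMap(str(lg_name), loci))
    return ComponentMap(name or Path(path).stem, lgs)


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(records.items())),
        str(path), "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_primers(primers, path) -> None:
    rows = [{"marker": p.marker_id, "fwd_seq": p.fwd, "rev_seq": p.rev} for p in primers]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_primers(path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [(r["marker"], r["fwd_seq"], r["rev_seq"]) for _, r in df.iterrows()]


def write_annotations(genes, path) -> None:
    """Gene annotation TSV: gene, scaffold, start, end (1-based inclusive),
    comma-joined ordered domain labels, NB-domain aa span."""
    rows = []
    for g in genes:
        span = getattr(g, "nb_domain_span", None) or getattr(g, "nb_span", None)
        rows.append({
            "gene": g.id, "scaffold": g.scaffold_id,
            "start": g.start_bp, "end": g.end_bp,
            "domains": ",".join(getattr(g, "domains", None) or g.domain_architecture),
            "nb_span": f"{span[0]}-{span[1]}" if span else "",
            "chromosome": getattr(g, "chromosome", "") or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path):
    from .rgh import RghGene

    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "scaffold": str}, keep_default_na=False)
    genes = []
    for _, r in df.iterrows():
        span = None
        if str(r.get("nb_span", "")):
            a, b = str(r["nb_span"]).split("-")
            span = (int(a), int(b))
        genes.append(RghGene(
            id=str(r["gene"]), scaffold_id=str(r["scaffold"]),
            start_bp=int(r["start"]), end_bp=int(r["end"]),
            domains=tuple(str(r["domains"]).split(",")),
            chromosome=str(r["chromosome"]) or None if "chromosome" in df.columns else None,
            nb_domain_span=span,
        ))
    return genes


def write_synteny_blocks(blocks, path) -> None:
    pd.DataFrame(
        blocks, columns=["q_chrom", "q_start", "q_end", "s_chrom", "s_start", "s_end"]
    ).to_csv(path, sep="\t", index=False)


def read_synteny_blocks(path):
    df = pd.read_csv(path, sep="\t")
    return [tuple(r) for r in df.itertuples(index=False)]


def write_clusters_bed(clusters, path) -> None:
    """Cluster intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.chromosome}\t{c.start_bp - 1}\t{c.end_bp}\t{c.id}\t{len(c.members)}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
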