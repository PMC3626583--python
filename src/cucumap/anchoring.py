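"""In silico PCR marker-to-scaffold assignment and genetic-physical anchoring.

Primer pairs are searched against both strands of every scaffold; a product
is called when the forward primer and the reverse-complemented reverse primer
face each other within the maximum product length.  Markers are labelled
"unique" (one product genome-wide), "no hit" (none) or "multi-copy" (two or
more).  Scaffolds are anchored to the linkage group carrying the majority of
their uniquely assigned mapped markers; coverage is the anchored fraction of
the genome length.  Colinearity of the genetic and physical orders is
summarised per linkage group with Spearman's rank correlation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class PcrError(ValueError):
    pass


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _primer_regex(primer: str) -> re.Pattern:
    parts = []
    for base in primer:
        opts = IUPAC.get(base.upper())
        if opts is None:
            raise PcrError(f"non-IUPAC base {base!r} in primer")
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def _find_sites(primer: str, template: str) -> list[int]:
    """All (overlapping) match start positions of a primer on a template."""
    primer = primer.upper()
    if all(b in "ACGT" for b in primer):  # fast path: exact substring scan
        sites = []
        pos = template.find(primer)
        while pos != -1:
            sites.append(pos)
            pos = template.find(primer, pos + 1)
        return sites
    return [m.start() for m in _primer_regex(primer).finditer(template)]


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product (1-based inclusive, forward-primer 5' end to
    reverse-primer 5' end)."""

    marker_id: str
    scaffold_id: str
    start_bp: int
    end_bp: int
    strand: str  # strand carrying the forward primer

    @property
    def product_length(self) -> int:
        return self.end_bp - self.start_bp + 1


def insilico_pcr(marker_id: str, fwd: str, rev: str, scaffolds: dict[str, str],
                 max_product: int = 2000) -> tuple[list[Amplicon], str]:
    """Search a primer pair against all scaffolds of one assembly.

    Exact matching (IUPAC degeneracy honoured); both orientations are
    scanned.  Returns the amplicons and a genome-wide label: "unique",
    "no hit" or "multi-copy".
    """
    if len(fwd) < 15 or len(rev) < 15:
        raise PcrError("primers must be at least 15 nt")
    for primer in (fwd, rev):
        for base in primer.upper():
            if base not in IUPAC:
                raise PcrError(f"non-IUPAC base {base!r} in primer")
    fwd_u, rev_u = fwd.upper(), rev.upper()

    amplicons: list[Amplicon] = []
    for sid in sorted(scaffolds):
        template = scaffolds[sid].upper()
        # forward primer on + strand, reverse primer site (revcomp) downstream
        f_sites = _find_sites(fwd_u, template)
        r_rc_sites = _find_sites(_revcomp(rev_u), template)
        for f in f_sites:
            for r in r_rc_sites:
                end = r + len(rev)  # 0-based exclusive end of the rev site
                if end - f >= len(fwd) + len(rev) and end - f <= max_product and r >= f:
                    amplicons.append(Amplicon(marker_id, sid, f + 1, end, "+"))
        # forward primer on - strand: rev primer on + strand, revcomp(fwd) downstream
        r_sites = _find_sites(rev_u, template)
        f_rc_sites = _find_sites(_revcomp(fwd_u), template)
        for r in r_sites:
            for f in f_rc_sites:
                end = f + len(fwd)
                if end - r >= len(fwd) + len(rev) and end - r <= max_product and f >= r:
                    amplicons.append(Amplicon(marker_id, sid, r + 1, end, "-"))

    label = "unique" if len(amplicons) == 1 else "no hit" if not amplicons else "multi-copy"
    return amplicons, label


def assign_markers(primer_pairs, scaffolds: dict[str, str],
                   max_product: int = 2000) -> dict[str, tuple[list[Amplicon], str]]:
    """Run in silico PCR for every (marker, fwd, rev) primer pair."""
    out = {}
    for p in primer_pairs:
        marker, fwd, rev = (p.marker_id, p.fwd, p.rev) if hasattr(p, "fwd") else p
        out[marker] = insilico_pcr(marker, fwd, rev, scaffolds, max_product)
    return out


# ---------------------------------------------------------------------------
# Scaffold anchoring
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldAnchor:
    scaffold_id: str
    lg: str | None
    anchored: bool
    supporting_markers: list[str]
    orientation: str  # "+", "-" or "unoriented"


@dataclass
class AnchorReport:
    scaffolds: list[ScaffoldAnchor]
    n_scaffolds_anchored: int
    anchored_bp: int
    genome_bp: int
    coverage_percent: float


def coverage_percent(anchored_bp: float, genome_bp: float) -> float:
    if genome_bp <= 0:
        raise PcrError("genome_bp must be positive")
    return 100.0 * anchored_bp / genome_bp


def anchor_scaffolds(map_positions: dict[str, tuple[str, float]],
                     marker_scaffolds: dict[str, str],
                     scaffold_lengths: dict[str, int],
                     genome_bp: int | None = None,
                     marker_offsets: dict[str, int] | None = None) -> AnchorReport:
    """Anchor scaffolds onto a genetic map via uniquely assigned markers.

    ``map_positions``: marker -> (lg, cM) from the consensus map;
    ``marker_scaffolds``: marker -> scaffold for uniquely assigned markers.
    A scaffold's lg is the majority lg of its mapped markers (ties are left
    unanchored with a warning).  Orientation is the sign of the within-
    scaffold cM-versus-bp slope when ``marker_offsets`` are supplied;
    single-marker scaffolds are anchored but unoriented.
    """
    by_scaffold: dict[str, list[str]] = {}
    for marker, scaf in marker_scaffolds.items():
        if marker in map_positions:
            by_scaffold.setdefault(scaf, []).append(marker)

    anchors: list[ScaffoldAnchor] = []
    anchored_bp = 0
    for sid in sorted(scaffold_lengths):
        markers = sorted(by_scaffold.get(sid, []))
        if not markers:
            anchors.append(ScaffoldAnchor(sid, None, False, [], "unoriented"))
            continue
        votes: dict[str, int] = {}
        for m in markers:
            lg = map_positions[m][0]
            votes[lg] = votes.get(lg, 0) + 1
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            warnings.warn(f"scaffold {sid}: tied linkage-group vote; unanchored", stacklevel=2)
            anchors.append(ScaffoldAnchor(sid, None, False, markers, "unoriented"))
            continue
        lg = ranked[0][0]
        support = [m for m in markers if map_positions[m][0] == lg]
        orientation = "unoriented"
        if marker_offsets and len(support) >= 2:
            cms = np.array([map_positions[m][1] for m in support])
            bps = np.array([float(marker_offsets.get(m, 0)) for m in support])
            if len(set(bps)) > 1 and len(set(cms)) > 1:
                slope = np.polyfit(bps, cms, 1)[0]
                orientation = "+" if slope >= 0 else "-"
        anchors.append(ScaffoldAnchor(sid, lg, True, support, orientation))
        anchored_bp += scaffold_lengths[sid]

    genome = genome_bp if genome_bp is not None else sum(scaffold_lengths.values())
    return AnchorReport(
        anchors,
        sum(1 for a in anchors if a.anchored),
        anchored_bp,
        genome,
        coverage_percent(anchored_bp, genome),
    )


def anchor_genes(genes, marker_scaffolds: dict[str, str],
                 map_positions: dict[str, tuple[str, float]]) -> dict[str, bool]:
    """Which genes can be delimited on the map (their scaffold carries at
    least one mapped marker)."""
    mapped_scaffolds = {marker_scaffolds[m] for m in marker_scaffolds if m in map_positions}
    return {g.id: (g.scaffold_id in mapped_scaffolds) for g in genes}


# ---------------------------------------------------------------------------
# Genetic-physical colinearity
# ---------------------------------------------------------------------------


def colinearity_check(map_positions: dict[str, tuple[str, float]],
                      marker_physical: dict[str, tuple[str, int]],
                      anchor_report: AnchorReport | None = None) -> dict[str, tuple[float | None, int]]:
    """Per-lg Spearman r between genetic (cM) and physical marker order.

    ``marker_physical``: marker -> (scaffold, bp offset).  Physical order is
    anchored-scaffold order (by median marker cM) then within-scaffold bp,
    flipped for scaffolds whose inferred orientation is "-".  Linkage groups
    with fewer than 2 dual-coordinate markers are reported as undefined
    (None).  |r| is reported together with the sign convention handled by
    scaffold orientation, so a perfectly colinear but globally reversed
    assembly still scores 1.
    """
    orientation = {}
    if anchor_report:
        orientation = {a.scaffold_id: a.orientation for a in anchor_report.scaffolds}

    by_lg: dict[str, list[tuple[str, float, str, int]]] = {}
    for m, (lg, cm) in map_positions.items():
        if m in marker_physical:
            scaf, bp = marker_physical[m]
            by_lg.setdefault(lg, []).append((m, cm, scaf, bp))

    out: dict[str, tuple[float | None, int]] = {}
    for lg in sorted(by_lg):
        rows = by_lg[lg]
        if len(rows) < 2:
            out[lg] = (None, len(rows))
            continue
        scaf_cm: dict[str, list[float]] = {}
        for _, cm, scaf, _ in rows:
            scaf_cm.setdefault(scaf, []).append(cm)
        scaf_rank = {s: float(np.median(c)) for s, c in scaf_cm.items()}
        phys = []
        for m, cm, scaf, bp in rows:
            signed_bp = -bp if orientation.get(scaf) == "-" else bp
            phys.append((scaf_rank[scaf], signed_bp, m))
        cm_vals = [cm for _, cm, _, _ in rows]
        # physical rank: lexicographic (scaffold order, oriented bp)
        order = sorted(range(len(phys)), key=lambda k: phys[k])
        rank = np.empty(len(phys))
        rank[order] = np.arange(len(phys))
        if len(set(cm_vals)) == 1:
            out[lg] = (None, len(rows))
            continue
        r, _ = stats.spearmanr(cm_vals, rank)
        out[lg] = (abs(float(r)), len(rows))
    return out
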