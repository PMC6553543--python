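"""Annotation and naming of poly(A)-clusters.

Each cluster is assigned a category — exonic, intronic, just downstream of
a gene's terminal exon, or intergenic — and a gene, then named under the
convention

    {gene}_{category}_{chrom}:{feature_start_1based}_PAS-{ordinal}

with ordinals running 5'->3' along the transcript within each host
exon/intron, so PAS-1 is always the most promoter-proximal cluster of its
feature.  Intergenic clusters are numbered sequentially genome-wide as
``intergenic_PAS-{k}``.  The naming convention is load-bearing: the
counting stage collapses clusters to exon and gene level by parsing these
names, and the classifier reads ordinal order as proximal/distal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from collections import defaultdict

from .clustering import PolyACluster, read_pac_bed

logger = logging.getLogger(__name__)

CATEGORIES = ("exon", "intron", "downstream", "intergenic")

PAC_NAME_RE = re.compile(
    r"^(?P<gene>.+)_(?P<category>exon|intron|downstream)_"
    r"(?P<chrom>[^:_]+):(?P<coord>\d+)(?:_PAS-(?P<ordinal>\d+))?$"
)
INTERGENIC_NAME_RE = re.compile(r"^intergenic_PAS-(?P<ordinal>\d+)$")


@dataclass
class GenomicFeature:
    """A strand-labelled exon or intron interval with its gene (BED-style, 0-based)."""

    chrom: str
    start: int
    end: int
    gene: str
    strand: str


@dataclass
class AnnotationConfig:
    """``downstream_window``: how far past a terminal exon's 3' end (nt) a
    cluster may sit and still be assigned to that gene (default 250)."""

    downstream_window: int = 250

    def __post_init__(self) -> None:
        if self.downstream_window < 0:
            raise ValueError("downstream_window must be >= 0")


@dataclass
class AnnotatedPAC(PolyACluster):
    """A poly(A)-cluster with category, gene and naming fields attached."""

    category: str = "intergenic"
    gene: str | None = None
    feature_coord: int = 0  # 1-based start of the host exon/intron
    ordinal: int = 0
    name: str = ""


def read_feature_bed(path: str) -> list[GenomicFeature]:
    """Read exon/intron annotation BED (gene name in column 4, strand in 6)."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: feature BED needs 6 columns")
            feats.append(GenomicFeature(f[0], int(f[1]), int(f[2]), f[3], f[5]))
    return feats


def write_feature_bed(feats: list[GenomicFeature], path: str) -> str:
    with open(path, "w") as fh:
        for ft in sorted(feats, key=lambda x: (x.chrom, x.start, x.end)):
            fh.write(f"{ft.chrom}\t{ft.start}\t{ft.end}\t{ft.gene}\t0\t{ft.strand}\n")
    return path


def terminal_exons(exons: list[GenomicFeature]) -> dict[str, GenomicFeature]:
    """The 3'-most exon of each gene: max end on '+', min start on '-'."""
    term: dict[str, GenomicFeature] = {}
    for ex in exons:
        cur = term.get(ex.gene)
        if cur is None:
            term[ex.gene] = ex
        elif ex.strand == "+" and ex.end > cur.end:
            term[ex.gene] = ex
        elif ex.strand == "-" and ex.start < cur.start:
            term[ex.gene] = ex
    return term


def _overlap(pac: PolyACluster, ft: GenomicFeature) -> int:
    if ft.chrom != pac.chrom or ft.strand != pac.strand:
        return 0
    return max(0, min(pac.end, ft.end) - max(pac.start, ft.start))


def _pick(
    pac: PolyACluster,
    feats: list[GenomicFeature],
    terminal: dict[str, GenomicFeature],
) -> GenomicFeature | None:
    """Best overlapping feature: terminal exon first, then longest overlap,
    then lexicographically first gene (determinism)."""
    best, best_key = None, None
    for ft in feats:
        ov = _overlap(pac, ft)
        if ov == 0:
            continue
        is_term = terminal.get(ft.gene) is ft
        key = (0 if is_term else 1, -ov, ft.gene, ft.start)
        if best_key is None or key < best_key:
            best, best_key = ft, key
    return best


def _downstream_host(
    pac: PolyACluster,
    terminal: dict[str, GenomicFeature],
    window: int,
) -> GenomicFeature | None:
    """Terminal exon whose 3' end lies within ``window`` nt upstream of the PAC."""
    best, best_d = None, None
    for ex in terminal.values():
        if ex.chrom != pac.chrom or ex.strand != pac.strand:
            continue
        if pac.strand == "+":
            d = pac.start - ex.end
        else:
            d = ex.start - pac.end
        if 0 <= d <= window and (best_d is None or (d, ex.gene) < (best_d, best.gene)):
            best, best_d = ex, d
    return best


def annotate_pac(
    pac: PolyACluster,
    exons: list[GenomicFeature],
    introns: list[GenomicFeature],
    config: AnnotationConfig | None = None,
    _terminal: dict[str, GenomicFeature] | None = None,
) -> AnnotatedPAC:
    """Assign one cluster its category and gene.

    Category priority is exon > intron > downstream > intergenic; overlap
    requires at least one shared base on the same strand.
    """
    config = config or AnnotationConfig()
    terminal = _terminal if _terminal is not None else terminal_exons(exons)

    host = _pick(pac, exons, terminal)
    category = "exon"
    if host is None:
        host = _pick(pac, introns, {})
        category = "intron"
    if host is None:
        host = _downstream_host(pac, terminal, config.downstream_window)
        category = "downstream"
    if host is None:
        category = "intergenic"

    return AnnotatedPAC(
        chrom=pac.chrom, start=pac.start, end=pac.end, strand=pac.strand,
        members=pac.members, total_count=pac.total_count,
        representative=pac.representative,
        category=category,
        gene=host.gene if host else None,
        feature_coord=host.start + 1 if host else 0,
    )


def annotate_pacs(
    pacs: list[PolyACluster],
    exons: list[GenomicFeature],
    introns: list[GenomicFeature],
    config: AnnotationConfig | None = None,
) -> list[AnnotatedPAC]:
    """Annotate and name a full cluster list (see :func:`name_pacs`)."""
    config = config or AnnotationConfig()
    chroms = {f.chrom for f in exons} | {f.chrom for f in introns}
    if pacs and chroms and not any(p.chrom in chroms for p in pacs):
        logger.warning(
            "no cluster chromosome matches the annotation; genome build mismatch?"
        )
    terminal = terminal_exons(exons)
    out = [annotate_pac(p, exons, introns, config, _terminal=terminal) for p in pacs]
    return name_pacs(out)


def name_pacs(pacs: list[AnnotatedPAC]) -> list[AnnotatedPAC]:
    """Assign ordinals and names; idempotent.

    Within each host feature (gene, category, feature coordinate) ordinals
    run 5'->3' in transcript orientation: ascending genomic start on '+',
    descending on '-'.  Intergenic clusters are numbered genome-wide in
    (chrom, start) order.
    """
    genic: dict[tuple, list[AnnotatedPAC]] = defaultdict(list)
    intergenic: list[AnnotatedPAC] = []
    for p in pacs:
        if p.category == "intergenic":
            intergenic.append(p)
        else:
            genic[(p.gene, p.category, p.chrom, p.feature_coord)].append(p)

    for (gene, cat, chrom, coord), group in genic.items():
        group.sort(key=lambda p: p.start, reverse=(group[0].strand == "-"))
        for i, p in enumerate(group, 1):
            p.ordinal = i
            p.name = f"{gene}_{cat}_{chrom}:{coord}_PAS-{i}"

    intergenic.sort(key=lambda p: (p.chrom, p.start, p.strand))
    for i, p in enumerate(intergenic, 1):
        p.ordinal = i
        p.name = f"intergenic_PAS-{i}"

    seen: set[str] = set()
    for p in pacs:
        if p.name in seen:
            raise RuntimeError(f"duplicate cluster name {p.name!r}: ordinal logic bug")
        seen.add(p.name)
    return pacs


def parse_pac_name(name: str) -> dict:
    """Decompose a cluster/exon-level name into its fields."""
    m = PAC_NAME_RE.match(name)
    if m:
        d = m.groupdict()
        d["coord"] = int(d["coord"])
        d["ordinal"] = int(d["ordinal"]) if d["ordinal"] else None
        return d
    m = INTERGENIC_NAME_RE.match(name)
    if m:
        return {
            "gene": None, "category": "intergenic", "chrom": None,
            "coord": None, "ordinal": int(m.group("ordinal")),
        }
    raise ValueError(f"feature name {name!r} does not follow the naming convention")


def adopt_external_db(
    bed_path: str,
    exons: list[GenomicFeature],
    introns: list[GenomicFeature],
    config: AnnotationConfig | None = None,
) -> list[AnnotatedPAC]:
    """Re-annotate and re-name an externally supplied cluster database.

    Accepts any BED6+ (e.g. a public poly(A)-site database export); clusters
    without thick columns get representative = interval midpoint.  Output is
    sorted and named exactly as de novo clusters, so downstream stages are
    agnostic to the database's origin.
    """
    pacs, _ = read_pac_bed(bed_path)
    pacs.sort(key=lambda p: (p.chrom, p.start, p.strand))
    return annotate_pacs(pacs, exons, introns, config)


def gtf_to_feature_beds(gtf_path: str) -> tuple[list[GenomicFeature], list[GenomicFeature]]:
    """Utility: derive exon and intron feature lists from a GTF.

    Exons are taken from ``exon`` records (gene_name, else gene_id); introns
    are the gaps between a gene's merged exons.
    """
    import gffutils

    db = gffutils.create_db(
        gtf_path, ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    per_gene: dict[tuple[str, str, str], list[tuple[int, int]]] = defaultdict(list)
    for ex in db.features_of_type("exon"):
        gene = ex.attributes.get("gene_name", ex.attributes.get("gene_id", ["?"]))[0]
        per_gene[(gene, ex.seqid, ex.strand)].append((ex.start - 1, ex.end))
    exons, introns = [], []
    for (gene, chrom, strand), ivs in per_gene.items():
        merged: list[list[int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            exons.append(GenomicFeature(chrom, s, e, gene, strand))
        for (_, e1), (s2, _) in zip(merged, merged[1:]):
            if s2 > e1:
                introns.append(GenomicFeature(chrom, e1, s2, gene, strand))
    return exons, introns
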