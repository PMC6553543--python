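"""Merging poly(A)-sites into poly(A)-clusters (PACs).

Cleavage is heterogeneous around a poly(A) signal, so individual sites
within a short genomic window are merged by single-linkage chaining into
a cluster, which downstream stages treat as one feature.  Each cluster
tracks its modal ("representative") site — the member supported by the
most qualified reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .pas import PolyASite


@dataclass
class ClusterConfig:
    """``cluster_window``: maximum gap (nt) between successive sites merged
    into one cluster (default 25)."""

    cluster_window: int = 25

    def __post_init__(self) -> None:
        if self.cluster_window < 0:
            raise ValueError("cluster_window must be >= 0")


@dataclass
class PolyACluster:
    """A genomic interval of merged poly(A)-sites on one strand.

    ``start``/``end`` are 0-based half-open and cover all member sites;
    ``total_count`` sums member qualified reads; ``representative`` is the
    modal member position (ties to the lower coordinate).
    """

    chrom: str
    start: int
    end: int
    strand: str
    members: list[PolyASite] = field(default_factory=list)
    total_count: int = 0
    representative: int = -1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("cluster end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def name_coord(self) -> str:
        """1-based display coordinate of the representative site."""
        return f"{self.chrom}:{self.representative + 1}"


def representative_site(members: list[PolyASite]) -> int:
    """Position of the member with the most qualified reads (ties: lowest coord)."""
    if not members:
        raise ValueError("cluster has no members")
    return min(members, key=lambda s: (-s.qualified_reads, s.position)).position


def cluster_pas(
    pas_list: list[PolyASite], config: ClusterConfig | None = None
) -> list[PolyACluster]:
    """Single-linkage merge of sorted same-chrom/strand sites into clusters.

    Successive sites with a positional gap <= ``cluster_window`` chain into
    one cluster (transitively, so a chain may span more than one window).
    Input must be position-sorted sites of a single chromosome and strand.
    """
    config = config or ClusterConfig()
    if not pas_list:
        return []
    chrom, strand = pas_list[0].chrom, pas_list[0].strand
    prev = None
    for s in pas_list:
        if s.chrom != chrom or s.strand != strand:
            raise ValueError("cluster_pas expects sites of one chromosome and strand")
        if prev is not None and s.position < prev:
            raise ValueError("cluster_pas expects position-sorted input")
        prev = s.position

    clusters: list[PolyACluster] = []
    group: list[PolyASite] = [pas_list[0]]
    for s in pas_list[1:]:
        if s.position - group[-1].position <= config.cluster_window:
            group.append(s)
        else:
            clusters.append(_finish(group))
            group = [s]
    clusters.append(_finish(group))
    return clusters


def _finish(members: list[PolyASite]) -> PolyACluster:
    return PolyACluster(
        chrom=members[0].chrom,
        start=members[0].position,
        end=members[-1].position + 1,
        strand=members[0].strand,
        members=list(members),
        total_count=sum(m.qualified_reads for m in members),
        representative=representative_site(members),
    )


def cluster_all(
    sites: list[PolyASite], config: ClusterConfig | None = None
) -> list[PolyACluster]:
    """Cluster a genome-wide site list, each chromosome and strand independently."""
    from itertools import groupby

    config = config or ClusterConfig()
    out: list[PolyACluster] = []
    key = lambda s: (s.chrom, s.strand)
    for _, grp in groupby(sorted(sites, key=lambda s: (s.chrom, s.strand, s.position)), key):
        out.extend(cluster_pas(list(grp), config))
    out.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return out


# ---------------------------------------------------------------------------
# BED serialization (representative site carried in the thick columns)


def write_pac_bed(pacs: list[PolyACluster], path: str, names: list[str] | None = None) -> str:
    """Write clusters as BED9-style lines.

    thickStart/thickEnd mark the representative (modal) site so genome
    browsers render it as the thicker portion of the cluster; score is the
    total qualified-read count capped at 1000.  Round-trips through
    :func:`read_pac_bed` (member-level detail is not serialized).
    """
    with open(path, "w") as fh:
        for i, pac in enumerate(pacs):
            name = names[i] if names is not None else f"PAC_{i + 1}"
            score = min(pac.total_count, 1000)
            fh.write(
                f"{pac.chrom}\t{pac.start}\t{pac.end}\t{name}\t{score}\t{pac.strand}"
                f"\t{pac.representative}\t{pac.representative + 1}\t{pac.total_count}\n"
            )
    return path


def read_pac_bed(path: str) -> tuple[list[PolyACluster], list[str]]:
    """Parse a cluster BED written by :func:`write_pac_bed` (or any BED6+).

    Column 9, when present, carries the uncapped total count; files without
    thick columns fall back to representative = interval midpoint.
    """
    pacs, names = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: need >= 6 BED columns, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, score, strand = f[3], int(f[4]), f[5]
                rep = int(f[6]) if len(f) > 6 else (start + end - 1) // 2
                total = int(f[8]) if len(f) > 8 else score
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from None
            pacs.append(
                PolyACluster(
                    chrom=chrom, start=start, end=end, strand=strand,
                    members=[], total_count=total, representative=rep,
                )
            )
            names.append(name)
    return pacs, names
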