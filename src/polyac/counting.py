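"""Per-sample quantification of poly(A)-cluster usage.

A read supports a cluster when its 3' end falls inside the cluster span or
within ``count_window`` nt of it on the same strand (10 nt by default,
absorbing residual cleavage heterogeneity).  Each read is assigned to at
most one cluster; equidistant ties go to the upstream (5'-ward) cluster so
tables stay integer and no read is double counted.  Cluster-level tables
are then collapsed to exon/intron level and to gene level by parsing the
cluster naming convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotatedPAC, GenomicFeature, parse_pac_name
from .pas import iter_primary, read_three_prime_end
from .preprocess import parse_tail_length

LEVELS = ("pac", "exon", "gene")


@dataclass
class CountMatrix:
    """An integer features x samples table at pac, exon or gene level."""

    level: str
    data: pd.DataFrame  # index = feature names, columns = sample ids

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        if self.data.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path: str) -> str:
        self.data.to_csv(path, index_label="feature")
        return path

    @classmethod
    def from_csv(cls, path: str, level: str) -> "CountMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(level, df.astype(np.int64))


@dataclass
class CountConfig:
    """Quantification settings.

    count_window
        Maximum distance (nt) between a read 3' end and a cluster span for
        the read to be counted (0 = inside only).
    include_introns
        Collapse intronic clusters into gene counts (off by default because
        intron-resident repeats can inflate gene totals).
    repeat_mask_path
        Optional BED of repetitive/mobile elements; overlapping clusters are
        dropped before collapsing.
    min_tail
        Tail-length floor a read must meet to be counted, mirroring the
        qualified-read criterion of site discovery; ``None`` counts every
        mapped read.
    """

    count_window: int = 10
    include_introns: bool = False
    repeat_mask_path: str | None = None
    min_tail: int | None = 25

    def __post_init__(self) -> None:
        if self.count_window < 0:
            raise ValueError("count_window must be >= 0")


@dataclass
class CountSummary:
    assigned: int = 0
    unassigned: int = 0
    below_tail: int = 0
    skipped: int = 0


class _StrandIndex:
    """Nearest-cluster lookup for one (chrom, strand), on sorted spans."""

    def __init__(self, pacs: list[AnnotatedPAC]):
        order = sorted(range(len(pacs)), key=lambda i: pacs[i].start)
        self.starts = np.array([pacs[i].start for i in order])
        self.ends = np.array([pacs[i].end for i in order])
        self.names = [pacs[i].name for i in order]
        self.strand = pacs[0].strand

    def assign(self, pos: int, window: int) -> str | None:
        i = int(np.searchsorted(self.starts, pos, side="right")) - 1
        # distance to the cluster at/left of pos and the one right of pos
        cand: list[tuple[int, int]] = []  # (distance, index)
        if i >= 0:
            d = 0 if pos < self.ends[i] else pos - (self.ends[i] - 1)
            cand.append((d, i))
        if i + 1 < len(self.starts):
            cand.append((self.starts[i + 1] - pos, i + 1))
        cand = [(d, j) for d, j in cand if d <= window]
        if not cand:
            return None
        dmin = min(d for d, _ in cand)
        tied = [j for d, j in cand if d == dmin]
        # upstream tie-break: 5'-ward cluster wins
        j = min(tied) if self.strand == "+" else max(tied)
        return self.names[j]


def _build_index(pac_db: Sequence[AnnotatedPAC]) -> dict[tuple[str, str], _StrandIndex]:
    if not pac_db:
        raise ValueError("empty poly(A)-cluster database")
    groups: dict[tuple[str, str], list[AnnotatedPAC]] = {}
    for p in pac_db:
        if not p.name:
            raise ValueError("cluster database must be annotated and named first")
        groups.setdefault((p.chrom, p.strand), []).append(p)
    return {k: _StrandIndex(v) for k, v in groups.items()}


def count_sample(
    sam_path: str,
    pac_db: Sequence[AnnotatedPAC],
    config: CountConfig | None = None,
) -> tuple[pd.Series, CountSummary]:
    """Count one sample's reads against a named cluster database.

    Returns an integer Series indexed by every database cluster name (zeros
    kept) plus an assignment summary.
    """
    config = config or CountConfig()
    index = _build_index(pac_db)
    counts = {p.name: 0 for p in pac_db}
    summary = CountSummary()
    for aln in iter_primary(sam_path):
        end = read_three_prime_end(aln)
        if end is None:
            summary.skipped += 1
            continue
        if config.min_tail is not None:
            if parse_tail_length(aln.query_name) < config.min_tail:
                summary.below_tail += 1
                continue
        chrom, pos, strand = end
        idx = index.get((chrom, strand))
        name = idx.assign(pos, config.count_window) if idx else None
        if name is None:
            summary.unassigned += 1
        else:
            counts[name] += 1
            summary.assigned += 1
    names = [p.name for p in pac_db]
    return pd.Series([counts[n] for n in names], index=names, dtype=np.int64), summary


def build_count_matrix(
    sample_sams: dict[str, str],
    pac_db: Sequence[AnnotatedPAC],
    config: CountConfig | None = None,
) -> tuple[CountMatrix, dict[str, CountSummary]]:
    """Cluster-level count table over all samples of a study."""
    config = config or CountConfig()
    cols, summaries = {}, {}
    for sample, path in sample_sams.items():
        cols[sample], summaries[sample] = count_sample(path, pac_db, config)
    return CountMatrix("pac", pd.DataFrame(cols)), summaries


def repeat_overlapping_names(
    pac_db: Sequence[AnnotatedPAC], repeats: Sequence[GenomicFeature]
) -> set[str]:
    """Names of clusters overlapping any repeat interval (strand-agnostic)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    hit = set()
    for p in pac_db:
        for s, e in by_chrom.get(p.chrom, ()):
            if p.start < e and s < p.end:
                hit.add(p.name)
                break
    return hit


def _exon_name(parsed: dict) -> str:
    return f"{parsed['gene']}_{parsed['category']}_{parsed['chrom']}:{parsed['coord']}"


def collapse_counts(
    table: CountMatrix,
    target_level: str,
    config: CountConfig | None = None,
    drop_names: set[str] | None = None,
) -> CountMatrix:
    """Collapse a cluster-level (or exon-level) table to exon or gene level.

    Exon level sums cluster rows sharing a host feature (gene, category,
    feature coordinate); intergenic clusters never collapse and are dropped.
    Gene level sums exonic and downstream-of-terminal-exon rows per gene,
    plus intronic rows when ``include_introns`` is set.  ``drop_names``
    (e.g. from :func:`repeat_overlapping_names`) removes rows before any
    summing.
    """
    config = config or CountConfig()
    if target_level not in ("exon", "gene"):
        raise ValueError("target_level must be 'exon' or 'gene'")
    if table.level == "gene":
        raise ValueError("cannot collapse a gene-level table")
    if table.level == "exon" and target_level == "exon":
        return table

    df = table.data
    if drop_names:
        df = df.loc[[n for n in df.index if n not in drop_names]]

    gene_cats = {"exon", "downstream"} | ({"intron"} if config.include_introns else set())
    keys: list[str | None] = []
    for name in df.index:
        try:
            parsed = parse_pac_name(name)
        except ValueError as exc:
            raise ValueError(f"cannot collapse feature {name!r}: {exc}") from None
        if parsed["category"] == "intergenic":
            keys.append(None)
        elif target_level == "exon":
            keys.append(_exon_name(parsed))
        else:
            keys.append(parsed["gene"] if parsed["category"] in gene_cats else None)

    mask = [k is not None for k in keys]
    sub = df.loc[mask]
    grouped = sub.groupby([k for k in keys if k is not None], sort=True).sum()
    grouped.index.name = None
    return CountMatrix(target_level, grouped.astype(np.int64))
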