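"""Poly(A)-site (PAS) calling from aligned 3'-end reads.

A PAS is the exact genomic nucleotide at the junction between a 3'UTR and
the poly(A) tract, evidenced by the 3' ends of mRNA-sense aligned reads.
Alignments from all samples are pooled, sites are scored by how many
supporting reads carry a poly(A) tract long enough that it cannot derive
solely from the oligo-dT primer ("qualified" reads), and sites that sit
immediately upstream of genomically A-rich sequence are masked as likely
internal-priming artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import defaultdict
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

from .preprocess import parse_tail_length, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class PolyASite:
    """A single putative cleavage/polyadenylation position.

    ``position`` is the 0-based coordinate of the junction base: the
    rightmost aligned base for '+' sites, the leftmost for '-' sites.
    ``qualified_reads`` counts supporting reads whose measured tail length
    met the evidence threshold; ``total_reads`` counts all supporting reads.
    """

    chrom: str
    position: int
    strand: str
    total_reads: int = 0
    qualified_reads: int = 0
    masked: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.qualified_reads > self.total_reads:
            raise ValueError("qualified_reads cannot exceed total_reads")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.position, self.strand)


@dataclass
class PasConfig:
    """Thresholds for site calling and internal-priming masking.

    pas_min_reads
        Minimum number of qualified reads for a site to be emitted.
    pas_min_tail
        Minimum measured tail length (in A's) for a read to qualify; for an
        unanchored 21-nt oligo-dT protocol the default of 25 guarantees the
        tail exceeds what the primer alone could contribute.  Protocols that
        retain only 10-15 tail nucleotides need this lowered.
    ip_window / ip_max_A
        A site is masked when >= ip_max_A A's occur within the ip_window
        genomic nucleotides immediately downstream (transcript sense).
    """

    pas_min_reads: int = 5
    pas_min_tail: int = 25
    ip_window: int = 20
    ip_max_A: int = 12

    def __post_init__(self) -> None:
        if min(self.pas_min_reads, self.pas_min_tail, self.ip_window, self.ip_max_A) < 0:
            raise ValueError("all PasConfig thresholds must be >= 0")


def read_three_prime_end(aln: pysam.AlignedSegment) -> tuple[str, int, str] | None:
    """Genomic coordinate of an alignment's 3' end, in transcript orientation.

    Reads are mRNA-sense after preprocessing, so the alignment strand is the
    transcript strand: forward alignments end at their rightmost aligned
    reference base ('+'), reverse alignments at their leftmost ('-').
    Soft-clipped bases do not consume reference and are excluded by
    construction.  Returns ``None`` for unmapped/secondary/supplementary
    records, which the caller should count as skipped.
    """
    if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
        return None
    if aln.is_reverse:
        return (aln.reference_name, aln.reference_start, "-")
    return (aln.reference_name, aln.reference_end - 1, "+")


def iter_primary(path: str) -> Iterator[pysam.AlignedSegment]:
    """Iterate primary mapped alignments of a SAM/BAM file, first hit per read id."""
    seen: set[str] = set()
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.query_name in seen:
                continue
            seen.add(aln.query_name)
            yield aln


def collect_pas(
    sam_paths: Sequence[str], config: PasConfig | None = None
) -> list[PolyASite]:
    """Pool alignments from all samples and call poly(A)-sites.

    One site per distinct (chrom, position, strand) of a read 3' end; only
    sites supported by at least ``pas_min_reads`` qualified reads (tail
    length >= ``pas_min_tail``) are returned.  Unqualified reads still
    contribute to each site's ``total_reads`` for diagnostics.
    """
    config = config or PasConfig()
    counts: dict[tuple[str, int, str], list[int]] = defaultdict(lambda: [0, 0])
    for path in sam_paths:
        for aln in iter_primary(path):
            end = read_three_prime_end(aln)
            if end is None:
                continue
            tail = parse_tail_length(aln.query_name)
            c = counts[end]
            c[0] += 1
            if tail >= config.pas_min_tail:
                c[1] += 1
    sites = [
        PolyASite(chrom, pos, strand, total_reads=tot, qualified_reads=qual)
        for (chrom, pos, strand), (tot, qual) in counts.items()
        if qual >= config.pas_min_reads
    ]
    sites.sort(key=lambda s: (s.chrom, s.position, s.strand))
    return sites


def site_counts_per_sample(
    sam_path: str, config: PasConfig | None = None
) -> dict[tuple[str, int, str], int]:
    """Qualified-read count per 3'-end site for a single sample (no floor)."""
    config = config or PasConfig()
    counts: dict[tuple[str, int, str], int] = defaultdict(int)
    for aln in iter_primary(sam_path):
        end = read_three_prime_end(aln)
        if end is None:
            continue
        if parse_tail_length(aln.query_name) >= config.pas_min_tail:
            counts[end] += 1
    return dict(counts)


def downstream_window(
    genome, chrom: str, position: int, strand: str, window: int
) -> str:
    """Genomic sequence immediately 3' of a site, in transcript orientation.

    For '+' sites this is the forward-strand sequence just right of the
    junction base; for '-' sites the reverse-complement of the sequence just
    left of it.  Windows running off the chromosome end are truncated.
    ``genome`` is any mapping of chrom -> indexable sequence (pyfaidx.Fasta
    works directly).
    """
    seq = genome[chrom]
    n = len(seq)
    if strand == "+":
        lo, hi = position + 1, min(position + 1 + window, n)
        if hi < position + 1 + window:
            logger.debug("window truncated at end of %s", chrom)
        return str(seq[lo:hi]).upper()
    lo, hi = max(position - window, 0), position
    if lo > position - window:
        logger.debug("window truncated at start of %s", chrom)
    return reverse_complement(str(seq[lo:hi]).upper())


def mask_internal_priming(
    pas: PolyASite, genome, config: PasConfig | None = None
) -> bool:
    """True when the site is likely an internal-priming artifact.

    Oligo-dT can anneal to genomically encoded A-rich stretches rather than
    a real tail; such events leave >= ``ip_max_A`` A's within ``ip_window``
    nucleotides downstream of the called junction.
    """
    config = config or PasConfig()
    win = downstream_window(genome, pas.chrom, pas.position, pas.strand, config.ip_window)
    return win.count("A") >= config.ip_max_A


def apply_internal_priming_mask(
    sites: Iterable[PolyASite], genome, config: PasConfig | None = None
) -> tuple[list[PolyASite], list[PolyASite]]:
    """Split sites into (kept, masked) under the internal-priming rule."""
    config = config or PasConfig()
    kept, masked = [], []
    for s in sites:
        if mask_internal_priming(s, genome, config):
            s.masked = True
            masked.append(s)
        else:
            kept.append(s)
    return kept, masked


# ---------------------------------------------------------------------------
# bedGraph output

_TRACK_FMT = 'track type=bedGraph name="{name}"\n'


def write_pas_bedgraph(
    sites: Iterable[PolyASite],
    out_prefix: str,
    signed_single_file: bool = False,
) -> list[str]:
    """Write poly(A)-sites as bedGraph (value = qualified read count).

    By default two files are written, ``<prefix>.plus.bedgraph`` and
    ``<prefix>.minus.bedgraph``, keeping values non-negative as the bedGraph
    standard expects.  With ``signed_single_file`` a single
    ``<prefix>.pas.bedgraph`` is written with negated values for '-' sites.
    Intervals are 0-based half-open, single-base, sorted.
    """
    sites = sorted(sites, key=lambda s: (s.chrom, s.position, s.strand))
    paths = []
    if signed_single_file:
        path = f"{out_prefix}.pas.bedgraph"
        with open(path, "w") as fh:
            fh.write(_TRACK_FMT.format(name=f"{out_prefix} PAS"))
            for s in sites:
                val = s.qualified_reads if s.strand == "+" else -s.qualified_reads
                fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t{val}\n")
        return [path]
    for strand, label in (("+", "plus"), ("-", "minus")):
        path = f"{out_prefix}.{label}.bedgraph"
        with open(path, "w") as fh:
            fh.write(_TRACK_FMT.format(name=f"{out_prefix} PAS ({strand})"))
            for s in sites:
                if s.strand == strand:
                    fh.write(
                        f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.qualified_reads}\n"
                    )
        paths.append(path)
    return paths


def read_pas_bedgraph(plus_path: str, minus_path: str) -> list[PolyASite]:
    """Parse the two-file bedGraph pair back into poly(A)-sites.

    Inverse of :func:`write_pas_bedgraph` on the qualified-read counts
    (total-read diagnostics are not serialized; ``total_reads`` is set equal
    to ``qualified_reads`` on read-back).
    """
    sites = []
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(path) as fh:
            for line in fh:
                if line.startswith(("track", "#")) or not line.strip():
                    continue
                chrom, start, _end, value = line.split()
                q = abs(int(value))
                sites.append(
                    PolyASite(chrom, int(start), strand, total_reads=q, qualified_reads=q)
                )
    sites.sort(key=lambda s: (s.chrom, s.position, s.strand))
    return sites


def write_coverage_bedgraph(sam_path: str, out_path: str) -> str:
    """Per-base read coverage of one sample as bedGraph (strand-pooled)."""
    import numpy as np

    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        diffs: dict[str, "np.ndarray"] = {
            c: np.zeros(l + 1, dtype=np.int64) for c, l in lengths.items()
        }
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            diffs[aln.reference_name][aln.reference_start] += 1
            diffs[aln.reference_name][aln.reference_end] -= 1
    with open(out_path, "w") as out:
        out.write(_TRACK_FMT.format(name=f"{out_path} coverage"))
        for chrom in sorted(diffs):
            cov = diffs[chrom][:-1].cumsum()
            # emit run-length-compressed intervals of constant nonzero coverage
            if cov.size == 0:
                continue
            change = np.flatnonzero(np.diff(cov)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [cov.size]))
            for s, e in zip(starts, ends):
                v = int(cov[s])
                if v != 0:
                    out.write(f"{chrom}\t{s}\t{e}\t{v}\n")
    return out_path
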