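"""Preprocessing of poly(A)-tail-targeted RNA-seq reads.

Raw reads from 3'-end sequencing protocols span the junction between a
transcript's 3'UTR and its poly(A) tail.  This module orients reads to
mRNA sense (poly(T)-at-5' protocols are reverse-complemented), measures
and removes the 3'-terminal poly(A) tract, filters on tail length, read
length and mean base quality, and records the measured tail length in
the read identifier so that downstream poly(A)-site calling can score
each read's tail evidence after alignment.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field

import pysam

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_SEQ = re.compile(r"^[ACGTNacgtn]*$")
_TAIL_RE = re.compile(r":(\d+)A$")


@dataclass
class RawRead:
    """A FASTQ record: identifier, sequence and per-base quality string."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id!r}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


@dataclass
class TailedRead:
    """A read after tail removal; ``tail_length`` A's were trimmed from the 3' end.

    The tail length is appended to the identifier as ``:<n>A`` so it survives
    a round trip through the SAM QNAME field.
    """

    id: str
    sequence: str
    quality: str
    tail_length: int


@dataclass
class PreprocessConfig:
    """Thresholds for read preprocessing.

    min_tail_in_read
        Minimum number of A's that must be removed from the 3' end for the
        read to be kept; shorter tracts cannot distinguish a genuine tail
        from primer carry-over.
    min_read_len
        Minimum remaining read length after trimming.
    reverse_complement
        Set for protocols that place a poly(T) tract at the read 5' end.
    leading_trim
        Number of bases dropped from the read 5' end (crude adapter/primer
        scar removal).
    min_mean_quality
        Reads with mean Phred quality below this are discarded.
    tail_interruption_every
        Tolerance of the tail scan: one non-A interruption is permitted per
        this many consecutive A's (0 disables interruptions entirely).
    """

    min_tail_in_read: int = 10
    min_read_len: int = 40
    reverse_complement: bool = False
    leading_trim: int = 6
    min_mean_quality: float = 20.0
    tail_interruption_every: int = 10

    def __post_init__(self) -> None:
        for name in ("min_tail_in_read", "min_read_len", "leading_trim",
                     "min_mean_quality", "tail_interruption_every"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PreprocessSummary:
    """Per-run accounting; categories partition the input reads."""

    total: int = 0
    kept: int = 0
    discarded_short_tail: int = 0
    discarded_short_read: int = 0
    discarded_low_quality: int = 0
    discarded_empty: int = 0
    counts: dict = field(default_factory=dict)

    def conserved(self) -> bool:
        return self.total == (
            self.kept
            + self.discarded_short_tail
            + self.discarded_short_read
            + self.discarded_low_quality
            + self.discarded_empty
        )


def reverse_complement(seq: str) -> str:
    if not _VALID_SEQ.match(seq):
        raise ValueError(f"non-IUPAC character in sequence {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def orient_read(read: RawRead, reverse_complement_flag: bool) -> RawRead:
    """Orient a read to mRNA sense.

    With the flag set the sequence is reverse-complemented and the quality
    string reversed, so a 5' poly(T) tract becomes a 3' poly(A) tract.
    Applying the operation twice returns the original read.
    """
    if not reverse_complement_flag:
        if not _VALID_SEQ.match(read.sequence):
            raise ValueError(f"non-IUPAC character in read {read.id!r}")
        return read
    return RawRead(read.id, reverse_complement(read.sequence), read.quality[::-1])


def _tail_span(seq: str, interruption_every: int) -> int:
    """Length of the 3'-terminal poly(A) tract under the tolerance rule.

    Scans from the 3' end consuming A's; a single non-A base may be consumed
    as an interruption provided at least ``interruption_every`` A's have been
    consumed since the previous interruption and the next base toward 5' is
    an A (so an interruption is never the junction-proximal base of the
    tract).  ``interruption_every == 0`` yields the plain maximal A-run.
    """
    n = len(seq)
    i = n - 1
    a_since_break = 0
    while i >= 0:
        base = seq[i]
        if base in "Aa":
            a_since_break += 1
            i -= 1
        elif (
            interruption_every > 0
            and a_since_break >= interruption_every
            and i > 0
            and seq[i - 1] in "Aa"
        ):
            a_since_break = 0
            i -= 1
        else:
            break
    return n - 1 - i


def measure_and_trim_tail(
    read: RawRead, config: PreprocessConfig
) -> TailedRead | None:
    """Remove and measure the 3' poly(A) tract; ``None`` means discard.

    The read must already be in mRNA sense.  Discard reasons (short tail,
    short remaining read, empty input) are distinguished by
    :func:`classify_read`, which this function wraps.
    """
    verdict, tailed = classify_read(read, config)
    return tailed if verdict == "kept" else None


def classify_read(
    read: RawRead, config: PreprocessConfig
) -> tuple[str, TailedRead | None]:
    """Tail-trim one oriented read and report its fate.

    Returns ``(verdict, tailed_read_or_None)`` with verdict one of
    ``kept``, ``short_tail``, ``short_read``, ``empty``.
    """
    if len(read.sequence) == 0:
        logger.warning("empty read %s discarded", read.id)
        return "empty", None
    tail = _tail_span(read.sequence, config.tail_interruption_every)
    if tail < config.min_tail_in_read:
        return "short_tail", None
    remaining = len(read.sequence) - tail
    if remaining < config.min_read_len:
        return "short_read", None
    base_id = read.id.split()[0] if read.id.strip() else read.id
    return "kept", TailedRead(
        id=f"{base_id}:{tail}A",
        sequence=read.sequence[:remaining],
        quality=read.quality[:remaining],
        tail_length=tail,
    )


def parse_tail_length(read_id: str) -> int:
    """Recover the tail length encoded in a processed read identifier."""
    m = _TAIL_RE.search(read_id)
    if m is None:
        raise ValueError(
            f"read id {read_id!r} carries no ':<n>A' tail annotation; "
            "was preprocessing skipped?"
        )
    return int(m.group(1))


def _mean_quality(qual: str) -> float:
    if not qual:
        return 0.0
    return sum(ord(c) - 33 for c in qual) / len(qual)


def _open_out(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def process_fastq(
    in_path: str, out_path: str, config: PreprocessConfig | None = None
) -> PreprocessSummary:
    """Run the full preprocessing pass over a FASTQ file (plain or gzip).

    Per read: orient to mRNA sense, drop ``leading_trim`` 5' bases, discard
    on low mean quality, then measure/trim the poly(A) tail and apply the
    tail- and length filters.  Retained reads are written with their tail
    length appended to the identifier.
    """
    config = config or PreprocessConfig()
    summary = PreprocessSummary()
    with pysam.FastxFile(in_path) as fh, _open_out(out_path) as out:
        for idx, rec in enumerate(fh):
            summary.total += 1
            if rec.quality is None:
                raise ValueError(f"record {idx} ({rec.name}): missing quality string")
            read = RawRead(rec.name, rec.sequence, rec.quality)
            read = orient_read(read, config.reverse_complement)
            t = config.leading_trim
            read = RawRead(read.id, read.sequence[t:], read.quality[t:])
            if len(read.sequence) == 0:
                summary.discarded_empty += 1
                continue
            if _mean_quality(read.quality) < config.min_mean_quality:
                summary.discarded_low_quality += 1
                continue
            verdict, tailed = classify_read(read, config)
            if verdict == "kept":
                summary.kept += 1
                out.write(
                    f"@{tailed.id}\n{tailed.sequence}\n+\n{tailed.quality}\n"
                )
            elif verdict == "short_tail":
                summary.discarded_short_tail += 1
            elif verdict == "short_read":
                summary.discarded_short_read += 1
            else:
                summary.discarded_empty += 1
    summary.counts = {
        "total": summary.total,
        "kept": summary.kept,
        "short_tail": summary.discarded_short_tail,
        "short_read": summary.discarded_short_read,
        "low_quality": summary.discarded_low_quality,
        "empty": summary.discarded_empty,
    }
    return summary
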