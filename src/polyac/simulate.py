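"""Synthetic study generator with known ground truth.

Builds self-contained toy references (genome FASTA, exon/intron BED),
poly(A)-targeted read sets (FASTQ and pre-aligned SAM) and cluster-level
count tables, all seeded and byte-reproducible, so every pipeline stage is
testable without external downloads or an aligner.

Reads are generated at planted poly(A)-sites: each read's 3' end sits
exactly at its site (plus optional jitter), a sampled poly(A) tail is
appended in FASTQ mode, and SAM records are emitted with the tail length
already encoded in the read name, exactly as the preprocessing stage would
leave them.  Decoy sites are planted over genomically A-rich downstream
windows so the internal-priming mask has true positives to find, and true
sites get A-free downstream windows so it has no false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .annotation import GenomicFeature, write_feature_bed
from .counting import CountMatrix
from .differential import DesignSpec
from .preprocess import reverse_complement

# downstream-window fills: zero A (transcript sense) for genuine sites,
# 16 A for internal-priming decoys
_CLEAN_PATTERN = "CGTCGGCTCGGTCGCTGGCC"
_DECOY_PATTERN = "AAAAAAAGCAAAAAAAGCAA"


@dataclass
class PacSpec:
    """A planted poly(A)-site/cluster: junction coordinate and per-condition
    mean read (or count) level per sample."""

    position: int
    means: dict[str, float]
    exon_index: int = -1  # index into the gene's exon list; -1 = terminal exon


@dataclass
class GeneSpec:
    name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, genomic order
    pacs: list[PacSpec]


@dataclass
class SiteSpec:
    """A gene-free planted site: an intergenic cluster or a priming decoy."""

    chrom: str
    position: int
    strand: str
    mean: float


@dataclass
class TruthSpec:
    """Full description of a simulated study.

    The defaults encode the study conditions emulated throughout the test
    suite: two conditions with three replicates each, NB dispersion 0.05,
    50-nt reads with 25-40-A tails, and zero positional jitter so planted
    and discovered sites coincide exactly.
    """

    genes: list[GeneSpec]
    chrom_lengths: dict[str, int]
    intergenic: list[SiteSpec] = field(default_factory=list)
    decoys: list[SiteSpec] = field(default_factory=list)
    conditions: tuple[str, str] = ("control", "knockdown")
    n_replicates: int = 3
    nb_dispersion: float = 0.05
    seed: int = 0
    read_length: int = 50
    tail_min: int = 25
    tail_max: int = 40
    jitter: int = 0

    def __post_init__(self) -> None:
        by_strand: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for g in self.genes:
            span = (g.exons[0][0], g.exons[-1][1])
            for other in by_strand.setdefault((g.chrom, g.strand), []):
                if span[0] < other[1] and other[0] < span[1]:
                    raise ValueError(
                        f"planted genes overlap on {g.chrom}{g.strand}: {span} vs {other}"
                    )
            by_strand[(g.chrom, g.strand)].append(span)

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_{r + 1}"
            for cond in self.conditions
            for r in range(self.n_replicates)
        ]

    def design(self) -> DesignSpec:
        conds = [
            cond for cond in self.conditions for _ in range(self.n_replicates)
        ]
        return DesignSpec(self.sample_ids, conds, reference=self.conditions[0])


@dataclass
class ToyReference:
    genome: dict[str, str]
    exons: list[GenomicFeature]
    introns: list[GenomicFeature]
    truth: pd.DataFrame
    fasta_path: str | None = None
    exon_bed: str | None = None
    intron_bed: str | None = None
    truth_path: str | None = None


def _host_exon(gene: GeneSpec, pac: PacSpec) -> tuple[int, int]:
    if pac.exon_index >= 0:
        return gene.exons[pac.exon_index]
    return gene.exons[-1] if gene.strand == "+" else gene.exons[0]


def expected_names(spec: TruthSpec) -> pd.DataFrame:
    """Ground-truth annotation: the name every planted cluster must receive.

    Replicates the naming convention directly from the planted layout
    (host exon, 5'->3' ordinal by strand) as an independent construction
    against which the de novo annotate-and-name path can be compared.
    """
    rows = []
    for g in self_sorted(spec.genes):
        by_exon: dict[tuple[int, int], list[PacSpec]] = {}
        for pac in g.pacs:
            by_exon.setdefault(_host_exon(g, pac), []).append(pac)
        for exon, pacs in by_exon.items():
            pacs = sorted(pacs, key=lambda p: p.position, reverse=(g.strand == "-"))
            for i, pac in enumerate(pacs, 1):
                rows.append(
                    {
                        "kind": "gene_pac", "gene": g.name, "chrom": g.chrom,
                        "strand": g.strand, "position": pac.position,
                        "category": "exon", "feature_coord": exon[0] + 1,
                        "ordinal": i,
                        "name": f"{g.name}_exon_{g.chrom}:{exon[0] + 1}_PAS-{i}",
                        **{f"mean_{c}": pac.means[c] for c in spec.conditions},
                    }
                )
    for site in spec.intergenic:
        rows.append(
            {
                "kind": "intergenic", "gene": None, "chrom": site.chrom,
                "strand": site.strand, "position": site.position,
                "category": "intergenic", "feature_coord": 0, "ordinal": 0,
                "name": "",
                **{f"mean_{c}": site.mean for c in spec.conditions},
            }
        )
    for site in spec.decoys:
        rows.append(
            {
                "kind": "decoy", "gene": None, "chrom": site.chrom,
                "strand": site.strand, "position": site.position,
                "category": "masked", "feature_coord": 0, "ordinal": 0,
                "name": "",
                **{f"mean_{c}": site.mean for c in spec.conditions},
            }
        )
    return pd.DataFrame(rows)


def self_sorted(genes: list[GeneSpec]) -> list[GeneSpec]:
    return sorted(genes, key=lambda g: (g.chrom, g.exons[0][0]))


def _plant_window(seq: bytearray, pos: int, strand: str, pattern: str) -> None:
    """Overwrite the 20-nt transcript-sense downstream window of a site."""
    if strand == "+":
        lo = pos + 1
        seq[lo:lo + len(pattern)] = pattern.encode()
    else:
        rc = reverse_complement(pattern).encode()
        lo = max(pos - len(pattern), 0)
        seq[lo:pos] = rc[len(rc) - (pos - lo):]


def make_toy_reference(spec: TruthSpec, outdir: str | None = None) -> ToyReference:
    """Build the toy genome, annotation features and truth table.

    The genome is uniform random sequence with every planted site's
    downstream window overwritten: A-free for genuine sites, >= 12 A's for
    decoys.  With ``outdir`` given, FASTA / exon BED / intron BED / truth
    CSV files are also written (byte-identical for a fixed seed).
    """
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, bytearray] = {
        c: bytearray(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n).tobytes())
        for c, n in spec.chrom_lengths.items()
    }
    for g in spec.genes:
        for pac in g.pacs:
            _plant_window(genome[g.chrom], pac.position, g.strand, _CLEAN_PATTERN)
    for site in spec.intergenic:
        _plant_window(genome[site.chrom], site.position, site.strand, _CLEAN_PATTERN)
    for site in spec.decoys:
        _plant_window(genome[site.chrom], site.position, site.strand, _DECOY_PATTERN)

    exons, introns = [], []
    for g in spec.genes:
        for s, e in g.exons:
            exons.append(GenomicFeature(g.chrom, s, e, g.name, g.strand))
        for (_, e1), (s2, _) in zip(g.exons, g.exons[1:]):
            introns.append(GenomicFeature(g.chrom, e1, s2, g.name, g.strand))

    ref = ToyReference(
        genome={c: s.decode() for c, s in genome.items()},
        exons=exons,
        introns=introns,
        truth=expected_names(spec),
    )
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        ref.fasta_path = os.path.join(outdir, "genome.fa")
        with open(ref.fasta_path, "w") as fh:
            for chrom in sorted(ref.genome):
                fh.write(f">{chrom}\n")
                s = ref.genome[chrom]
                for i in range(0, len(s), 60):
                    fh.write(s[i:i + 60] + "\n")
        ref.exon_bed = write_feature_bed(exons, os.path.join(outdir, "exons.bed"))
        ref.intron_bed = write_feature_bed(introns, os.path.join(outdir, "introns.bed"))
        ref.truth_path = os.path.join(outdir, "truth.csv")
        ref.truth.to_csv(ref.truth_path, index=False)
    return ref


# ---------------------------------------------------------------------------
# read simulation


def _nb_draw(rng: np.random.Generator, mean: float, disp: float) -> int:
    if mean <= 0:
        return 0
    if disp <= 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=1.0 / disp, scale=mean * disp)
    return int(rng.poisson(lam))


@dataclass
class SimulatedReads:
    sam_paths: dict[str, str]
    fastq_paths: dict[str, str]
    metadata_path: str
    truth: pd.DataFrame
    counts_true: pd.DataFrame  # planted reads per (site, sample)


def simulate_reads(
    spec: TruthSpec,
    reference: ToyReference,
    outdir: str,
    polyT_mode: bool = False,
    write_fastq: bool = True,
) -> SimulatedReads:
    """Emit per-sample FASTQ and coordinate-sorted SAM for a toy study.

    Per sample and planted site, the read number is NB(mean, dispersion);
    each read's 3' end sits at the site position (plus jitter), its body is
    the ``read_length`` transcript-sense nucleotides ending there, and a
    sampled tail of ``tail_min``..``tail_max`` A's is appended in FASTQ
    output.  SAM records carry the tail in the QNAME (``:<n>A``) as the
    preprocessing stage would produce.  ``polyT_mode`` emits FASTQ reads
    reverse-complemented (5' poly(T)), emulating protocols that need the
    orientation flip during preprocessing.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)
    genome = reference.genome
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": c, "LN": len(genome[c])} for c in sorted(genome)
            ],
        }
    )
    tids = {c: i for i, c in enumerate(sorted(genome))}

    sites: list[tuple[str, int, str, dict[str, float], str]] = []
    for g in spec.genes:
        for pac in g.pacs:
            sites.append((g.chrom, pac.position, g.strand, pac.means, "gene_pac"))
    for s in spec.intergenic:
        sites.append((s.chrom, s.position, s.strand,
                      {c: s.mean for c in spec.conditions}, "intergenic"))
    for s in spec.decoys:
        sites.append((s.chrom, s.position, s.strand,
                      {c: s.mean for c in spec.conditions}, "decoy"))

    sam_paths, fastq_paths = {}, {}
    counts_rows = []
    meta_rows = []
    L = spec.read_length
    for cond in spec.conditions:
        for rep in range(spec.n_replicates):
            sample = f"{cond}_{rep + 1}"
            records = []
            serial = 0
            for si, (chrom, pos, strand, means, kind) in enumerate(sites):
                n = _nb_draw(rng, means[cond], spec.nb_dispersion)
                counts_rows.append({"site_index": si, "sample": sample, "reads": n})
                for _ in range(n):
                    serial += 1
                    end = pos
                    if spec.jitter:
                        end += int(rng.integers(-spec.jitter, spec.jitter + 1))
                    tail = int(rng.integers(spec.tail_min, spec.tail_max + 1))
                    if strand == "+":
                        lo, hi = end - L + 1, end + 1
                        body = genome[chrom][max(lo, 0):hi]
                    else:
                        lo, hi = end, end + L
                        body = reverse_complement(genome[chrom][lo:min(hi, len(genome[chrom]))])
                    qname = f"{sample}_{serial}:{tail}A"
                    records.append((chrom, strand, end, body, tail, qname))

            sam = os.path.join(outdir, f"{sample}.sam")
            records.sort(key=lambda r: (tids[r[0]], r[2]))
            with pysam.AlignmentFile(sam, "w", header=header) as out:
                for chrom, strand, end, body, tail, qname in records:
                    a = pysam.AlignedSegment(header)
                    a.query_name = qname
                    a.flag = 0 if strand == "+" else 16
                    a.reference_id = tids[chrom]
                    a.reference_start = end - len(body) + 1 if strand == "+" else end
                    a.mapping_quality = 60
                    a.cigarstring = f"{len(body)}M"
                    a.query_sequence = body if strand == "+" else reverse_complement(body)
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(body))
                    out.write(a)
            sam_paths[sample] = sam

            if write_fastq:
                fq = os.path.join(outdir, f"{sample}.fastq")
                with open(fq, "w") as out:
                    for chrom, strand, end, body, tail, qname in records:
                        base = qname.rsplit(":", 1)[0]
                        seq = body + "A" * tail
                        if polyT_mode:
                            seq = reverse_complement(seq)
                        out.write(f"@{base}\n{seq}\n+\n{'I' * len(seq)}\n")
                fastq_paths[sample] = fq
            meta_rows.append((sample, sam, cond))

    metadata_path = os.path.join(outdir, "metadata.tsv")
    with open(metadata_path, "w") as fh:
        fh.write("sample\tpath\tcondition\n")
        for sample, path, cond in meta_rows:
            fh.write(f"{sample}\t{path}\t{cond}\n")
    return SimulatedReads(
        sam_paths=sam_paths,
        fastq_paths=fastq_paths,
        metadata_path=metadata_path,
        truth=reference.truth,
        counts_true=pd.DataFrame(counts_rows),
    )


# ---------------------------------------------------------------------------
# direct count-table simulation (bypasses reads)


def simulate_count_tables(
    spec: TruthSpec, mirror: bool = False
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB cluster-level counts drawn directly from planted means.

    Returns the cluster-level count matrix (named per the convention) plus
    a truth table.  ``mirror`` flips every gene's strand *after* drawing,
    so ordinals (proximal/distal roles) reverse while the counts stay
    byte-identical — a strand-symmetry fixture for the classifier.
    """
    rng = np.random.default_rng(spec.seed + 2)
    data: dict[str, list[int]] = {}
    rows = []
    samples = spec.sample_ids
    draw_order = []  # (gene, pac) in stable order, independent of mirror
    for g in self_sorted(spec.genes):
        for pac in g.pacs:
            draw_order.append((g, pac))
    counts: dict[int, list[int]] = {}
    for i, (g, pac) in enumerate(draw_order):
        vals = []
        for cond in spec.conditions:
            for _ in range(spec.n_replicates):
                vals.append(_nb_draw(rng, pac.means[cond], spec.nb_dispersion))
        counts[i] = vals

    names = {}
    by_gene: dict[str, list[tuple[int, PacSpec, GeneSpec]]] = {}
    for i, (g, pac) in enumerate(draw_order):
        by_gene.setdefault(g.name, []).append((i, pac, g))
    for gname, items in by_gene.items():
        g = items[0][2]
        strand = {"+": "-", "-": "+"}[g.strand] if mirror else g.strand
        by_exon: dict[tuple[int, int], list[tuple[int, PacSpec]]] = {}
        for i, pac, _ in items:
            by_exon.setdefault(_host_exon(g, pac), []).append((i, pac))
        for exon, pacs in by_exon.items():
            pacs = sorted(pacs, key=lambda t: t[1].position, reverse=(strand == "-"))
            for k, (i, pac) in enumerate(pacs, 1):
                names[i] = f"{gname}_exon_{g.chrom}:{exon[0] + 1}_PAS-{k}"
                rows.append(
                    {
                        "gene": gname, "name": names[i], "strand": strand,
                        "ordinal": k, "position": pac.position,
                        **{f"mean_{c}": pac.means[c] for c in spec.conditions},
                    }
                )

    table = pd.DataFrame(
        {s: [counts[i][j] for i in sorted(names)] for j, s in enumerate(samples)},
        index=[names[i] for i in sorted(names)],
    )
    return CountMatrix("pac", table.astype(np.int64)), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ready-made study specs


def toy_spec(seed: int = 0, jitter: int = 0) -> TruthSpec:
    """A small hand-laid study: seven genes over two chromosomes and both
    strands, one gene with two same-exon clusters undergoing a usage swap,
    one multi-exon gene, decoy and intergenic sites.  Means are tens of
    reads per sample so every planted site clears the discovery floor."""
    A, B = "chrA", "chrB"
    genes = [
        GeneSpec("alpha", A, "+", [(1000, 1600), (2000, 3000)], [
            PacSpec(2500, {"control": 60.0, "knockdown": 60.0}),
            PacSpec(2800, {"control": 40.0, "knockdown": 40.0}),
        ]),
        GeneSpec("beta", A, "-", [(5000, 6200)], [
            PacSpec(5200, {"control": 50.0, "knockdown": 120.0}),
        ]),
        GeneSpec("gamma", A, "+", [(8000, 9500)], [
            PacSpec(8700, {"control": 70.0, "knockdown": 20.0}),
            PacSpec(9200, {"control": 30.0, "knockdown": 80.0}),
        ]),
        GeneSpec("delta", B, "+", [(1500, 2500), (3000, 4200)], [
            PacSpec(3700, {"control": 45.0, "knockdown": 45.0}),
        ]),
        GeneSpec("epsilon", B, "-", [(6000, 7500)], [
            PacSpec(6400, {"control": 55.0, "knockdown": 55.0}),
            PacSpec(6900, {"control": 35.0, "knockdown": 35.0}),
        ]),
        GeneSpec("zeta", B, "+", [(9000, 10500)], [
            PacSpec(10000, {"control": 65.0, "knockdown": 65.0}),
        ]),
        GeneSpec("eta", A, "+", [(12000, 13000)], [
            PacSpec(12800, {"control": 50.0, "knockdown": 50.0}),
        ]),
    ]
    return TruthSpec(
        genes=genes,
        chrom_lengths={A: 20000, B: 15000},
        intergenic=[
            SiteSpec(A, 16000, "+", 40.0),
            SiteSpec(B, 12500, "-", 35.0),
        ],
        decoys=[
            SiteSpec(A, 18000, "+", 30.0),
            SiteSpec(B, 13500, "-", 25.0),
            SiteSpec(A, 19000, "-", 20.0),
        ],
        seed=seed,
        jitter=jitter,
    )


def classifier_spec(
    seed: int = 0,
    n_genes: int = 200,
    shift: float = 0.40,
    gene_mean: float = 400.0,
    nb_dispersion: float = 0.05,
) -> tuple[TruthSpec, pd.DataFrame]:
    """The 200-gene classifier-recovery study.

    Composition: 20 genes with programmed 3'UTR shortening (proximal
    cluster occupancy up by ``shift``), 10 lengthening, 10 terminal-exon
    switches, 10 four-fold whole-gene expression changes with constant
    occupancy, and 150 genes with no effect — a sparse-effect regime, as
    in real knockdown studies where only a minority of genes shift their
    poly(A)-site usage.  Gene totals are lognormal around ``gene_mean``.
    Returns the spec plus a per-gene truth label table.
    """
    rng = np.random.default_rng(seed)
    n_short, n_long, n_te, n_dge = 20, 10, 10, 10
    labels = (
        ["shortening"] * n_short + ["lengthening"] * n_long
        + ["te"] * n_te + ["dge"] * n_dge
    )
    labels += ["null"] * (n_genes - len(labels))

    genes, rows = [], []
    gap = 5000
    for i, label in enumerate(labels):
        name = f"g{i:03d}"
        strand = "+" if i % 2 == 0 else "-"
        start = 1000 + i * gap
        total = float(np.exp(rng.normal(np.log(gene_mean), 0.4)))
        occ = (0.5 - shift / 2, 0.5 + shift / 2)
        if label == "shortening":
            occ_ref, occ_alt = (occ[0], occ[1]), (occ[1], occ[0])
        elif label in ("lengthening",):
            occ_ref, occ_alt = (occ[1], occ[0]), (occ[0], occ[1])
        elif label == "te":
            occ_ref, occ_alt = (occ[0], occ[1]), (occ[1], occ[0])
        else:
            occ_ref, occ_alt = (0.5, 0.5), (0.5, 0.5)
        scale_alt = 4.0 if label == "dge" else 1.0
        # two clusters; genomic order low->high, proximal = 5'-most by strand
        p_low, p_high = start + 600, start + 900
        if strand == "+":
            prox_pos, dist_pos = p_low, p_high
        else:
            prox_pos, dist_pos = p_high, p_low
        if label == "te":
            exons = [(start, start + 1000), (start + 2000, start + 3000)]
            prox_pos = start + 800 if strand == "+" else start + 2200
            dist_pos = start + 2800 if strand == "+" else start + 200
            prox_exon = 0 if strand == "+" else 1
            dist_exon = 1 if strand == "+" else 0
        else:
            exons = [(start, start + 1200)]
            prox_exon = dist_exon = 0
        pacs = [
            PacSpec(prox_pos,
                    {"control": total * occ_ref[0],
                     "knockdown": total * occ_alt[0] * scale_alt},
                    exon_index=prox_exon),
            PacSpec(dist_pos,
                    {"control": total * occ_ref[1],
                     "knockdown": total * occ_alt[1] * scale_alt},
                    exon_index=dist_exon),
        ]
        genes.append(GeneSpec(name, "chrS", strand, exons, pacs))
        rows.append({"gene": name, "label": label, "strand": strand, "total": total})

    spec = TruthSpec(
        genes=genes,
        chrom_lengths={"chrS": 1000 + n_genes * gap + 5000},
        nb_dispersion=nb_dispersion,
        seed=seed,
    )
    return spec, pd.DataFrame(rows).set_index("gene")
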