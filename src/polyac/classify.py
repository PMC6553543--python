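"""Per-gene verdicts: differential expression, terminal-exon switching, APA.

The three differential tables (gene, exon, cluster level) are combined
into one call per gene:

* **DGE** — UP/DOWN when the gene-level fold change exceeds the threshold
  at the padj cutoff, else NC.
* **TE** — terminal-exon switching: a significantly shifted cluster whose
  gene carries eligible clusters in more than one exon/intron.
* **APA** — a shift between clusters of one exon, read directionally:
  usage moving to the promoter-proximal cluster shortens the 3'UTR, to the
  distal cluster lengthens it; a falling middle cluster that feeds both
  flanks is called "both".

Eligibility and shift size are expressed as *occupancy* — a cluster's
share of its gene's normalized signal within one condition — so the calls
are insensitive to overall gene-level changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import parse_pac_name
from .counting import CountMatrix
from .differential import DesignSpec, size_factors


@dataclass
class ClassifyConfig:
    """Decision thresholds.

    fc_thresh
        Gene-level fold change (linear scale, > 1) for UP/DOWN.
    padj_thresh
        FDR cutoff applied at gene level (DGE) and cluster level (APA/TE).
    min_occupancy
        A cluster must hold at least this fraction of its gene's signal in
        one condition to participate in APA/TE logic.
    min_frac_change
        Minimum absolute occupancy change, in fractions (0.10 = ten
        percentage points), for a significant cluster to trigger a call.
    include_introns
        Carry intronic clusters into the report and the APA/TE logic.
    """

    fc_thresh: float = 1.5
    padj_thresh: float = 0.1
    min_occupancy: float = 0.05
    min_frac_change: float = 0.10
    include_introns: bool = False

    def __post_init__(self) -> None:
        if self.fc_thresh <= 1:
            raise ValueError("fc_thresh must exceed 1")
        for name in ("padj_thresh", "min_occupancy", "min_frac_change"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class GeneCall:
    gene: str
    dge: str = "NC"               # UP / DOWN / NC
    te: str = "none"              # TE / none
    apa: str = "none"             # APA_shortening / APA_lengthening / APA_both / none
    pac_rows: pd.DataFrame = field(default_factory=pd.DataFrame)


def occupancy(
    pac_counts: CountMatrix,
    design: DesignSpec,
    sf: pd.Series | None = None,
    config: ClassifyConfig | None = None,
) -> pd.DataFrame:
    """Per-cluster occupancies per condition, with eligibility.

    Occupancy of cluster p in condition c = its mean normalized count over
    the samples of c divided by the gene's total over its clusters in c.
    A cluster is *eligible* when its occupancy reaches ``min_occupancy`` in
    at least one condition; a gene silent in one condition gets NA
    occupancies there and eligibility is judged on the other condition.
    Intergenic clusters carry no gene and are excluded.
    """
    config = config or ClassifyConfig()
    if sf is None:
        sf = size_factors(pac_counts)
    df = pac_counts.data
    norm = df / sf.loc[df.columns]
    ref, alt = design.masks()
    mean_ref = norm.loc[:, np.asarray(ref)].mean(axis=1)
    mean_alt = norm.loc[:, np.asarray(alt)].mean(axis=1)

    meta = []
    for name in df.index:
        parsed = parse_pac_name(name)
        meta.append(
            (name, parsed["gene"], parsed["category"], parsed["chrom"],
             parsed["coord"], parsed["ordinal"])
        )
    out = pd.DataFrame(
        meta, columns=["name", "gene", "category", "chrom", "coord", "ordinal"]
    ).set_index("name")
    out["mean_ref"] = mean_ref
    out["mean_alt"] = mean_alt

    genic = out[out["gene"].notna()]
    tot_ref = genic.groupby("gene")["mean_ref"].transform("sum")
    tot_alt = genic.groupby("gene")["mean_alt"].transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        occ_ref = np.where(tot_ref > 0, genic["mean_ref"] / tot_ref, np.nan)
        occ_alt = np.where(tot_alt > 0, genic["mean_alt"] / tot_alt, np.nan)
    out = out.loc[genic.index].copy()
    out["occ_ref"] = occ_ref
    out["occ_alt"] = occ_alt
    out["delta_occ"] = out["occ_alt"] - out["occ_ref"]
    out["eligible"] = (
        (out["occ_ref"].fillna(-1) >= config.min_occupancy)
        | (out["occ_alt"].fillna(-1) >= config.min_occupancy)
    )
    return out


def call_dge(log2fc: float, padj: float, config: ClassifyConfig | None = None) -> str:
    """UP/DOWN/NC verdict from a gene-level test row (NA padj -> NC)."""
    config = config or ClassifyConfig()
    if padj is None or (isinstance(padj, float) and math.isnan(padj)):
        return "NC"
    if log2fc is None or (isinstance(log2fc, float) and math.isnan(log2fc)):
        return "NC"
    lfc_cut = math.log2(config.fc_thresh)
    if padj < config.padj_thresh:
        if log2fc > lfc_cut:
            return "UP"
        if log2fc < -lfc_cut:
            return "DOWN"
    return "NC"


def call_apa_te(
    gene_pacs: pd.DataFrame, config: ClassifyConfig | None = None
) -> tuple[str, str]:
    """TE and APA verdicts for one gene.

    ``gene_pacs`` holds the gene's clusters with occupancy columns (from
    :func:`occupancy`) plus cluster-level ``padj``.  A *triggering* cluster
    is eligible, significant (padj below threshold) and shifts occupancy by
    at least ``min_frac_change``.  A triggering cluster paired with an
    eligible cluster in a different exon/intron gives TE; within one exon,
    the direction comes from ordinal (5'->3') position:

    * proximal cluster gaining usage -> shortening; losing -> lengthening;
    * distal cluster mirrored;
    * a triggering middle cluster with opposite-signed shifts on at least
      one flank on each side -> both.

    TE and APA can co-occur.  Both verdicts require at least two eligible
    clusters (in >= 2 features for TE, within one feature for APA).
    """
    config = config or ClassifyConfig()
    if "ordinal" not in gene_pacs.columns or gene_pacs["ordinal"].isna().any():
        raise ValueError("cluster ordinals missing; annotate and name clusters first")

    elig = gene_pacs[gene_pacs["eligible"]].copy()
    if len(elig) < 2:
        return "none", "none"
    trig = (
        (elig["padj"] < config.padj_thresh)
        & (elig["delta_occ"].abs() >= config.min_frac_change)
    ).fillna(False)

    feat_key = list(zip(elig["category"], elig["chrom"], elig["coord"]))
    elig["_feat"] = pd.Series(feat_key, index=elig.index).astype(str)

    te = "none"
    if trig.any() and elig["_feat"].nunique() >= 2:
        te = "TE"

    votes: set[str] = set()
    for feat, grp in elig.groupby("_feat"):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("ordinal")
        dv = grp["delta_occ"].to_numpy()
        tv = trig.loc[grp.index].to_numpy()
        for k in range(len(grp)):
            if not tv[k]:
                continue
            d = dv[k]
            if not np.isfinite(d):
                continue
            if k == 0:  # proximal
                votes.add("shortening" if d > 0 else "lengthening")
            elif k == len(grp) - 1:  # distal
                votes.add("lengthening" if d > 0 else "shortening")
            else:  # middle cluster
                up_opp = np.any(np.sign(dv[:k]) == -np.sign(d))
                dn_opp = np.any(np.sign(dv[k + 1:]) == -np.sign(d))
                if up_opp and dn_opp:
                    votes.add("both")
                elif up_opp:
                    # behaves as the distal member of the shifted pair
                    votes.add("lengthening" if d > 0 else "shortening")
                elif dn_opp:
                    votes.add("shortening" if d > 0 else "lengthening")

    if "both" in votes or {"shortening", "lengthening"} <= votes:
        apa = "APA_both"
    elif "shortening" in votes:
        apa = "APA_shortening"
    elif "lengthening" in votes:
        apa = "APA_lengthening"
    else:
        apa = "none"
    return te, apa


def classify_genes(
    gene_results: pd.DataFrame,
    pac_results: pd.DataFrame,
    occ: pd.DataFrame,
    config: ClassifyConfig | None = None,
) -> list[GeneCall]:
    """Assemble one :class:`GeneCall` per tested gene, sorted by name."""
    config = config or ClassifyConfig()
    occ = occ.join(pac_results[["log2fc", "padj"]], how="left")
    if not config.include_introns:
        occ = occ[occ["category"] != "intron"]

    pac_genes = set(occ["gene"].dropna())
    missing = pac_genes - set(gene_results.index)
    if missing:
        raise ValueError(
            f"genes present at cluster level but absent from the gene table: "
            f"{sorted(missing)[:5]}"
        )

    calls = []
    for gene in sorted(gene_results.index):
        row = gene_results.loc[gene]
        dge = call_dge(row.get("log2fc"), row.get("padj"), config)
        sub = occ[occ["gene"] == gene].sort_values(["category", "coord", "ordinal"])
        te, apa = ("none", "none")
        if len(sub[sub["eligible"]]) >= 2:
            te, apa = call_apa_te(sub, config)
        calls.append(GeneCall(gene=gene, dge=dge, te=te, apa=apa, pac_rows=sub))
    return calls


REPORT_COLUMNS = [
    "gene", "row_type", "dge", "te", "apa", "feature",
    "base_mean", "log2fc", "padj", "occ_ref", "occ_alt", "delta_occ",
]


def compile_report(
    gene_results: pd.DataFrame,
    exon_results: pd.DataFrame,
    pac_results: pd.DataFrame,
    calls: list[GeneCall],
    config: ClassifyConfig | None = None,
) -> pd.DataFrame:
    """The final compiled per-gene table.

    One gene row per tested gene carrying the DGE/TE/APA verdicts and the
    gene-level statistics; genes with more than one cluster additionally
    get one sub-row per cluster with occupancies, occupancy change and the
    cluster-level test.  Row order is deterministic: gene name, then
    cluster ordinal within feature.  Single-cluster genes return only
    their gene row.
    """
    config = config or ClassifyConfig()
    rows = []
    for call in calls:
        g = gene_results.loc[call.gene]
        rows.append(
            {
                "gene": call.gene, "row_type": "gene", "dge": call.dge,
                "te": call.te, "apa": call.apa, "feature": call.gene,
                "base_mean": g.get("base_mean"), "log2fc": g.get("log2fc"),
                "padj": g.get("padj"),
                "occ_ref": np.nan, "occ_alt": np.nan, "delta_occ": np.nan,
            }
        )
        if len(call.pac_rows) > 1:
            for name, p in call.pac_rows.iterrows():
                rows.append(
                    {
                        "gene": call.gene, "row_type": "pac", "dge": "",
                        "te": "", "apa": "", "feature": name,
                        "base_mean": np.nan, "log2fc": p.get("log2fc"),
                        "padj": p.get("padj"), "occ_ref": p["occ_ref"],
                        "occ_alt": p["occ_alt"], "delta_occ": p["delta_occ"],
                    }
                )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
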