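"""Single-marker GWAS with genomic-control inflation adjustment.

The scan regresses BLUP-adjusted progeny phenotypes on each marker's
{0,1,2} code; the squared t statistic is treated as a 1-df chi-square,
the vector of statistics is deflated by the genomic-control factor
lambda = median(chi2) / 0.4549 (floored at 1), and markers reaching an
association score -log10(p_adj) >= 3.0 (P < 0.001) are declared
significant.  Significant markers are classified by gene context from a
GFF3 annotation: C (exonic), I (intronic/within the gene span), F
(strictly within 3000 bp of the gene span) or 0 (intergenic).  Markers
without a chromosome assignment are placed on a fictitious trailing
pseudo-chromosome for Manhattan plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import MISSING, DiploidCodedMatrix

ASSOCIATION_THRESHOLD = 3.0  # -log10(p) corresponding to P < 0.001
FLANK_BP = 3000
#: median of the 1-df chi-square distribution, the genomic-control denominator
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class GeneAnnotation:
    """Gene and exon spans on 1-based inclusive coordinates."""

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end
    exons: pd.DataFrame  # columns: gene_id, chrom, start, end

    def __post_init__(self) -> None:
        for frame, kind in ((self.genes, "gene"), (self.exons, "exon")):
            if len(frame) and (frame["start"] > frame["end"]).any():
                raise ValueError(f"malformed {kind} span: start > end")
        if len(self.exons):
            spans = self.genes.set_index("gene_id")
            for _, ex in self.exons.iterrows():
                g = spans.loc[ex["gene_id"]]
                if ex["start"] < g["start"] or ex["end"] > g["end"]:
                    raise ValueError(f"exon outside gene span for {ex['gene_id']}")


def load_gff3(path) -> GeneAnnotation:
    """Read gene and exon features from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes, exons = [], []
    for g in db.features_of_type("gene"):
        genes.append({"gene_id": g.id, "chrom": g.seqid, "start": g.start, "end": g.end})
    for e in db.features_of_type("exon"):
        parents = [p.id for p in db.parents(e, featuretype="gene")]
        if not parents:  # exon -> mRNA -> gene chains resolved transitively
            parents = [e.attributes.get("Parent", ["?"])[0]]
        exons.append(
            {"gene_id": parents[0], "chrom": e.seqid, "start": e.start, "end": e.end}
        )
    return GeneAnnotation(pd.DataFrame(genes), pd.DataFrame(exons))


def marker_scan(g: DiploidCodedMatrix | np.ndarray, y) -> pd.DataFrame:
    """Per-marker simple linear regression of phenotype on genotype code.

    Returns a frame with columns (marker, effect, chi2, p_raw, r2,
    monomorphic).  Monomorphic markers are flagged and excluded from
    p-value computation.  Genotypes must be complete (run after
    imputation).
    """
    if isinstance(g, DiploidCodedMatrix):
        codes = g.codes
        marker_ids = list(g.marker_ids)
        if (codes == MISSING).any():
            raise ValueError("genotype matrix contains MISSING codes; impute first")
    else:
        codes = np.asarray(g)
        marker_ids = [f"M{j + 1:05d}" for j in range(codes.shape[1])]
    y = np.asarray(y, dtype=float)
    n = codes.shape[0]
    if y.shape[0] != n:
        raise ValueError(f"{y.shape[0]} phenotypes for {n} samples")
    if n < 3:
        raise ValueError("need >= 3 samples")

    X = codes.astype(float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ssx = (Xc**2).sum(axis=0)
    ssy = float((yc**2).sum())
    mono = ssx == 0.0
    sxy = Xc.T @ yc

    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sxy / ssx
        r2 = np.where(ssy > 0, sxy**2 / (ssx * ssy), np.nan)
        r2 = np.clip(r2, 0.0, 1.0)
        t2 = r2 * (n - 2) / np.maximum(1.0 - r2, np.finfo(float).tiny)
    chi2 = t2  # squared t with n-2 df treated as 1-df chi-square
    p_raw = stats.chi2.sf(chi2, df=1)
    beta[mono] = np.nan
    chi2 = np.where(mono, np.nan, chi2)
    p_raw = np.where(mono, np.nan, p_raw)
    return pd.DataFrame(
        {
            "marker": marker_ids,
            "effect": beta,
            "chi2": chi2,
            "p_raw": p_raw,
            "r2": np.where(mono, np.nan, r2),
            "monomorphic": mono,
        }
    )


def genomic_control(statistics: np.ndarray) -> tuple[float, np.ndarray]:
    """Genomic-control adjustment of 1-df chi-square statistics.

    lambda = median(chi2)/0.4549, floored at 1 so deflation never
    inflates significance; returns (lambda, adjusted p-values).  NaN
    statistics (monomorphic markers) propagate as NaN.
    """
    statistics = np.asarray(statistics, dtype=float)
    valid = np.isfinite(statistics)
    if valid.sum() == 0:
        raise ValueError("no finite statistics to adjust")
    lam = float(np.median(statistics[valid]) / CHI2_1DF_MEDIAN)
    lam = max(lam, 1.0)
    adjusted = statistics / lam
    p_adj = np.where(valid, stats.chi2.sf(adjusted, df=1), np.nan)
    return lam, p_adj


def association_score(p) -> np.ndarray | float:
    """-log10(p); a score >= 3.0 corresponds to P < 0.001."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must be in (0, 1]")
    out = -np.log10(arr)
    return out if arr.ndim else float(out)


def marker_r2(codes, y) -> float:
    """Squared Pearson correlation between a marker's codes and phenotype."""
    codes = np.asarray(codes, dtype=float)
    y = np.asarray(y, dtype=float)
    if codes.std() == 0 or y.std() == 0:
        raise ValueError("constant input: r2 undefined")
    r = np.corrcoef(codes, y)[0, 1]
    return float(r**2)


def annotate_gene_context(
    chrom: str,
    position: int,
    annotation: GeneAnnotation,
    flank_bp: int = FLANK_BP,
) -> tuple[str, str | None]:
    """Classify a marker position relative to annotated genes.

    Returns (context, gene_id): 'C' inside an exon, 'I' inside the gene
    span but not an exon, 'F' strictly closer than ``flank_bp`` to a
    gene span, '0' otherwise (gene_id None).  Ambiguity resolves to the
    nearest gene boundary; exact ties to the lexicographically lower
    gene id.
    """
    genes = annotation.genes
    cand = genes[genes["chrom"] == chrom]
    if len(cand):
        inside = cand[(cand["start"] <= position) & (position <= cand["end"])]
        if len(inside):
            gid = sorted(inside["gene_id"])[0]
            ex = annotation.exons
            ex = ex[(ex["gene_id"].isin(inside["gene_id"]))]
            in_exon = ex[(ex["start"] <= position) & (position <= ex["end"])]
            if len(in_exon):
                return "C", sorted(in_exon["gene_id"])[0]
            return "I", gid
        dist = np.where(
            position < cand["start"], cand["start"] - position, position - cand["end"]
        )
        near = dist < flank_bp
        if near.any():
            sub = cand.loc[near].assign(dist=dist[near])
            sub = sub.sort_values(["dist", "gene_id"], kind="stable")
            return "F", sub["gene_id"].iloc[0]
    return "0", None


def assign_pseudo_chromosome(
    chroms: pd.Series | list, pseudo_label: str = "chr9"
) -> pd.Series:
    """Replace missing chromosome labels with the trailing pseudo-chromosome."""
    s = pd.Series(chroms, dtype="object")
    return s.where(s.notna() & (s != ""), pseudo_label)


def manhattan_table(
    records: pd.DataFrame,
    pseudo_label: str = "chr9",
    threshold: float = ASSOCIATION_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Order GWAS records for Manhattan plotting.

    Aligned markers sort by chromosome then position; markers with no
    chromosome go last on the pseudo-chromosome, ordered by their input
    index.  Returns (ordered frame, metadata with the threshold line).
    """
    df = records.copy().reset_index(drop=True)
    df["_input_order"] = np.arange(len(df))
    chroms = assign_pseudo_chromosome(df.get("chromosome"), pseudo_label)
    unaligned = chroms == pseudo_label
    df["chromosome"] = chroms

    def chrom_key(c: str) -> tuple:
        if c == pseudo_label:
            return (1, np.inf)
        digits = "".join(ch for ch in str(c) if ch.isdigit())
        return (0, int(digits) if digits else np.inf)

    df["_ckey"] = [chrom_key(c) for c in df["chromosome"]]
    df["_pos"] = np.where(unaligned, df["_input_order"], df.get("position", 0))
    df = df.sort_values(["_ckey", "_pos"], kind="stable").drop(columns=["_ckey", "_pos"])
    meta = {"threshold": threshold, "pseudo_chromosome": pseudo_label if unaligned.any() else None}
    return df.drop(columns="_input_order").reset_index(drop=True), meta


def gwas_scan(
    g: DiploidCodedMatrix,
    y,
    positions: pd.DataFrame | None = None,
    annotation: GeneAnnotation | None = None,
    flank_bp: int = FLANK_BP,
    threshold: float = ASSOCIATION_THRESHOLD,
) -> tuple[pd.DataFrame, float]:
    """Full association scan: regression, genomic control, scores, context.

    ``positions`` (optional) maps marker -> (chromosome, position);
    unmapped markers land on the pseudo-chromosome.  Returns the record
    table and the genomic-control lambda.
    """
    res = marker_scan(g, y)
    lam, p_adj = genomic_control(res["chi2"].to_numpy())
    res["p_adj"] = p_adj
    with np.errstate(invalid="ignore"):
        res["score"] = np.where(np.isfinite(p_adj), -np.log10(np.maximum(p_adj, 1e-300)), np.nan)
    res["significant"] = res["score"] >= threshold
    if positions is not None:
        res = res.merge(positions, on="marker", how="left")
    else:
        res["chromosome"] = None
        res["position"] = np.nan
    if annotation is not None:
        contexts, gene_ids = [], []
        for _, row in res.iterrows():
            if row.get("chromosome") is None or pd.isna(row.get("position")):
                contexts.append("0")
                gene_ids.append(None)
            else:
                ctx, gid = annotate_gene_context(
                    row["chromosome"], int(row["position"]), annotation, flank_bp
                )
                contexts.append(ctx)
                gene_ids.append(gid)
        res["gene_context"] = contexts
        res["gene_id"] = gene_ids
    return res, lam
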