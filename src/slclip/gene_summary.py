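"""Gene- and start-site-level aggregation of per-read 5'-end classes.

Builds the per-(gene, alignment start) count table, computes SL2/SL1 ratios
at discriminable sites, strand-aware distances to the nearest upstream
coding gene (the operon signal: SL2 trans-splicing concentrates ~100 nt
downstream of a neighbor), SL variant usage frequencies, and the gene-level
trans-splicing call at each gene's most expressed start position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import AMBIGUOUS_CLASSES, is_sl_class
from .sl_detection import (
    CLASS_HAIRPIN,
    CLASS_SENSE_UNTESTED,
    CLASS_SL2X,
    CLASS_UNIDENTIFIED,
)

log = logging.getLogger(__name__)

# Fig-style defaults, all overridable per call
MIN_DISCRIMINABLE = 10     # confident SL1+SL2 reads needed for an SL2 ratio
SL2_FAVORED = 0.60         # ratio > 0.60 -> SL2-favored site
SL1_FAVORED = 0.40         # ratio < 0.40 -> SL1-favored site
MIN_READS_GENE = 20        # reads at the dominant start for a gene call
LOW_SL_MIN_READS = 100     # support needed to flag a poorly trans-spliced gene
LOW_SL_MAX_FRAC = 0.10     # ... with SL detection below 10%


class Annotation:
    """Gene coordinates + transcript-to-gene map loaded from GFF3."""

    def __init__(self, genes: pd.DataFrame, tx2gene: dict[str, str]):
        self.genes = genes.set_index("gene_id", drop=False)
        self.tx2gene = tx2gene

    @classmethod
    def from_gff3(cls, path) -> "Annotation":
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                                merge_strategy="create_unique")
        rows = []
        for g in db.features_of_type("gene"):
            rows.append({
                "gene_id": g.id,
                "contig": g.seqid,
                "start": g.start,     # 1-based inclusive
                "end": g.end,
                "strand": g.strand,
                "biotype": g.attributes.get("biotype", [""])[0],
            })
        tx2gene = {}
        for t in db.features_of_type("mRNA"):
            parents = t.attributes.get("Parent", [])
            if parents:
                tx2gene[t.id] = parents[0]
        return cls(pd.DataFrame(rows), tx2gene)

    def coding_genes(self) -> pd.DataFrame:
        """Genes used as upstream neighbors: protein_coding when annotated,
        else every gene feature."""
        if (self.genes["biotype"] == "protein_coding").any():
            return self.genes[self.genes["biotype"] == "protein_coding"]
        return self.genes

    def upstream_distance(self, gene_id: str) -> float | None:
        """Strand-aware distance from the gene 5' start to the 3' end of the
        nearest upstream coding gene; 0 for an overlapping upstream gene;
        None when there is none (first gene on its contig) or the gene is
        not annotated."""
        if gene_id not in self.genes.index:
            log.warning("gene %s missing from annotation", gene_id)
            return None
        g = self.genes.loc[gene_id]
        others = self.coding_genes()
        others = others[(others["contig"] == g["contig"])
                        & (others["gene_id"] != gene_id)]
        if g["strand"] == "+":
            cand = others[others["start"] < g["start"]]
            if cand.empty:
                return None
            return float(max(0, g["start"] - cand["end"].max()))
        cand = others[others["end"] > g["end"]]
        if cand.empty:
            return None
        return float(max(0, cand["start"].min() - g["end"]))

    def lift_to_genome(self, gene_id: str, pos: int) -> int | None:
        """Transcript coordinate -> genomic coordinate (1-based)."""
        if gene_id not in self.genes.index:
            return None
        g = self.genes.loc[gene_id]
        return int(g["start"] + pos) if g["strand"] == "+" else int(g["end"] - pos)


def _with_gene_ids(class_df: pd.DataFrame, annotation: Annotation | None) -> pd.DataFrame:
    df = class_df.copy()
    if annotation is None:
        df["gene_id"] = df["ref_id"]
        return df
    mapped = df["ref_id"].map(annotation.tx2gene)
    missing = mapped.isna()
    if missing.any():
        for ref in df.loc[missing, "ref_id"].unique():
            log.warning("transcript %s absent from annotation; binned by ref_id", ref)
    df["gene_id"] = mapped.fillna(df["ref_id"])
    return df


def aggregate_start_sites(
    class_df: pd.DataFrame,
    annotation: Annotation | None = None,
    collapse_window: int = 0,
) -> pd.DataFrame:
    """Per-(gene, start position) counts of every 5'-end class.

    Returns one row per (gene_id, ref_id, start_pos) with ``n_total``,
    grouped convenience counts (``n_sl``, ``n_hairpin``, ``n_unidentified``,
    ``n_sense_untested``), confident family counts, and one ``n[<class>]``
    column per observed read class.  ``collapse_window`` > 0 merges start
    positions within that many nt of a more supported one (alignment jitter).
    """
    df = _with_gene_ids(class_df, annotation)
    if df.empty:
        return pd.DataFrame(columns=["gene_id", "ref_id", "start_pos", "n_total",
                                     "n_sl", "n_hairpin", "n_unidentified",
                                     "n_sense_untested", "n_confident_sl1",
                                     "n_confident_sl2"])
    if collapse_window > 0:
        df = df.copy()
        for (gid, rid), grp in df.groupby(["gene_id", "ref_id"]):
            counts = grp["start_pos"].value_counts()
            anchors = []
            for pos in counts.sort_values(ascending=False).index:
                near = [a for a in anchors if abs(a - pos) <= collapse_window]
                if near:
                    df.loc[grp.index[grp["start_pos"] == pos], "start_pos"] = near[0]
                else:
                    anchors.append(pos)
    keys = ["gene_id", "ref_id", "start_pos"]
    cls_counts = (df.groupby(keys)["read_class"].value_counts()
                    .unstack(fill_value=0))
    out = pd.DataFrame(index=cls_counts.index)
    out["n_total"] = cls_counts.sum(axis=1)
    sl_cols = [c for c in cls_counts.columns if is_sl_class(c)]
    out["n_sl"] = cls_counts[sl_cols].sum(axis=1) if sl_cols else 0
    for col, label in (("n_hairpin", CLASS_HAIRPIN),
                       ("n_unidentified", CLASS_UNIDENTIFIED),
                       ("n_sense_untested", CLASS_SENSE_UNTESTED)):
        out[col] = cls_counts[label] if label in cls_counts else 0
    conf = df[df["sl_confident"] & df["sl_family"].isin(["SL1", "SL2"])]
    for fam in ("SL1", "SL2"):
        c = conf[conf["sl_family"] == fam].groupby(keys).size()
        out[f"n_confident_{fam.lower()}"] = c.reindex(out.index, fill_value=0)
    for label in cls_counts.columns:
        out[f"n[{label}]"] = cls_counts[label]
    return out.reset_index()


def dominant_starts(site_df: pd.DataFrame) -> pd.DataFrame:
    """One row per gene: its most supported start (ties to the 5'-most)."""
    s = site_df.sort_values(["gene_id", "n_total", "start_pos"],
                            ascending=[True, False, True])
    return s.groupby("gene_id", as_index=False).first()


def sl2_ratio(
    site_df: pd.DataFrame,
    min_discriminable: int = MIN_DISCRIMINABLE,
    sl2_favored: float = SL2_FAVORED,
    sl1_favored: float = SL1_FAVORED,
) -> pd.DataFrame:
    """SL2/(SL1+SL2) on confident, family-unambiguous matches per site.

    Sites with fewer than ``min_discriminable`` such reads are excluded.
    Categories: ``SL2`` (> 0.60), ``SL1`` (< 0.40), else ``intermediate``
    (strict inequalities on both sides)."""
    n_disc = site_df["n_confident_sl1"] + site_df["n_confident_sl2"]
    out = site_df[n_disc >= min_discriminable].copy()
    if out.empty:
        out["sl2_ratio"] = pd.Series(dtype=float)
        out["category"] = pd.Series(dtype=object)
        return out
    out["sl2_ratio"] = out["n_confident_sl2"] / (
        out["n_confident_sl1"] + out["n_confident_sl2"])
    out["category"] = np.select(
        [out["sl2_ratio"] > sl2_favored, out["sl2_ratio"] < sl1_favored],
        ["SL2", "SL1"], default="intermediate")
    return out


def classify_gene(
    site_df: pd.DataFrame,
    min_reads: int = MIN_READS_GENE,
    sl_majority: float = 0.5,
    include_unidentified: bool = True,
    annotation: Annotation | None = None,
) -> pd.DataFrame:
    """Gene-level trans-splicing call at the dominant start position.

    ``sl_fraction`` = SL reads / (SL + hairpin [+ unidentified]) at the
    dominant start; status is ``trans_spliced`` when it exceeds
    ``sl_majority``, ``hairpin`` when hairpin reads dominate the remainder,
    ``unidentified`` when only unresolved reads are present, and
    ``low_coverage`` below ``min_reads`` informative reads."""
    dom = dominant_starts(site_df)
    rows = []
    for row in dom.itertuples(index=False):
        denom = row.n_sl + row.n_hairpin + (
            row.n_unidentified if include_unidentified else 0)
        sl_frac = row.n_sl / denom if denom else float("nan")
        if denom < min_reads:
            status = "low_coverage"
        elif sl_frac > sl_majority:
            status = "trans_spliced"
        elif row.n_hairpin > 0 and row.n_hairpin >= row.n_unidentified:
            status = "hairpin"
        else:
            status = "unidentified"
        n_disc = row.n_confident_sl1 + row.n_confident_sl2
        rows.append({
            "gene_id": row.gene_id,
            "ref_id": row.ref_id,
            "dominant_start": row.start_pos,
            "n_informative": denom,
            "status": status,
            "sl_fraction": sl_frac,
            "sl2_ratio": (row.n_confident_sl2 / n_disc) if n_disc else float("nan"),
            "upstream_distance": (annotation.upstream_distance(row.gene_id)
                                  if annotation is not None else None),
        })
    return pd.DataFrame(rows)


def trans_spliced_sweep(
    site_df: pd.DataFrame,
    thresholds: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    min_reads: int = MIN_READS_GENE,
    include_unidentified: bool = True,
) -> pd.DataFrame:
    """Fraction of covered genes called trans-spliced at each SL-majority
    threshold (monotone non-increasing in the threshold)."""
    rows = []
    for thr in thresholds:
        calls = classify_gene(site_df, min_reads=min_reads, sl_majority=thr,
                              include_unidentified=include_unidentified)
        covered = calls[calls["status"] != "low_coverage"]
        frac = (covered["status"] == "trans_spliced").mean() if len(covered) else float("nan")
        rows.append({"sl_majority": thr, "n_genes": len(covered),
                     "frac_trans_spliced": frac})
    return pd.DataFrame(rows)


def flag_low_sl_genes(
    site_df: pd.DataFrame,
    min_reads: int = LOW_SL_MIN_READS,
    max_sl_frac: float = LOW_SL_MAX_FRAC,
) -> list[str]:
    """Genes whose dominant start has >= ``min_reads`` reads but an SL
    detection fraction strictly below ``max_sl_frac`` — candidates for
    endogenous-hairpin (non-trans-spliced) 5' ends."""
    dom = dominant_starts(site_df)
    sel = (dom["n_total"] >= min_reads) & (dom["n_sl"] / dom["n_total"] < max_sl_frac)
    return dom.loc[sel, "gene_id"].tolist()


def sl_variant_usage(class_df: pd.DataFrame) -> pd.DataFrame:
    """Usage frequency of each SL among confident, unambiguous matches.

    ``frac_all`` is over all counted reads; ``frac_within_family`` is within
    the read's SL family.  Family-unambiguous SL2.X reads are tallied as
    their own row (they count toward SL2 family totals)."""
    conf = class_df[class_df["sl_confident"]]
    named = conf[conf["sl_name"].notna()]
    counts = named.groupby("sl_name").size()
    n_sl2x = int((conf["read_class"] == CLASS_SL2X).sum())
    if n_sl2x:
        counts = pd.concat([counts, pd.Series({CLASS_SL2X: n_sl2x})])
    if counts.empty:
        return pd.DataFrame(columns=["sl_name", "family", "n", "frac_all",
                                     "frac_within_family"])
    df = counts.rename("n").rename_axis("sl_name").reset_index()
    df["family"] = ["SL2" if (n == CLASS_SL2X or n.startswith("SL2")) else "SL1"
                    for n in df["sl_name"]]
    df["frac_all"] = df["n"] / df["n"].sum()
    fam_tot = df.groupby("family")["n"].transform("sum")
    df["frac_within_family"] = df["n"] / fam_tot
    return df.sort_values("sl_name").reset_index(drop=True)


def sl2_variant_profile(
    class_df: pd.DataFrame,
    sites: pd.DataFrame,
    annotation: Annotation | None = None,
) -> pd.DataFrame:
    """Per-site SL2 variant frequency matrix (rows sum to 1).

    ``sites`` carries (gene_id, ref_id, start_pos) of SL2-favored sites;
    only confident, variant-unambiguous SL2 reads contribute.  Sites without
    such reads are dropped; an empty site set gives an empty matrix."""
    if sites.empty:
        return pd.DataFrame()
    df = _with_gene_ids(class_df, annotation)
    sl2 = df[df["sl_confident"] & df["sl_name"].notna()
             & (df["sl_family"] == "SL2")]
    keys = ["gene_id", "ref_id", "start_pos"]
    merged = sl2.merge(sites[keys], on=keys)
    if merged.empty:
        return pd.DataFrame()
    mat = (merged.groupby(keys)["sl_name"].value_counts().unstack(fill_value=0))
    return mat.div(mat.sum(axis=1), axis=0)


def start_site_report(
    class_df: pd.DataFrame,
    gene_id: str,
    annotation: Annotation | None = None,
) -> pd.DataFrame:
    """Per-start-position map for one gene: read support and majority label.

    Labels: ``SL`` (SL classes in the majority of informative reads),
    ``hairpin``, or ``no-evidence``.  Genomic positions are lifted through
    the annotation when available; a gene with no reads gives an empty
    report."""
    df = _with_gene_ids(class_df, annotation)
    df = df[df["gene_id"] == gene_id]
    rows = []
    for (rid, pos), grp in df.groupby(["ref_id", "start_pos"]):
        n_sl = int(grp["read_class"].map(is_sl_class).sum())
        n_hp = int((grp["read_class"] == CLASS_HAIRPIN).sum())
        n_other = len(grp) - n_sl - n_hp
        if n_sl > max(n_hp, n_other):
            label = "SL"
        elif n_hp > max(n_sl, n_other):
            label = "hairpin"
        else:
            label = "no-evidence"
        rows.append({
            "gene_id": gene_id, "ref_id": rid, "start_pos": pos,
            "n_total": len(grp), "n_sl": n_sl, "n_hairpin": n_hp,
            "n_no_evidence": n_other, "majority_label": label,
            "genomic_pos": (annotation.lift_to_genome(gene_id, pos)
                            if annotation is not None else None),
        })
    out = pd.DataFrame(rows, columns=["gene_id", "ref_id", "start_pos",
                                      "n_total", "n_sl", "n_hairpin",
                                      "n_no_evidence", "majority_label",
                                      "genomic_pos"])
    return out.sort_values(["ref_id", "start_pos"]).reset_index(drop=True)


def write_bed(report: pd.DataFrame, annotation: Annotation, path) -> None:
    """Export a start-site report as BED (0-based half-open intervals)."""
    with open(path, "w") as fh:
        for row in report.itertuples(index=False):
            gpos = row.genomic_pos
            if gpos is None:
                continue
            g = annotation.genes.loc[row.gene_id]
            fh.write(f"{g['contig']}\t{int(gpos) - 1}\t{int(gpos)}\t"
                     f"{row.gene_id}:{row.majority_label}\t{row.n_total}\t"
                     f"{g['strand']}\n")
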