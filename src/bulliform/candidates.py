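"""LD-window candidate genes around top GWAS SNPs.

For the most significant SNP of a scan, r^2 against every SNP on the
same chromosome defines a candidate window: the positional span
(1-based, inclusive) of all SNPs in stronger than 0.5 LD with the top
SNP, the top SNP included.  Genes whose intervals overlap the window
are candidate genes; each is cross-referenced with the differential-
expression table and flagged up- or downregulated at FDR < 0.10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import ld_profile
from .synth.annotation import DE_FDR_CUTOFF

R2_WINDOW_THRESHOLD = 0.5


@dataclass
class LDWindow:
    top_snp: str
    chrom: int
    top_pos: int
    start: int
    end: int
    n_partner_snps: int
    genes: pd.DataFrame = field(repr=False)
    r2: pd.DataFrame = field(repr=False)

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def degenerate(self) -> bool:
        """True when no other SNP exceeded the r^2 threshold."""
        return self.n_partner_snps == 0


def de_status(de_table: pd.DataFrame, fdr_cutoff: float = DE_FDR_CUTOFF) -> pd.Series:
    """Map gene_id -> 'up' / 'down' / 'ns' from a (gene, logFC, FDR) table."""
    sig = de_table["FDR"] < fdr_cutoff
    status = np.where(~sig, "ns", np.where(de_table["logFC"] > 0, "up", "down"))
    return pd.Series(status, index=de_table["gene_id"], name="de_status")


def candidate_genes(
    result: pd.DataFrame,
    dosages,
    snp_info: pd.DataFrame,
    annotation: pd.DataFrame,
    de_table: pd.DataFrame | None = None,
    r2_threshold: float = R2_WINDOW_THRESHOLD,
    top_idx: int | None = None,
) -> LDWindow:
    """Candidate-gene report for a GWAS scan.

    ``result`` is the scan table (needs ``p`` aligned with
    ``snp_info``); the top SNP is its minimum-p row unless ``top_idx``
    overrides it.  ``annotation`` has gene_id/chrom/start/end.  When no
    same-chromosome SNP exceeds the threshold the window degenerates to
    the top SNP position (reported, not an error).
    """
    if top_idx is None:
        if result["p"].isna().all():
            raise ValueError("scan has no tested SNPs")
        top_idx = int(result["p"].idxmin())
    top = snp_info.iloc[top_idx]

    prof = ld_profile(dosages, snp_info, top_idx)
    partners = prof[(prof["r2"] > r2_threshold)]
    start = int(min(partners["pos"].min(), top["pos"])) if len(partners) else int(top["pos"])
    end = int(max(partners["pos"].max(), top["pos"])) if len(partners) else int(top["pos"])
    n_partners = int((partners["snp_id"] != top["snp_id"]).sum())

    genes = annotation[
        (annotation["chrom"] == top["chrom"])
        & (annotation["end"] >= start)
        & (annotation["start"] <= end)
    ].copy()
    if de_table is not None:
        status = de_status(de_table)
        genes["de_status"] = genes["gene_id"].map(status).fillna("ns")
    genes = genes.reset_index(drop=True)
    return LDWindow(
        top_snp=str(top["snp_id"]), chrom=int(top["chrom"]), top_pos=int(top["pos"]),
        start=start, end=end, n_partner_snps=n_partners, genes=genes, r2=prof,
    )


def window_report(window: LDWindow) -> dict:
    """JSON-ready summary with candidate-gene DE counts."""
    counts = (
        window.genes["de_status"].value_counts().to_dict()
        if "de_status" in window.genes
        else {}
    )
    return {
        "top_snp": window.top_snp,
        "chrom": window.chrom,
        "top_pos": window.top_pos,
        "window_start": window.start,
        "window_end": window.end,
        "span_bp": window.span_bp,
        "n_partner_snps": window.n_partner_snps,
        "n_genes": int(len(window.genes)),
        "n_upregulated": int(counts.get("up", 0)),
        "n_downregulated": int(counts.get("down", 0)),
        "genes": window.genes.to_dict("records"),
    }
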