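"""Synthetic gene annotation (GFF3) and differential-expression table.

Gene models are non-overlapping 1-based inclusive intervals laid out by
partitioning each chromosome into equal slots, one gene per slot, with a
random sub-interval chosen inside the slot.  The DE table assigns a
chosen fraction of genes as upregulated at FDR < 0.10 (positive logFC),
an optional fraction downregulated, and the remainder non-significant —
mirroring an ontogenic-zone vs differentiated-tissue contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DE_FDR_CUTOFF = 0.10


def gen_annotation_and_de(
    chrom_lengths: dict[int, int],
    n_genes: int,
    frac_up: float,
    seed: int = 0,
    frac_down: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate gene models and a matched DE results table.

    Returns (genes, de): genes with columns gene_id/chrom/start/end/strand,
    de with columns gene_id/logFC/FDR.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= frac_up <= 1 or not 0 <= frac_down <= 1 or frac_up + frac_down > 1:
        raise ValueError("frac_up/frac_down must be fractions summing to <= 1")
    rng = np.random.default_rng(seed)

    total_len = sum(chrom_lengths.values())
    rows = []
    gene_no = 0
    for chrom, length in sorted(chrom_lengths.items()):
        n_here = int(round(n_genes * length / total_len))
        if chrom == sorted(chrom_lengths)[-1]:
            n_here = n_genes - gene_no  # absorb rounding remainder
        if n_here == 0:
            continue
        slot = length // n_here
        if slot < 10:
            raise ValueError(
                f"{n_here} genes do not fit on a {length}-bp chromosome"
            )
        for k in range(n_here):
            lo, hi = k * slot + 1, (k + 1) * slot
            glen = int(rng.integers(max(2, slot // 10), max(3, slot // 2)))
            start = int(rng.integers(lo, hi - glen))
            rows.append(
                {
                    "gene_id": f"G{gene_no:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + glen - 1,  # 1-based inclusive
                    "strand": rng.choice(["+", "-"]),
                }
            )
            gene_no += 1
    genes = pd.DataFrame(rows)
    if (genes["end"] > [chrom_lengths[c] for c in genes["chrom"]]).any():
        raise ValueError("generated gene exceeds chromosome length")

    n_up = int(round(frac_up * n_genes))
    n_down = int(round(frac_down * n_genes))
    status = np.array(["ns"] * n_genes, dtype=object)
    order = rng.permutation(n_genes)
    status[order[:n_up]] = "up"
    status[order[n_up : n_up + n_down]] = "down"

    logfc = np.where(
        status == "ns",
        rng.normal(0.0, 0.2, size=n_genes),
        np.sign((status == "up").astype(float) - 0.5) * np.abs(rng.normal(1.5, 0.5, size=n_genes)),
    )
    fdr = np.where(
        status == "ns",
        rng.uniform(DE_FDR_CUTOFF, 1.0, size=n_genes),
        rng.uniform(0.0, DE_FDR_CUTOFF * 0.99, size=n_genes),
    )
    de = pd.DataFrame({"gene_id": genes["gene_id"], "logFC": logfc, "FDR": fdr})
    return genes, de


def write_gff3(path, genes: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(
                f"{g.chrom}\tsynth\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID=gene:{g.gene_id};Name={g.gene_id}\n"
            )


def read_gff3_genes(path) -> pd.DataFrame:
    """Parse gene records from a GFF3 file into the internal gene table."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
    )
    df = df[df["type"] == "gene"].copy()
    df["gene_id"] = df["attrs"].str.extract(r"ID=(?:gene:)?([^;]+)")
    return df[["gene_id", "chrom", "start", "end", "strand"]].reset_index(drop=True)
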