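"""Inbred SNP panel simulator with controllable LD, MAF and missingness.

Lines are mosaics of a founder haplotype pool: along each chromosome a
line copies one founder, switching to a random founder with a fixed
per-SNP recombination probability, with a forced switch at LD-block
boundaries (``ld_block_len``).  Shared founder tracts create local LD
whose r^2 decays with inter-SNP distance; ``ld_block_len=1`` forces a
redraw at every SNP, giving independent markers.  Per-SNP mutation noise
keeps markers polymorphic within tracts.

Dosages are 0/2 (inbred) with a small heterozygosity rate and random
missingness; additive QTL can be planted at chosen SNP indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # integer missing code in dosage matrices


@dataclass
class GenotypeSimParams:
    n_lines: int = 400
    n_snps: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_block_len: int = 50
    missing_rate: float = 0.0
    het_rate: float = 0.0
    causal: list = field(default_factory=list)  # [(snp_index, effect_size), ...]
    n_founders: int = 16
    founder_corr: float = 0.95
    recomb_rate: float = 0.02
    mutation_rate: float = 0.01
    n_chroms: int = 1
    bp_per_snp: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.ld_block_len < 1:
            raise ValueError("ld_block_len must be >= 1")
        for name in ("missing_rate", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for idx, _ in self.causal:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"causal SNP index {idx} out of range")


def gen_genotypes(params: GenotypeSimParams):
    """Simulate the panel.

    Returns
    -------
    dosages : int8 array (n_lines, n_snps) with values {0, 1, 2, -1}
    snp_info : DataFrame with snp_id, chrom, pos, founder_freq, maf
        (realized minor-allele frequency over non-missing calls)
    truth : dict with the causal list and founder haplotypes
    """
    rng = np.random.default_rng(params.seed)
    n, m = params.n_lines, params.n_snps

    freqs = rng.uniform(params.maf_low, params.maf_high, size=m)
    # planted QTL get mid-range frequencies so they stay well polymorphic
    for idx, _ in params.causal:
        freqs[idx] = rng.uniform(0.3, 0.5)

    # chromosome assignment: contiguous equal chunks
    chrom_of = np.repeat(np.arange(params.n_chroms), int(np.ceil(m / params.n_chroms)))[:m]
    pos = np.empty(m, dtype=np.int64)
    for c in range(params.n_chroms):
        idx = np.flatnonzero(chrom_of == c)
        pos[idx] = np.sort(
            rng.choice(
                np.arange(1, max(len(idx) * params.bp_per_snp, len(idx)) + 1),
                size=len(idx),
                replace=False,
            )
        )

    new_block = np.zeros(m, dtype=bool)
    new_block[0] = True
    new_block[np.arange(m) % params.ld_block_len == 0] = True
    new_block[np.flatnonzero(np.diff(chrom_of)) + 1] = True

    # founder haplotypes: Gaussian-copula AR(1) along each LD block, so
    # founder alleles are locally correlated and panel r^2 decays with
    # inter-SNP distance; block boundaries reset the chain.
    from scipy.stats import norm

    rho = params.founder_corr
    z = np.empty((params.n_founders, m))
    fresh = rng.standard_normal((params.n_founders, m))
    z[:, 0] = fresh[:, 0]
    for j in range(1, m):
        if new_block[j]:
            z[:, j] = fresh[:, j]
        else:
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * fresh[:, j]
    founders = (z < norm.ppf(freqs)[None, :]).astype(np.int8)

    # line mosaics: Markov copying over founders with forced switches at
    # block starts
    founder_idx = np.empty((n, m), dtype=np.int32)
    redraws = rng.integers(0, params.n_founders, size=(n, m))
    do_switch = (rng.random((n, m)) < params.recomb_rate) | new_block[None, :]
    cur = redraws[:, 0].copy()
    for j in range(m):
        sw = do_switch[:, j]
        cur = np.where(sw, redraws[:, j], cur)
        founder_idx[:, j] = cur

    alleles = founders[founder_idx, np.arange(m)[None, :]]
    # per-SNP mutation: replace with an independent Bernoulli(freq) draw
    mut = rng.random((n, m)) < params.mutation_rate
    fresh = (rng.random((n, m)) < freqs[None, :]).astype(np.int8)
    alleles = np.where(mut, fresh, alleles)

    dosages = (2 * alleles).astype(np.int8)
    if params.het_rate > 0:
        het = rng.random((n, m)) < params.het_rate
        dosages = np.where(het, 1, dosages).astype(np.int8)
    if params.missing_rate > 0:
        miss = rng.random((n, m)) < params.missing_rate
        dosages = np.where(miss, MISSING, dosages).astype(np.int8)

    maf = realized_maf(dosages)
    snp_info = pd.DataFrame(
        {
            "snp_id": [f"S{j:06d}" for j in range(m)],
            "chrom": (chrom_of + 1).astype(int),
            "pos": pos,
            "founder_freq": freqs,
            "maf": maf,
        }
    )
    truth = {"causal": list(params.causal), "founders": founders}
    return dosages, snp_info, truth


def realized_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per SNP over non-missing calls (NaN if none)."""
    d = np.asarray(dosages, dtype=float)
    d[np.asarray(dosages) == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    return np.minimum(p, 1 - p)


def qtl_phenotype(
    dosages: np.ndarray,
    causal: list[tuple[int, float]],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Additive QTL phenotype: sum of effect * dosage (mean-imputed) + N(0, sd^2)."""
    rng = np.random.default_rng(seed)
    d = np.asarray(dosages, dtype=float)
    d[np.asarray(dosages) == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean, d)
    y = np.zeros(d.shape[0])
    for idx, eff in causal:
        y += eff * d[:, idx]
    return y + rng.normal(0.0, noise_sd, size=d.shape[0])


def write_dosage_tsv(path, dosages, snp_info, line_ids=None):
    """Line x SNP dosage table; missing written as NA."""
    n = dosages.shape[0]
    line_ids = line_ids or [f"L{i:04d}" for i in range(n)]
    df = pd.DataFrame(dosages, index=line_ids, columns=snp_info["snp_id"])
    df = df.replace(MISSING, pd.NA)
    df.to_csv(path, sep="\t", index_label="line", na_rep="NA")


def write_vcf(path, dosages, snp_info, line_ids=None):
    """Write the panel as a minimal VCF v4.2 with GT fields (A ref, T alt)."""
    n, m = dosages.shape
    line_ids = line_ids or [f"L{i:04d}" for i in range(n)]
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = snp_info["chrom"].unique()
        for c in chroms:
            max_pos = int(snp_info.loc[snp_info.chrom == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={max_pos + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(line_ids) + "\n")
        for j in range(m):
            row = snp_info.iloc[j]
            gts = "\t".join(gt_code[int(dosages[i, j])] for i in range(n))
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf_dosages(path):
    """Read a VCF back into (dosages, snp_info, line_ids) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    rows, dos = [], []
    for var in vcf:
        rows.append({"snp_id": var.ID, "chrom": int(var.CHROM), "pos": var.POS})
        gt = var.gt_types  # 0=hom_ref,1=het,2=unknown? cyvcf2: 0,1,2,3
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        conv = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dos.append(conv.astype(np.int8))
    return np.array(dos, dtype=np.int8).T, pd.DataFrame(rows), line_ids
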