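#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes a small gallery of synthetic epidermis images with truth masks,
the two-environment field-trial phenotype tables for both bulliform
traits, a SNP panel (VCF + dosage TSV), gene models (GFF3) and a
differential-expression table under results/simulated/.
"""

import argparse
from pathlib import Path

import numpy as np
import imageio.v3 as iio

from bulliform.pipelines import TRAIT_COMPONENTS, TRAIT_MEANS, benchmark_image_params
from bulliform.synth import (
    FieldDesign, GenotypeSimParams, gen_annotation_and_de, gen_epidermis_image,
    gen_field_phenotypes, gen_genotypes, write_gff3, write_vcf, write_dosage_tsv,
)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out-dir", type=Path, default=Path("results/simulated"))
args = ap.parse_args()
out = args.out_dir
(out / "images").mkdir(parents=True, exist_ok=True)

rng = np.random.default_rng(args.seed)
print("-- images: 8 benchmark-scale examples with truth masks")
for i in range(8):
    p = benchmark_image_params(seed=int(rng.integers(2**31)), n_columns=int(rng.integers(3, 6)))
    img, mask, truth = gen_epidermis_image(p)
    iio.imwrite(out / "images" / f"img{i:02d}.png", (img * 255).astype(np.uint8))
    iio.imwrite(out / "images" / f"img{i:02d}_mask.png", mask * 255)
    print(f"   img{i:02d}: {truth['n_columns']} columns, width {truth['width_px']:.1f} px")

print("-- field trial: 468 lines x 2 environments, both traits")
design = FieldDesign(seed=args.seed)
for t_i, (trait, vc) in enumerate(TRAIT_COMPONENTS.items()):
    pheno, _ = gen_field_phenotypes(
        design, vc, seed=args.seed + 1000 * t_i, grand_mean=TRAIT_MEANS[trait],
        check_effects={"N28HT": 0.5, "Mo17": -0.5},
    )
    pheno.to_csv(out / f"pheno_{trait}.tsv", sep="\t", index=False)
    print(f"   {trait}: {len(pheno)} plots -> pheno_{trait}.tsv")

print("-- SNP panel: 400 lines x 2000 SNPs with LD and one planted QTL")
gp = GenotypeSimParams(n_lines=400, n_snps=2000, ld_block_len=50,
                       missing_rate=0.05, het_rate=0.01,
                       seed=args.seed, causal=[(1000, 0.5)])
dos, info, truth = gen_genotypes(gp)
write_vcf(out / "panel.vcf", dos, info)
write_dosage_tsv(out / "panel_dosages.tsv", dos, info)
info.to_csv(out / "snp_info.tsv", sep="\t", index=False)

print("-- annotation: 300 genes + DE table")
genes, de = gen_annotation_and_de({1: int(info.pos.max()) + 10_000}, 300,
                                  frac_up=0.2, frac_down=0.2, seed=args.seed)
write_gff3(out / "genes.gff3", genes)
de.to_csv(out / "de_table.tsv", sep="\t", index=False)
print(f"wrote inputs under {out}")
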