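#!/usr/bin/env python
"""LD-window candidate genes around the top GWAS SNP.

Takes the scan from step 05 (re-run via the shared study driver for
self-containment), builds the r^2 > 0.5 window around the most
significant SNP, lists the genes it spans, and cross-references each
against the differential-expression table (upregulated in the bulliform
ontogenic zone at FDR < 0.10).
"""

import argparse
import json
from pathlib import Path

from bulliform.pipelines import gwas_study

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out-dir", type=Path, default=Path("results/candidates"))
args = ap.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

study = gwas_study(seed=args.seed)
win = study["window"]
print(f"top SNP {win['top_snp']} (chr{win['chrom']}:{win['top_pos']})")
print(f"r^2 > 0.5 window: {win['window_start']:,}-{win['window_end']:,} "
      f"({win['span_bp'] / 1e3:.1f} kb, {win['n_partner_snps']} partner SNPs)")
print(f"genes in window: {win['n_genes']} "
      f"({win['n_upregulated']} upregulated, {win['n_downregulated']} downregulated)")
for g in win["genes"]:
    print(f"  {g['gene_id']}  chr{g['chrom']}:{g['start']}-{g['end']}  {g.get('de_status', 'ns')}")

(args.out_dir / "window_report.json").write_text(json.dumps(win, indent=2))
print(f"wrote {args.out_dir / 'window_report.json'}")
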