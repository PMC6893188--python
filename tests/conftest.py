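import numpy as np
import pandas as pd
import pytest

from bulliform.synth import (
    FieldDesign,
    GenotypeSimParams,
    ImageSimParams,
    VarianceComponents,
    gen_epidermis_image,
    gen_field_phenotypes,
    gen_genotypes,
)


@pytest.fixture(scope="session")
def clean_bands_image():
    """Noiseless image with 5 straight 30-px bands (known layout)."""
    params = ImageSimParams(
        n_columns=5, column_width_px=30, width_jitter_frac=0.0,
        edge_jitter_px=0.0, column_spacing_jitter=0.0, noise_sd=0.0, seed=1,
    )
    return gen_epidermis_image(params)


@pytest.fixture(scope="session")
def small_design():
    """A 6-block design (108 lines) for fast mixed-model Monte Carlo."""
    return FieldDesign(n_blocks=6, seed=0)


@pytest.fixture(scope="session")
def small_panel():
    """300 lines x 600 SNPs with moderate LD, no missingness."""
    params = GenotypeSimParams(n_lines=300, n_snps=600, ld_block_len=40, seed=5)
    return gen_genotypes(params)


@pytest.fixture
def one_way_balanced():
    """Balanced one-way random-effects data with known components."""
    rng = np.random.default_rng(11)
    g, r = 25, 6
    s2g, s2e = 2.0, 1.0
    eff = rng.normal(0, np.sqrt(s2g), g)
    rows = [
        {
            "env": "E1", "block": "B0", "col": f"R{j}", "entry": f"L{i:03d}",
            "is_check": False, "trait": 5 + eff[i] + rng.normal(0, np.sqrt(s2e)),
        }
        for i in range(g)
        for j in range(r)
    ]
    return pd.DataFrame(rows), g, r


def make_replicated_pheno(vc, seed, n_lines=50, n_reps=2, envs=("AZ", "CA")):
    """Two-environment data with ``n_reps`` plots per line and environment.

    Unlike the single-replicate field layout (where G x E and residual
    variance are confounded), replication identifies every component, so
    component-wise recovery and reduction tests are well-posed.
    """
    rng = np.random.default_rng(seed)
    lines = [f"L{i:03d}" for i in range(n_lines)]
    g = dict(zip(lines, rng.normal(0, np.sqrt(vc.sigma2_G), n_lines)))
    rows = []
    for env in envs:
        e = rng.normal(0, np.sqrt(vc.sigma2_env))
        ge = dict(zip(lines, rng.normal(0, np.sqrt(vc.sigma2_GE), n_lines)))
        n_blocks = max(2, n_lines * n_reps // 20)
        blocks = [f"B{k:02d}" for k in range(n_blocks)]
        cols = [f"C{k:02d}" for k in range(10)]
        b_eff = dict(zip(blocks, rng.normal(0, np.sqrt(vc.sigma2_block), n_blocks)))
        c_eff = dict(zip(cols, rng.normal(0, np.sqrt(vc.sigma2_col), 10)))
        k = 0
        for rep in range(n_reps):
            order = rng.permutation(lines)
            for ln in order:
                b, c = blocks[k % n_blocks], cols[k % 10]
                rows.append(
                    {
                        "env": env, "block": b, "col": c, "entry": ln,
                        "is_check": False,
                        "trait": 10 + e + g[ln] + ge[ln] + b_eff[b] + c_eff[c]
                        + rng.normal(0, np.sqrt(vc.sigma2_eps)),
                    }
                )
                k += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def both_env_pheno(small_design):
    vc = VarianceComponents(
        sigma2_G=1.0, sigma2_GE=0.3, sigma2_env=0.5,
        sigma2_block=0.2, sigma2_col=0.2, sigma2_eps=1.0,
    )
    pheno, truth = gen_field_phenotypes(
        small_design, vc, seed=7, check_effects={"N28HT": 1.0, "Mo17": -1.0}
    )
    return pheno, vc, truth
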