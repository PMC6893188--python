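"""Two-environment incomplete-block field trial simulator.

Emulates a maize diversity-panel trial: in each of two environments the
experimental lines are laid out as an incomplete block design of 26
blocks x 18 experimental entries, each block augmented with the two
check inbred lines (N28HT and Mo17) at random positions, i.e. a 20-row x
26-column grid per environment.  Every experimental line appears exactly
once per environment (a single replicate per location).

Plot values follow the additive model

    y = mu + check + env + g(line) + ge(line, env) + block(env) + col(env) + eps

with every random term drawn i.i.d. normal with its own variance
component.  Flowering time is generated analogously from its own
components, with an optional genetic correlation to the trait so that
covariate selection has signal to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

CHECK_LINES = ("N28HT", "Mo17")


@dataclass
class FieldDesign:
    """Layout constants of the augmented incomplete-block trial."""

    environments: tuple[str, str] = ("AZ", "CA")
    n_blocks: int = 26
    entries_per_block: int = 18
    checks: tuple[str, str] = CHECK_LINES
    seed: int = 0

    @property
    def n_lines(self) -> int:
        return self.n_blocks * self.entries_per_block

    @property
    def rows_per_block(self) -> int:
        return self.entries_per_block + len(self.checks)

    def layout(self) -> pd.DataFrame:
        """One row per plot: env, block, col, entry, is_check.

        Blocks are the grid columns; the crossed ``col`` factor is the
        grid row (``rows_per_block`` levels), carrying positional trend
        orthogonal to blocks.  Check positions are re-randomized per
        block and environment.
        """
        rng = np.random.default_rng(self.seed)
        lines = [f"L{i:04d}" for i in range(self.n_lines)]
        rows = []
        for env in self.environments:
            perm = rng.permutation(self.n_lines)
            k = 0
            for b in range(self.n_blocks):
                positions = rng.permutation(self.rows_per_block)
                check_pos = set(positions[: len(self.checks)])
                checks_iter = iter(self.checks)
                for r in range(self.rows_per_block):
                    if r in check_pos:
                        entry, is_check = next(checks_iter), True
                    else:
                        entry, is_check = lines[perm[k]], False
                        k += 1
                    rows.append(
                        {"env": env, "block": f"B{b:02d}", "col": f"R{r:02d}",
                         "entry": entry, "is_check": is_check}
                    )
        return pd.DataFrame(rows)


@dataclass
class VarianceComponents:
    """Variance components of the plot-level model (trait units squared)."""

    sigma2_G: float = 0.5
    sigma2_GE: float = 0.2
    sigma2_env: float = 0.3
    sigma2_block: float = 0.1
    sigma2_col: float = 0.1
    sigma2_eps: float = 0.5

    def __post_init__(self):
        for name, v in self.as_dict().items():
            if v < 0:
                raise ValueError(f"variance component {name} must be >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma2_G": self.sigma2_G,
            "sigma2_GE": self.sigma2_GE,
            "sigma2_env": self.sigma2_env,
            "sigma2_block": self.sigma2_block,
            "sigma2_col": self.sigma2_col,
            "sigma2_eps": self.sigma2_eps,
        }


def _draw_effects(levels, sigma2: float, rng) -> dict:
    sd = float(np.sqrt(sigma2))
    return dict(zip(levels, rng.normal(0.0, sd, size=len(levels))))


def gen_field_phenotypes(
    design: FieldDesign,
    vc: VarianceComponents,
    line_effects: dict[str, float] | float = 0.0,
    seed: int = 0,
    grand_mean: float = 10.0,
    check_effects: dict[str, float] | None = None,
    trait: str = "trait",
    ft_vc: VarianceComponents | None = None,
    ft_grand_mean: float = 75.0,
    ft_genetic_corr: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate plot-level phenotypes on the given design.

    Parameters
    ----------
    line_effects
        Fixed additive genetic values per experimental line (e.g. from
        planted QTL), or a scalar applied to all lines; the random
        polygenic term N(0, sigma2_G) is added on top.
    ft_vc, ft_genetic_corr
        Variance components for the flowering-time column and the
        correlation between its genetic effects and the trait's.  With
        ``ft_vc=None`` flowering time uses the same components.

    Returns
    -------
    (pheno, truth): the plot table with columns env/block/col/entry/
    is_check/<trait>/flowering_time, and a dict of the realized per-line
    genetic effects and all drawn random effects.
    """
    rng = np.random.default_rng(seed)
    plots = design.layout()
    lines = sorted(plots.loc[~plots.is_check, "entry"].unique())
    if np.isscalar(line_effects):
        line_effects = {ln: float(line_effects) for ln in lines}
    missing = set(lines) - set(line_effects)
    if missing:
        raise KeyError(f"line_effects missing {len(missing)} entries, e.g. {sorted(missing)[:3]}")
    check_effects = dict(check_effects or {})

    envs = list(design.environments)
    g_std = rng.standard_normal(len(lines))
    g = dict(zip(lines, np.sqrt(vc.sigma2_G) * g_std))

    def _simulate(components: VarianceComponents, mean: float, gen: dict, name: str):
        env_eff = _draw_effects(envs, components.sigma2_env, rng)
        ge_eff = {
            (ln, e): v
            for e in envs
            for ln, v in _draw_effects(lines, components.sigma2_GE, rng).items()
        }
        block_eff = {
            (e, b): v
            for e in envs
            for b, v in _draw_effects(plots.block.unique(), components.sigma2_block, rng).items()
        }
        col_eff = {
            (e, c): v
            for e in envs
            for c, v in _draw_effects(plots.col.unique(), components.sigma2_col, rng).items()
        }
        eps = rng.normal(0.0, np.sqrt(components.sigma2_eps), size=len(plots))
        vals = np.empty(len(plots))
        for i, p in enumerate(plots.itertuples()):
            base = mean + env_eff[p.env] + block_eff[(p.env, p.block)] + col_eff[(p.env, p.col)]
            if p.is_check:
                base += check_effects.get(p.entry, 0.0) if name == "trait" else 0.0
            else:
                base += gen[p.entry] + ge_eff[(p.entry, p.env)]
            vals[i] = base + eps[i]
        return vals, {"env": env_eff, "ge": ge_eff, "block": block_eff, "col": col_eff}

    total_g = {ln: g[ln] + line_effects[ln] for ln in lines}
    trait_vals, trait_draws = _simulate(vc, grand_mean, total_g, "trait")

    ft_components = ft_vc if ft_vc is not None else vc
    rho = float(ft_genetic_corr)
    ft_g_std = rho * g_std + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(len(lines))
    ft_g = dict(zip(lines, np.sqrt(ft_components.sigma2_G) * ft_g_std))
    ft_vals, ft_draws = _simulate(ft_components, ft_grand_mean, ft_g, "ft")

    pheno = plots.copy()
    pheno[trait] = trait_vals
    pheno["flowering_time"] = ft_vals
    truth = {
        "line_genetic_effects": total_g,
        "ft_genetic_effects": ft_g,
        "trait_draws": trait_draws,
        "ft_draws": ft_draws,
    }
    return pheno, truth
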