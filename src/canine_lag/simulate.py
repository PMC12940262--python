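"""Synthetic breed datasets with the statistical structure the PGLS assumes.

The generator emulates the study design: a handful of ancient breeds on deep
lineages plus a large radiation of modern European breeds on a 200-year star
polytomy (104 modern + 7 ancient by default), body weights log-uniform over
5-70 kg, and traits that are linear in (transformed) weight within each
breed-age group with a constant ancient-modern offset. Residuals are drawn
from a multivariate normal whose covariance is the breed tree's Brownian
covariance under chosen Pagel lambda/kappa/delta, normalised to unit
diagonal so ``sigma`` is the residual standard deviation on the transformed
trait scale.

Default effect sizes mirror the published fits: lifespan declines 0.0865
yr/kg with a +1.287 yr ancient offset; sqrt litter size rises 0.344 per log
kg with a -0.1778 ancient offset; log cancer mortality rate rises 0.3187
per log kg for modern breeds and declines 0.6639 per log kg for ancient
breeds (interaction -0.9826, ancient lines crossing at 20 kg). Cancer
mortality is emitted as counts: diagnosed deaths uniform on 100-600 and
cancer deaths binomial at the model proportion, so downstream log-transform
and zero-rate edge cases are exercised realistically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

from .phylogeny import build_tree, pagel_covariance
from .pgls import _cholesky_psd

__all__ = [
    "SimulationConfig",
    "DEFAULT_BETAS",
    "DEFAULT_SIGMAS",
    "random_breed_tree",
    "simulate_traits",
    "simulate_dataset",
    "load_synthetic_ancient_breeds",
]

#: (intercept, weight slope, ancient offset, weight x ancient) on the
#: transformed scale of each trait
DEFAULT_BETAS: dict[str, tuple[float, float, float, float]] = {
    "lifespan": (13.0, -0.0865, 1.287, 0.0),
    "litter": (1.4651, 0.3435, -0.1778, 0.0),
    "cmr": (-2.5058, 0.3187, 2.9436, -0.9826),
}

#: residual standard deviations on the transformed scales
DEFAULT_SIGMAS: dict[str, float] = {"lifespan": 1.0, "litter": 0.15, "cmr": 0.3}


@dataclass
class SimulationConfig:
    n_modern: int = 104
    n_ancient: int = 7
    weight_range_kg: tuple[float, float] = (5.0, 70.0)
    betas: dict = field(default_factory=lambda: dict(DEFAULT_BETAS))
    sigmas: dict = field(default_factory=lambda: dict(DEFAULT_SIGMAS))
    pagel: tuple[float, float, float] = (1.0, 1.0, 1.0)  # lambda, kappa, delta
    tree_depth_years: float = 16000.0
    modern_branch: float = 200.0
    ancient_min_divergence: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_modern < 0 or self.n_ancient < 0 or self.n_modern + self.n_ancient < 2:
            raise ValueError("need at least two breeds in total")
        lo, hi = self.weight_range_kg
        if not 0 < lo < hi:
            raise ValueError("weight range must be positive and increasing")
        for t, s in self.sigmas.items():
            if s < 0:
                raise ValueError(f"sigma for {t} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "weight_range_kg" in raw:
            raw["weight_range_kg"] = tuple(raw["weight_range_kg"])
        if "pagel" in raw:
            raw["pagel"] = tuple(raw["pagel"])
        if "betas" in raw:
            raw["betas"] = {k: tuple(v) for k, v in raw["betas"].items()}
        return cls(**raw)


def random_breed_tree(config: SimulationConfig) -> dendropy.Tree:
    """Ultrametric breed tree: a pectinate ancient backbone plus the modern
    star polytomy. Deterministic given the config (tip names and divergence
    times are functions of the counts and depth only)."""
    modern = [f"modern_{i + 1:03d}" for i in range(config.n_modern)]
    ancient = [f"ancient_{i + 1}" for i in range(config.n_ancient)]
    if not ancient:
        return build_tree(None, modern, modern_branch=config.modern_branch)
    heights = np.geomspace(
        config.tree_depth_years, config.ancient_min_divergence, config.n_ancient
    )
    rows = []
    for i, (name, h) in enumerate(zip(ancient, heights)):
        node = f"node_{i + 1}"
        parent = "" if i == 0 else f"node_{i}"
        rows.append((node, parent, float(h)))
        rows.append((name, node, 0.0))
    rows.append(("modern", f"node_{config.n_ancient}", config.modern_branch))
    lineages = pd.DataFrame(rows, columns=["child", "parent", "divergence_time_years"])
    if not modern:
        # ancient-only tree: modern node would dangle, so rebuild without it
        lineages = lineages.iloc[:-1]
        return build_tree(lineages, [], modern_branch=config.modern_branch)
    return build_tree(lineages, modern, modern_branch=config.modern_branch)


def _phylo_noise(L: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    return sigma * (L @ rng.standard_normal(L.shape[0]))


def simulate_traits(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Trait table for the tips of ``tree`` under the configured ANCOVA.

    Tips named ``ancient_*`` are labelled ancient, all others modern.
    Returns columns ``breed,label,weight_kg,lifespan_yr,litter_size,
    cancer_deaths,diagnosed_deaths``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    labels = ["ancient" if t.startswith("ancient") else "modern" for t in tips]
    n = len(tips)
    ind = np.array([1.0 if l == "ancient" else 0.0 for l in labels])
    lo, hi = config.weight_range_kg
    weight = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    lam, kappa, delta = config.pagel
    V = pagel_covariance(tree, lam=lam, kappa=kappa, delta=delta).loc[tips, tips]
    Vn = V.to_numpy(dtype=float)
    Vn = Vn / Vn.diagonal().max()  # unit-diagonal so sigma is the residual sd
    L = _cholesky_psd(Vn)

    def eta(trait, w_t):
        b0, b1, b2, b3 = config.betas[trait]
        return b0 + b1 * w_t + b2 * ind + b3 * w_t * ind

    lifespan = eta("lifespan", weight) + _phylo_noise(L, config.sigmas["lifespan"], rng)
    sqrt_litter = eta("litter", np.log(weight)) + _phylo_noise(
        L, config.sigmas["litter"], rng
    )
    log_cmr = eta("cmr", np.log(weight)) + _phylo_noise(L, config.sigmas["cmr"], rng)
    for _ in range(100):
        bad = log_cmr >= 0.0
        if not bad.any():
            break
        warnings.warn(
            f"{int(bad.sum())} simulated cancer mortality rate(s) >= 1; resampling",
            UserWarning,
            stacklevel=2,
        )
        redraw = eta("cmr", np.log(weight)) + _phylo_noise(L, config.sigmas["cmr"], rng)
        log_cmr = np.where(bad, redraw, log_cmr)
    else:
        raise RuntimeError("could not simulate cancer mortality rates below 1")

    diagnosed = rng.integers(100, 601, size=n)
    cancer = rng.binomial(diagnosed, np.exp(log_cmr))
    return pd.DataFrame(
        {
            "breed": tips,
            "label": labels,
            "weight_kg": weight,
            "lifespan_yr": lifespan,
            "litter_size": sqrt_litter**2,
            "cancer_deaths": cancer,
            "diagnosed_deaths": diagnosed,
        }
    )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Convenience: tree plus matching trait table from one config/seed."""
    tree = random_breed_tree(config)
    return tree, simulate_traits(tree, config)


def load_synthetic_ancient_breeds() -> pd.DataFrame:
    """Bundled synthetic covariate table for the seven named ancient breeds.

    Values are plausible but flat placeholders for interface tests only —
    they are not biological measurements.
    """
    import importlib.resources

    ref = importlib.resources.files("canine_lag.data") / "synthetic_ancient_breeds.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)
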