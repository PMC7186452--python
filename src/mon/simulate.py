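"""Synthetic input generator with planted essentiality signal.

Produces a coherent bundle — interaction network, domain annotations,
expression time courses, ortholog counts, modular scores and a benchmark
essential set — where essentiality correlates with degree, domain
rarity, co-expression clustering and ortholog counts, each through an
independently tunable knob. Setting every knob to zero yields a null
configuration where essential and non-essential proteins are
statistically exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from mon.evaluation import Benchmark
from mon.network import (
    DomainMap,
    ExpressionProfile,
    PinGraph,
    ProteinUniverse,
)
from mon.ranking import OrthologTable


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 200
    n_essential: int = 40
    n_modules: int = 6
    n_domains: int = 30
    n_timepoints: int = 36
    p_within: float = 0.3  # edge density inside a module
    p_background: float = 0.02  # density between modules
    degree_boost: float = 0.1  # extra edge probability on essential endpoints
    domain_rarity_bias: float = 0.6  # essentials' preference for rare domains
    rho: float = 0.6  # expected within-module expression correlation
    ortholog_shift: float = 40.0  # added Poisson rate for essentials
    ortholog_base_rate: float = 10.0
    modular_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_modules < 1 or self.n_domains < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.n_essential <= self.n_proteins):
            raise ValueError("n_essential must lie in [0, n_proteins]")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")
        for name in ("p_within", "p_background", "degree_boost"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if not (0.0 <= self.domain_rarity_bias <= 1.0):
            raise ValueError("domain_rarity_bias must lie in [0, 1]")
        if self.p_within > 0 and self.n_proteins // self.n_modules < 2:
            raise ValueError(
                "modules of size < 2 cannot carry within-module edges"
            )


@dataclass(frozen=True)
class SyntheticBundle:
    pin: PinGraph
    domains: DomainMap
    expression: ExpressionProfile
    orthologs: OrthologTable
    modular_scores: Dict[str, float]
    benchmark: Benchmark
    module_of: Dict[str, int] = field(default_factory=dict)


def _protein_ids(n: int) -> List[str]:
    width = len(str(n - 1))
    return [f"P{i:0{width}d}" for i in range(n)]


def generate(cfg: SyntheticConfig) -> SyntheticBundle:
    """Draw one reproducible bundle from the configuration's seed."""
    rng = np.random.default_rng(cfg.seed)
    ids = _protein_ids(cfg.n_proteins)
    universe = ProteinUniverse.from_ids(ids)

    # contiguous module assignment; essentials fill the first modules,
    # concentrating them in a subset of modules
    module_of = {
        p: (i * cfg.n_modules) // cfg.n_proteins for i, p in enumerate(ids)
    }
    essential = frozenset(ids[: cfg.n_essential])
    is_ess = np.array([p in essential for p in ids])

    # --- interaction network ------------------------------------------------
    edges = set()
    for i in range(cfg.n_proteins):
        for j in range(i + 1, cfg.n_proteins):
            base = (
                cfg.p_within
                if module_of[ids[i]] == module_of[ids[j]]
                else cfg.p_background
            )
            p = base + cfg.degree_boost * 0.5 * (is_ess[i] + is_ess[j])
            if rng.random() < min(p, 1.0):
                edges.add((ids[i], ids[j]))
    pin = PinGraph.from_edges(edges, universe=universe)

    # --- domains ------------------------------------------------------------
    # the first half of the domain pool is "rare": essentials draw from it
    # preferentially, so rare domains end up held by few (mostly essential)
    # proteins and carry high inverse-frequency scores
    n_rare = max(1, cfg.n_domains // 2)
    rare = [f"D{d:03d}" for d in range(n_rare)]
    common = [f"D{d:03d}" for d in range(n_rare, cfg.n_domains)] or rare
    memberships = set()
    for i, p in enumerate(ids):
        k_domains = 1 + rng.integers(0, 3)
        p_rare = 0.5 + (cfg.domain_rarity_bias / 2 if is_ess[i] else -cfg.domain_rarity_bias / 2)
        for _ in range(k_domains):
            pool = rare if rng.random() < p_rare else common
            memberships.add((p, pool[rng.integers(0, len(pool))]))
    domains = DomainMap.from_pairs(memberships)

    # --- expression ---------------------------------------------------------
    # latent-factor model: g_i = sqrt(rho) f_m + sqrt(1-rho) eps_i gives
    # expected pairwise correlation rho between members of one module
    factors = rng.standard_normal((cfg.n_modules, cfg.n_timepoints))
    values = {}
    for p in ids:
        noise = rng.standard_normal(cfg.n_timepoints)
        values[p] = (
            np.sqrt(cfg.rho) * factors[module_of[p]]
            + np.sqrt(1.0 - cfg.rho) * noise
        )
    expression = ExpressionProfile.from_dict(values)

    # --- orthologs ----------------------------------------------------------
    rates = np.where(
        is_ess, cfg.ortholog_base_rate + cfg.ortholog_shift, cfg.ortholog_base_rate
    )
    counts = rng.poisson(rates)
    orthologs = OrthologTable(dict(zip(ids, (int(c) for c in counts))))

    # --- modular scores -----------------------------------------------------
    ess_frac_by_module = np.zeros(cfg.n_modules)
    size_by_module = np.zeros(cfg.n_modules)
    for p in ids:
        size_by_module[module_of[p]] += 1
        if p in essential:
            ess_frac_by_module[module_of[p]] += 1
    ess_frac_by_module /= np.maximum(size_by_module, 1)
    modular_scores = {}
    for p in ids:
        noisy = ess_frac_by_module[module_of[p]] + cfg.modular_noise * rng.standard_normal()
        modular_scores[p] = float(np.clip(noisy, 0.0, 1.0))

    benchmark = Benchmark.from_ids(essential, universe)
    return SyntheticBundle(
        pin=pin,
        domains=domains,
        expression=expression,
        orthologs=orthologs,
        modular_scores=modular_scores,
        benchmark=benchmark,
        module_of=module_of,
    )
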