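"""Synthetic fixture generator with planted lncRNA-protein group structure.

The walk's working assumption is that similar lncRNAs share interaction
partners. The generator plants that structure explicitly: lncRNAs and
proteins are partitioned into groups; lncRNAs in a group draw their
expression profiles from a shared latent profile plus independent Gaussian
noise (so within-group |PCC| exceeds between-group |PCC|); proteins in a
group are densely connected with high scores; and each lncRNA's interaction
partners fall inside its own group except for a configurable noise fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, InteractionTable, WeightedPPITable

__all__ = ["ScenarioConfig", "GeneratedScenario", "generate_scenario", "degenerate_fixtures"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator settings.

    ``mean_interactions_per_lncrna`` defaults to 4.37 (the average partner
    count in the curated human interaction set the method was designed for);
    each lncRNA draws 1 + Poisson(mean - 1) partners, so every lncRNA has at
    least one. ``within_group_expression_correlation`` is the target |PCC|
    between two profiles of the same group; the additive-noise standard
    deviation is solved from rho = 1/(1 + sigma^2).
    """

    n_lncrnas: int = 60
    n_proteins: int = 40
    n_conditions: int = 24
    n_groups: int = 4
    within_group_expression_correlation: float = 0.8
    ppi_within_group_density: float = 0.8
    ppi_between_group_density: float = 0.05
    ppi_within_score_range: tuple[float, float] = (0.6, 1.0)
    ppi_between_score_range: tuple[float, float] = (0.1, 0.4)
    mean_interactions_per_lncrna: float = 4.37
    noise_rate: float = 0.1
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("ppi_within_group_density", "ppi_between_group_density", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.within_group_expression_correlation < 1.0:
            raise ValueError("within_group_expression_correlation must be in (0, 1)")
        if self.n_groups < 1 or self.n_groups > min(self.n_lncrnas, self.n_proteins):
            raise ValueError("n_groups must be in [1, min(n_lncrnas, n_proteins)]")
        if self.mean_interactions_per_lncrna < 1:
            raise ValueError("mean_interactions_per_lncrna must be >= 1")
        if self.n_conditions < 2:
            raise ValueError("n_conditions must be >= 2")
        if self.mean_interactions_per_lncrna > self.n_proteins // self.n_groups:
            raise ValueError(
                "infeasible config: mean interaction demand exceeds proteins per group"
            )


@dataclass(frozen=True)
class GeneratedScenario:
    expression: ExpressionMatrix
    ppi: WeightedPPITable
    interactions: InteractionTable
    lncrna_groups: dict[str, int]
    protein_groups: dict[str, int]


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_scenario(cfg: ScenarioConfig) -> GeneratedScenario:
    """Draw one planted-structure dataset; identical seeds give identical output."""
    rng = np.random.default_rng(cfg.seed)
    lnc_ids = _ids("L", cfg.n_lncrnas)
    prot_ids = _ids("P", cfg.n_proteins)
    lnc_grp = np.arange(cfg.n_lncrnas) % cfg.n_groups
    prot_grp = np.arange(cfg.n_proteins) % cfg.n_groups

    # expression: shared latent profile per group + independent noise
    rho = cfg.within_group_expression_correlation
    sigma = float(np.sqrt(1.0 / rho - 1.0))
    latent = rng.standard_normal((cfg.n_groups, cfg.n_conditions))
    expr = latent[lnc_grp] + sigma * rng.standard_normal((cfg.n_lncrnas, cfg.n_conditions))
    expression = ExpressionMatrix(tuple(lnc_ids), tuple(_ids("T", cfg.n_conditions)), expr)

    # PPI: dense high-score edges within groups, sparse low-score between
    edges: list[tuple[str, str, float]] = []
    lo_w, hi_w = cfg.ppi_within_score_range
    lo_b, hi_b = cfg.ppi_between_score_range
    for i in range(cfg.n_proteins):
        for j in range(i + 1, cfg.n_proteins):
            same = prot_grp[i] == prot_grp[j]
            dens = cfg.ppi_within_group_density if same else cfg.ppi_between_group_density
            if rng.random() < dens:
                score = rng.uniform(lo_w, hi_w) if same else rng.uniform(lo_b, hi_b)
                edges.append((prot_ids[i], prot_ids[j], float(score)))
    ppi = WeightedPPITable(tuple(edges))

    # interactions: partners inside own group except with prob noise_rate
    pairs: list[tuple[str, str]] = []
    prot_by_grp = {g: np.flatnonzero(prot_grp == g) for g in range(cfg.n_groups)}
    all_prot = np.arange(cfg.n_proteins)
    for i in range(cfg.n_lncrnas):
        g = lnc_grp[i]
        k = 1 + rng.poisson(cfg.mean_interactions_per_lncrna - 1.0)
        k = min(k, cfg.n_proteins)
        own = prot_by_grp[g]
        chosen: list[int] = []
        avail_own = list(own)
        avail_other = [p for p in all_prot if prot_grp[p] != g]
        for _ in range(k):
            cross = rng.random() < cfg.noise_rate
            pool = avail_other if cross and avail_other else avail_own
            if not pool and cfg.noise_rate > 0:
                pool = avail_other
            if not pool:
                break  # group exhausted; zero noise never crosses groups
            p = int(pool[rng.integers(len(pool))])
            pool.remove(p)
            chosen.append(p)
        for p in sorted(chosen):
            pairs.append((lnc_ids[i], prot_ids[p]))
    interactions = InteractionTable(tuple(pairs))

    return GeneratedScenario(
        expression=expression,
        ppi=ppi,
        interactions=interactions,
        lncrna_groups={lnc_ids[i]: int(lnc_grp[i]) for i in range(cfg.n_lncrnas)},
        protein_groups={prot_ids[i]: int(prot_grp[i]) for i in range(cfg.n_proteins)},
    )


def degenerate_fixtures() -> dict[str, GeneratedScenario]:
    """Hand-checkable tiny datasets used across the test suite.

    ``tiny_2x2``        two proteins with one PPI edge, two perfectly
                        correlated lncRNAs, a single interaction (L1, P1);
                        its 4x4 transition matrix is verifiable by hand.
    ``star_ppi``        hub P0 linked to P1..P3 with unit scores.
    ``zero_variance``   one lncRNA with a constant expression profile.
    ``isolated_protein`` a protein with no PPI edge and no interaction.
    ``single_partner``  a lncRNA with exactly one partner (excluded by the
                        >=2-partner cross-validation filter).
    """
    ramp = np.array([1.0, 2.0, 3.0])
    out: dict[str, GeneratedScenario] = {}

    out["tiny_2x2"] = GeneratedScenario(
        expression=ExpressionMatrix(("L1", "L2"), ("T0", "T1", "T2"), np.array([ramp, 2 * ramp])),
        ppi=WeightedPPITable((("P1", "P2", 0.9),)),
        interactions=InteractionTable((("L1", "P1"),)),
        lncrna_groups={"L1": 0, "L2": 0},
        protein_groups={"P1": 0, "P2": 0},
    )
    out["star_ppi"] = GeneratedScenario(
        expression=ExpressionMatrix(
            ("L1", "L2"), ("T0", "T1", "T2"), np.array([ramp, ramp[::-1]])
        ),
        ppi=WeightedPPITable(
            (("P0", "P1", 1.0), ("P0", "P2", 1.0), ("P0", "P3", 1.0))
        ),
        interactions=InteractionTable((("L1", "P0"), ("L1", "P1"))),
        lncrna_groups={"L1": 0, "L2": 0},
        protein_groups={p: 0 for p in ("P0", "P1", "P2", "P3")},
    )
    out["zero_variance"] = GeneratedScenario(
        expression=ExpressionMatrix(
            ("L1", "L2", "L3"),
            ("T0", "T1", "T2"),
            np.array([ramp, [5.0, 5.0, 5.0], 3 * ramp]),
        ),
        ppi=WeightedPPITable((("P1", "P2", 0.8),)),
        interactions=InteractionTable((("L1", "P1"), ("L2", "P2"))),
        lncrna_groups={"L1": 0, "L2": 0, "L3": 0},
        protein_groups={"P1": 0, "P2": 0},
    )
    out["isolated_protein"] = GeneratedScenario(
        expression=ExpressionMatrix(("L1", "L2"), ("T0", "T1", "T2"), np.array([ramp, 2 * ramp])),
        ppi=WeightedPPITable((("P1", "P2", 0.5),)),
        interactions=InteractionTable((("L1", "P1"),)),
        lncrna_groups={"L1": 0, "L2": 0},
        # P3 appears only through explicit registration in tests
        protein_groups={"P1": 0, "P2": 0, "P3": 0},
    )
    out["single_partner"] = GeneratedScenario(
        expression=ExpressionMatrix(
            ("L1", "L2"), ("T0", "T1", "T2"), np.array([ramp, ramp + 1.0])
        ),
        ppi=WeightedPPITable((("P1", "P2", 1.0), ("P2", "P3", 1.0))),
        interactions=InteractionTable(
            (("L1", "P1"), ("L1", "P2"), ("L2", "P3"))
        ),
        lncrna_groups={"L1": 0, "L2": 0},
        protein_groups={"P1": 0, "P2": 0, "P3": 0},
    )
    return out
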