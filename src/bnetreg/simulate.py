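"""Synthetic pathway-structured datasets with known ground truth.

The generator emulates the structure the model is designed for: genes
grouped into pathways with one hub regulating several satellites (a star
per pathway), correlated expression within a pathway, and a coefficient
vector that is smooth over the network in the degree-scaled metric — the
hub carries effect h and each satellite h'/sqrt(d_hub), which zeroes the
Laplacian smoothness penalty sum_{u~v} (beta_u/sqrt(d_u) -
beta_v/sqrt(d_v))^2 within an active star when h' = h.  Responses are
either Gaussian (y = X beta + noise) or binary from the probit
mechanism (y = 1 iff X beta + standard normal noise > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset, standardize
from .graph import GeneNetwork

__all__ = ["SimulationScenario", "SyntheticDataset", "make_pathway_network", "simulate"]


@dataclass(frozen=True)
class SimulationScenario:
    """Design of one synthetic study.

    Defaults give 10 star pathways of 5 genes (p = 50), 3 of them
    carrying signal, 100 samples, within-pathway correlation 0.5, unit
    hub effect and unit Gaussian noise — a signal-to-noise ratio well
    above 3.
    """

    n_pathways: int = 10
    genes_per_pathway: int = 5
    n_active_pathways: int = 3
    hub_effect: float = 1.0
    satellite_effect: float = 1.0
    within_pathway_correlation: float = 0.5
    noise_sd: float = 1.0
    n_samples: int = 100
    response_type: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1 or self.genes_per_pathway < 1:
            raise ValueError("need at least one pathway with at least one gene")
        if not 0 <= self.n_active_pathways <= self.n_pathways:
            raise ValueError("n_active_pathways must be in [0, n_pathways]")
        if not 0 <= self.within_pathway_correlation < 1:
            raise ValueError("within-pathway correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.response_type not in ("gaussian", "binary"):
            raise ValueError(f"unknown response_type {self.response_type!r}")

    @property
    def n_genes(self) -> int:
        return self.n_pathways * self.genes_per_pathway

    def gene_ids(self) -> list[str]:
        ids = []
        for q in range(self.n_pathways):
            ids.append(f"pw{q:02d}_hub")
            ids.extend(f"pw{q:02d}_s{s}" for s in range(1, self.genes_per_pathway))
        return ids


@dataclass
class SyntheticDataset:
    """Generated data plus the ground truth it was generated from."""

    data: ExpressionDataset
    network: GeneNetwork
    true_beta: np.ndarray
    true_sigma2: float
    scenario: SimulationScenario = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.network.nodes != self.data.gene_ids:
            raise ValueError("network nodes must equal dataset gene ids")

    @property
    def active_genes(self) -> list[str]:
        return [g for g, b in zip(self.data.gene_ids, self.true_beta) if b != 0]


def make_pathway_network(scenario: SimulationScenario) -> GeneNetwork:
    """Star topology per pathway: hub connected to every satellite, unit weights."""
    ids = scenario.gene_ids()
    edges = []
    for q in range(scenario.n_pathways):
        hub = f"pw{q:02d}_hub"
        edges.extend(
            (hub, f"pw{q:02d}_s{s}", 1.0) for s in range(1, scenario.genes_per_pathway)
        )
    return GeneNetwork.from_edges(edges, nodes=ids)


def _true_beta(scenario: SimulationScenario) -> np.ndarray:
    g = scenario.genes_per_pathway
    beta = np.zeros(scenario.n_genes)
    hub_degree = g - 1
    for q in range(scenario.n_active_pathways):
        base = q * g
        beta[base] = scenario.hub_effect
        if hub_degree > 0:
            beta[base + 1 : base + g] = scenario.satellite_effect / np.sqrt(hub_degree)
    return beta


def simulate(scenario: SimulationScenario) -> SyntheticDataset:
    """Generate one dataset under the scenario.

    Expression rows are i.i.d. multivariate normal with unit variances
    and equicorrelation ``within_pathway_correlation`` inside each
    pathway (independence across pathways), then standardized.  The
    Gaussian response is X beta + N(0, noise_sd^2); the binary response
    thresholds the probit latent X beta + N(0, 1) at zero.  Bitwise
    reproducible from the scenario's seed.
    """
    rng = np.random.default_rng(scenario.seed)
    n, g = scenario.n_samples, scenario.genes_per_pathway
    rho = scenario.within_pathway_correlation

    # equicorrelated block = sqrt(rho)*shared + sqrt(1-rho)*idiosyncratic
    blocks = []
    for _ in range(scenario.n_pathways):
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, g))
        blocks.append(np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own)
    X = np.concatenate(blocks, axis=1)
    X, _, _ = standardize(X)

    beta = _true_beta(scenario)
    signal = X @ beta
    if scenario.response_type == "gaussian":
        y = signal + scenario.noise_sd * rng.standard_normal(n)
        true_sigma2 = scenario.noise_sd**2
    else:
        y = (signal + rng.standard_normal(n) > 0).astype(float)
        true_sigma2 = 1.0

    ids = scenario.gene_ids()
    data = ExpressionDataset(
        X=X, y=y, gene_ids=ids,
        sample_ids=[f"s{i:04d}" for i in range(n)],
        standardized=True,
    )
    return SyntheticDataset(
        data=data,
        network=make_pathway_network(scenario),
        true_beta=beta,
        true_sigma2=true_sigma2,
        scenario=scenario,
    )
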