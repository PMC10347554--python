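"""Reproducible synthetic graph populations and regression datasets.

Stands in for imaged mitochondrial networks: populations are produced by
evolving a single two-node tubule under the stochastic morphological
process and recording the endpoint, with tubule lengths drawn log-normally
(positive, right-skewed, defaults mu_log = ln 1.0 um, sigma_log = 0.5).

Two styles mirror the experimentally contrasted populations:

* ``wildtype`` - all processes active; fusion back onto the same component
  creates cycles, so a healthy fraction of endpoints is cyclic;
* ``dko``      - fission and both fusions disabled, as in the
  fission-fusion double knockout (Delta dnm1 Delta fzo1), leaving only
  outgrowth and resorption; every endpoint is a tree (circuit rank 0).
  Mitophagy is also off by default: without fission a single-component
  tree never fragments into the isolated two-node tubules mitophagy
  consumes, so a nonzero rate could only ever delete the whole network.

The (n1, n3) generator draws tip counts uniformly over a positive range
and places junction counts on a chosen steady-state law plus Gaussian
noise floored at zero - the harness for steady-state model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .graph import MLGraph, validate_mlg
from .kinetics import RateModel, SteadyStateFit, gillespie_trajectory, steady_state_n3

__all__ = [
    "PopulationSpec",
    "WILDTYPE_RATES",
    "DKO_RATES",
    "generate_population",
    "generate_n1n3_data",
]

#: default wild-type process rates: fission/fusion active and balanced,
#: growth slightly dominant so endpoints are non-trivial networks
WILDTYPE_RATES = RateModel(
    k_fis=0.8, k_fus_tt=0.5, k_fus_ts=0.5, k_out=0.9, k_res=0.3, k_aut=0.05, k_flip=0.1
)

#: double-knockout rates: no fission, no fusion (and hence no mitophagy
#: substrate; see module docstring)
DKO_RATES = RateModel(
    k_fis=0.0, k_fus_tt=0.0, k_fus_ts=0.0, k_out=1.0, k_res=0.3, k_aut=0.0, k_flip=0.0
)


@dataclass(frozen=True)
class PopulationSpec:
    style: Literal["wildtype", "dko"] = "wildtype"
    size: int = 50
    rates: RateModel | None = None  # None -> style default
    t_max: float = 1.5
    max_nodes: int = 16
    length_mu_log: float = 0.0  # ln(1.0 um)
    length_sigma_log: float = 0.5
    seed: int = 0

    def resolved_rates(self) -> RateModel:
        if self.rates is not None:
            return self.rates
        return WILDTYPE_RATES if self.style == "wildtype" else DKO_RATES


def _assign_lengths(graph: MLGraph, rng: np.random.Generator, spec: PopulationSpec) -> MLGraph:
    g = graph.nx.copy()
    for u, v in g.edges:
        g.edges[u, v][MLGraph.LENGTH_KEY] = float(
            rng.lognormal(spec.length_mu_log, spec.length_sigma_log)
        )
    return MLGraph.from_networkx(g)


def generate_population(spec: PopulationSpec) -> list[MLGraph]:
    """Evolve ``spec.size`` independent networks and return the endpoints.

    Each network starts from a single two-node tubule and runs the
    stochastic morphological process to ``t_max`` (capped at
    ``max_nodes``); endpoints that die out (mitophagy of the last tubule)
    are re-run with a shifted stream so every emitted graph is non-empty.
    Tubule lengths are drawn after evolution, log-normally per edge.
    Fully reproducible from ``spec.seed``.
    """
    if spec.size < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(spec.seed)
    rates = spec.resolved_rates()
    out: list[MLGraph] = []
    attempts = 0
    while len(out) < spec.size:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        attempts += 1
        if attempts > 50 * spec.size:
            raise RuntimeError("population generation kept dying out; check rates")
        seed_graph = MLGraph([(0, 1)])
        _, final, _ = gillespie_trajectory(
            seed_graph, rates, t_max=spec.t_max, seed_rng=sub_seed, max_nodes=spec.max_nodes
        )
        if final.n_nodes == 0:
            continue
        assert validate_mlg(final).valid
        out.append(_assign_lengths(final, rng, spec))
    return out


def generate_n1n3_data(
    model: SteadyStateFit,
    n: int,
    noise_sigma: float,
    seed: int,
    n1_range: tuple[float, float] = (2.0, 40.0),
) -> list[tuple[float, float]]:
    """Scatter data (n1, n3) from a steady-state law plus Gaussian noise.

    n1 is uniform over ``n1_range``; n3 = law(n1) + N(0, sigma), floored
    at 0 (node counts cannot be negative).
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    rng = np.random.default_rng(seed)
    n1 = rng.uniform(n1_range[0], n1_range[1], size=n)
    n3 = np.array([steady_state_n3(v, model) for v in n1])
    n3 = np.maximum(n3 + rng.normal(0.0, noise_sigma, size=n), 0.0)
    return list(zip(n1.tolist(), n3.tolist()))
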