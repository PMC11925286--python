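"""Vaccination mapping and the discrete-time SIR stage.

After the opinion stage, every agent with a non-negative opinion is
vaccinated and gains full immunity; the anti-vaccine adopters are the only
susceptible individuals.  Disease then spreads by a synchronous discrete
SIR process restricted to that subpopulation: every infected agent (as of
the start of a step) independently attempts to infect each currently
susceptible neighbor with probability beta, then draws recovery with
probability gamma.  A newly infected agent neither transmits nor recovers
within its infection step.  The process stops when no infected agents
remain and the epidemic size S_r is the recovered count at absorption.

Vaccinated agents keep their network position, so they block transmission
paths between susceptible clusters (the structural herd effect).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .opinion import NEGATIVE, Population

if TYPE_CHECKING:
    from .network import ContactNetwork

__all__ = ["SIRParams", "EpidemicResult", "vaccinate", "seed_infection", "run_sir"]


@dataclass(frozen=True)
class SIRParams:
    """beta: per-contact per-step transmission probability; gamma:
    per-step recovery probability; i0: initial infected count."""

    beta: float
    gamma: float
    i0: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0,1], got {self.beta}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0,1], got {self.gamma}")
        if self.i0 < 1:
            raise ValueError(f"I0 must be >= 1, got {self.i0}")


@dataclass
class EpidemicResult:
    """Final size and time series of one SIR run.

    ``s_r`` counts the ever-infected agents (= recovered at absorption);
    ``series`` is an (n_steps+1, 3) array of (S, I, R) counts restricted
    to the unvaccinated subpopulation; ``seed_nodes`` the initially
    infected agents (empty when no susceptible agents existed).
    """

    s_r: int
    series: np.ndarray
    seed_nodes: np.ndarray


def vaccinate(pop: Population) -> np.ndarray:
    """Node ids left susceptible after vaccination: exactly the
    anti-vaccine adopters."""
    return np.flatnonzero(pop.states == NEGATIVE)


def seed_infection(
    susceptible: np.ndarray, i0: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample (without replacement) of ``i0`` susceptible agents.

    An empty susceptible set yields an empty seed (no outbreak possible);
    a non-empty set smaller than ``i0`` is an error.
    """
    susceptible = np.asarray(susceptible)
    if susceptible.size == 0:
        return np.empty(0, dtype=np.int64)
    if susceptible.size < i0:
        raise ValueError(
            f"I0={i0} exceeds the susceptible population of {susceptible.size}"
        )
    return rng.choice(susceptible, size=i0, replace=False)


def run_sir(
    net: "ContactNetwork",
    susceptible: np.ndarray,
    params: SIRParams,
    rng: np.random.Generator,
) -> EpidemicResult:
    """Run one synchronous discrete-time SIR outbreak.

    ``susceptible`` are the node ids at risk (the anti-vaccine adopters);
    all other nodes are immune and never enter the S/I/R accounting.
    """
    susceptible = np.asarray(susceptible, dtype=np.int64)
    n = net.n_nodes
    seeds = seed_infection(susceptible, params.i0, rng)
    if seeds.size == 0:
        return EpidemicResult(
            s_r=0,
            series=np.zeros((1, 3), dtype=np.int64),
            seed_nodes=seeds,
        )
    # status over all nodes: 0 immune/outside, 1 susceptible, 2 infected, 3 recovered
    status = np.zeros(n, dtype=np.int8)
    status[susceptible] = 1
    status[seeds] = 2
    adj = net.adjacency
    series = [(int(np.sum(status == 1)), int(seeds.size), 0)]
    while True:
        infected = status == 2
        n_inf = int(infected.sum())
        if n_inf == 0:
            break
        sus_mask = status == 1
        if params.beta > 0 and sus_mask.any():
            # number of infectious contacts per susceptible agent; each
            # contact is an independent Bernoulli(beta) trial, so the
            # per-agent infection probability is 1 - (1-beta)^m
            m = adj @ infected.astype(np.int32)
            at_risk = np.flatnonzero(sus_mask & (m > 0))
            if at_risk.size:
                p_inf = 1.0 - (1.0 - params.beta) ** m[at_risk]
                newly = at_risk[rng.random(at_risk.size) < p_inf]
            else:
                newly = np.empty(0, dtype=np.int64)
        else:
            newly = np.empty(0, dtype=np.int64)
        # recovery draws for the agents infectious at the start of the step
        inf_ids = np.flatnonzero(infected)
        recovering = inf_ids[rng.random(inf_ids.size) < params.gamma]
        status[newly] = 2
        status[recovering] = 3
        series.append(
            (
                int(np.sum(status == 1)),
                int(np.sum(status == 2)),
                int(np.sum(status == 3)),
            )
        )
    s_r = int(np.sum(status == 3))
    return EpidemicResult(
        s_r=s_r, series=np.asarray(series, dtype=np.int64), seed_nodes=seeds
    )
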