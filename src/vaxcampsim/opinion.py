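"""Opinion-diffusion stage: competing complex contagion with exposure counters.

Every agent starts neutral and accumulates integer counters of negative
(phi-) and positive (phi+) exposures.  Exposures arrive from two channels:

* **general** (campaign/media): one Bernoulli trial per agent per step with
  probability mu- for the negative channel and a per-agent allocation
  mu_i+ for the positive channel;
* **social**: one Bernoulli trial per adopter-neighbor link per step, with
  probability omega- for negative neighbors and omega+ for positive ones.

A neutral agent commits to the negative opinion when phi- - phi+ >= theta
and to the positive opinion when phi- - phi+ <= -theta; committed agents
never change again and stop accumulating exposures.  Updates are
synchronous: an agent adopting at step t exerts social influence from step
t+1 onward.

The per-step draw order is fixed (retargeting, negative general, positive
general, negative social, positive social) so that a run is bit-reproducible
given a seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Protocol

import numpy as np

if TYPE_CHECKING:
    from .network import ContactNetwork

__all__ = [
    "NEGATIVE",
    "NEUTRAL",
    "POSITIVE",
    "Population",
    "DiffusionParams",
    "OpinionTrajectory",
    "initialize_agents",
    "apply_general_exposures",
    "apply_social_exposures",
    "update_opinion",
    "run_opinion_stage",
]

NEGATIVE: int = -1
NEUTRAL: int = 0
POSITIVE: int = 1

#: Hard cap on the number of steps when tau is "run to full adoption";
#: exceeding it raises rather than silently truncating.
MAX_STEPS: int = 10**6


@dataclass
class Population:
    """Vectorized agent states and exposure counters.

    ``states`` is an int8 array over agents with values -1/0/+1;
    ``phi_minus``/``phi_plus`` are the cumulative exposure counters.
    """

    states: np.ndarray
    phi_minus: np.ndarray
    phi_plus: np.ndarray

    @property
    def n(self) -> int:
        return len(self.states)

    def counts(self) -> tuple[int, int, int]:
        """(negative, neutral, positive) agent counts."""
        return (
            int(np.sum(self.states == NEGATIVE)),
            int(np.sum(self.states == NEUTRAL)),
            int(np.sum(self.states == POSITIVE)),
        )

    def neutral_mask(self) -> np.ndarray:
        return self.states == NEUTRAL


@dataclass(frozen=True)
class DiffusionParams:
    """Opinion-stage parameters.

    Attributes
    ----------
    mu_minus : float
        Negative general exposure probability per agent per step.
    omega_minus, omega_plus : float
        Social exposure probability per adopter-neighbor link per step.
    theta : int
        Opinion formation threshold (net exposures needed to commit).
    tau : int or math.inf
        Stage length; ``math.inf`` runs until no neutral agents remain.
    """

    mu_minus: float
    omega_minus: float
    omega_plus: float
    theta: int
    tau: float  # positive int or math.inf

    def __post_init__(self) -> None:
        for name in ("mu_minus", "omega_minus", "omega_plus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")
        if self.theta < 1:
            raise ValueError(f"theta must be >= 1, got {self.theta}")
        if self.tau != math.inf:
            if int(self.tau) != self.tau or self.tau < 1:
                raise ValueError(f"tau must be a positive integer or inf, got {self.tau}")


@dataclass
class OpinionTrajectory:
    """Per-step opinion counts and how the stage ended."""

    n_negative: np.ndarray
    n_neutral: np.ndarray
    n_positive: np.ndarray
    termination: str  # "tau_reached" | "all_adopted"

    @property
    def n_steps(self) -> int:
        return len(self.n_negative) - 1  # row 0 is the initial condition


class Campaign(Protocol):
    """Positive-campaign hook consumed by :func:`run_opinion_stage`.

    ``allocation_for_step`` returns the per-agent positive exposure
    probability vector for this step (recomputing the target set first if
    the strategy's retargeting schedule is due).
    """

    def allocation_for_step(
        self,
        step: int,
        net: "ContactNetwork",
        pop: Population,
        rng: np.random.Generator,
    ) -> np.ndarray: ...


def initialize_agents(n: int) -> Population:
    """All-neutral population with zeroed counters."""
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    return Population(
        states=np.zeros(n, dtype=np.int8),
        phi_minus=np.zeros(n, dtype=np.int64),
        phi_plus=np.zeros(n, dtype=np.int64),
    )


def apply_general_exposures(
    pop: Population,
    allocation: np.ndarray | float,
    mu_minus: float,
    rng: np.random.Generator,
) -> None:
    """One step of campaign/media exposure (in place).

    Each *neutral* agent runs one Bernoulli(mu-) trial on the negative
    channel and one Bernoulli(mu_i+) trial on the positive channel;
    successes increment the matching counter by 1.  Committed agents are
    untouched.
    """
    alloc = np.broadcast_to(np.asarray(allocation, dtype=float), (pop.n,))
    if np.any(alloc < 0) or np.any(alloc > 1):
        bad = alloc[(alloc < 0) | (alloc > 1)][0]
        raise ValueError(
            f"positive allocation must be in [0,1]; got {bad} "
            "(mu_plus * N / |T| exceeds 1?)"
        )
    neutral = pop.neutral_mask()
    if mu_minus > 0:
        hits = rng.random(pop.n) < mu_minus
        pop.phi_minus += (hits & neutral).astype(np.int64)
    if np.any(alloc > 0):
        hits = rng.random(pop.n) < alloc
        pop.phi_plus += (hits & neutral).astype(np.int64)


def apply_social_exposures(
    pop: Population,
    net: "ContactNetwork",
    omega_minus: float,
    omega_plus: float,
    rng: np.random.Generator,
) -> None:
    """One step of peer influence (in place, synchronous).

    For each link from a committed agent (state as of entry) to a neutral
    neighbor, an independent Bernoulli trial with the committed side's
    omega increments the neutral agent's matching counter.  A neutral agent
    with m negative neighbors therefore receives a Binomial(m, omega-)
    increment, drawn directly.
    """
    neutral = pop.neutral_mask()
    if not np.any(neutral):
        return
    adj = net.adjacency
    if omega_minus > 0:
        neg = (pop.states == NEGATIVE).astype(np.int32)
        if neg.any():
            m = adj @ neg
            idx = np.flatnonzero(neutral & (m > 0))
            if idx.size:
                pop.phi_minus[idx] += rng.binomial(m[idx], omega_minus)
    if omega_plus > 0:
        pos = (pop.states == POSITIVE).astype(np.int32)
        if pos.any():
            m = adj @ pos
            idx = np.flatnonzero(neutral & (m > 0))
            if idx.size:
                pop.phi_plus[idx] += rng.binomial(m[idx], omega_plus)


def update_opinion(phi_minus: int, phi_plus: int, theta: int) -> int:
    """Threshold rule for a single neutral agent.

    Returns -1 if phi- - phi+ >= theta, +1 if phi- - phi+ <= -theta,
    else 0.  For theta >= 1 the two adoption conditions are mutually
    exclusive.
    """
    diff = phi_minus - phi_plus
    if diff >= theta:
        return NEGATIVE
    if diff <= -theta:
        return POSITIVE
    return NEUTRAL


def _threshold_update(pop: Population, theta: int) -> None:
    """Vectorized synchronous threshold update of all neutral agents."""
    neutral = pop.neutral_mask()
    diff = pop.phi_minus - pop.phi_plus
    pop.states[neutral & (diff >= theta)] = NEGATIVE
    pop.states[neutral & (diff <= -theta)] = POSITIVE


def run_opinion_stage(
    net: "ContactNetwork",
    params: DiffusionParams,
    campaign: Campaign | None,
    rng: np.random.Generator,
    snapshot_hook=None,
) -> tuple[Population, OpinionTrajectory]:
    """Run the full opinion-diffusion stage on ``net``.

    Per step: (1) campaign retargeting/allocation, (2) general exposures,
    (3) social exposures, (4) synchronous threshold update.  Terminates
    after ``tau`` steps, or when no neutral agents remain when
    ``tau == inf``.

    ``snapshot_hook(step, net, pop, campaign)``, if given, is called after
    the update of each step (used for diagnostics such as target
    neighborhood histograms).
    """
    n = net.n_nodes
    pop = initialize_agents(n)
    if params.tau == math.inf:
        no_general = params.mu_minus == 0 and (
            campaign is None or getattr(campaign, "mu_plus", 0) == 0
        )
        if no_general:
            raise ValueError(
                "tau=inf requires a positive general exposure rate on at "
                "least one channel, otherwise the stage cannot terminate"
            )
    zeros = np.zeros(n, dtype=float)
    neg_hist = [0]
    neu_hist = [n]
    pos_hist = [0]
    termination = "tau_reached"
    step = 0
    while True:
        if params.tau != math.inf and step >= params.tau:
            break
        if params.tau == math.inf and not np.any(pop.neutral_mask()):
            termination = "all_adopted"
            break
        if step >= MAX_STEPS:
            raise RuntimeError(
                f"opinion stage exceeded the safety cap of {MAX_STEPS} steps"
            )
        if campaign is not None:
            alloc = campaign.allocation_for_step(step, net, pop, rng)
        else:
            alloc = zeros
        apply_general_exposures(pop, alloc, params.mu_minus, rng)
        apply_social_exposures(pop, net, params.omega_minus, params.omega_plus, rng)
        _threshold_update(pop, params.theta)
        c_neg, c_neu, c_pos = pop.counts()
        neg_hist.append(c_neg)
        neu_hist.append(c_neu)
        pos_hist.append(c_pos)
        if snapshot_hook is not None:
            snapshot_hook(step, net, pop, campaign)
        step += 1
    traj = OpinionTrajectory(
        n_negative=np.array(neg_hist, dtype=np.int64),
        n_neutral=np.array(neu_hist, dtype=np.int64),
        n_positive=np.array(pos_hist, dtype=np.int64),
        termination=termination,
    )
    return pop, traj
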