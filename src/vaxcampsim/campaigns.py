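"""Positive-campaign targeting strategies and budget allocation.

A positive campaign distributes a population-averaged exposure budget mu+
over a target set: each targeted agent i receives

    mu_i+ = T_i * mu+ * N / sum_j T_j,

so the total allocation is always mu+ * N regardless of how many agents
are targeted.  Seven strategies are implemented:

========== ==========================================================
StatRandAll every agent targeted with the uniform allocation mu+
StatRandT   fixed uniform-random subset of size T
StatCentT   the T highest-betweenness nodes (random tie-breaking)
DynRandT    size-T uniform sample of currently neutral agents,
            redrawn every t_r steps
DynAntiT    like DynRandT but restricted to neutral agents with at
            least one anti-vaccine neighbor (random top-up)
DynLocT     the T neutral agents minimizing |n_i^- - zeta|
DynAdvLocT  the T neutral agents minimizing
            |n_i^- - zeta| + |n_i^0 - Z|
========== ==========================================================

Dynamic strategies reselect at steps 0, t_r, 2*t_r, ...; static
strategies select once at step 0 and keep the set (and its allocation)
fixed even if targets later adopt an opinion -- exposures aimed at
committed agents are dropped by the opinion stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .network import betweenness_scores
from .opinion import NEGATIVE, NEUTRAL, Population

if TYPE_CHECKING:
    from .network import ContactNetwork

__all__ = [
    "STRATEGIES",
    "STATIC_STRATEGIES",
    "DYNAMIC_STRATEGIES",
    "CampaignSpec",
    "TargetSet",
    "allocate_positive",
    "select_static_random",
    "select_static_central",
    "select_dynamic_random",
    "select_dyn_anti",
    "score_local",
    "score_advanced",
    "select_by_score",
    "retargeting_schedule",
    "CampaignState",
    "make_campaign",
]

STATIC_STRATEGIES = ("StatRandAll", "StatRandT", "StatCentT")
DYNAMIC_STRATEGIES = ("DynRandT", "DynAntiT", "DynLocT", "DynAdvLocT")
STRATEGIES = STATIC_STRATEGIES + DYNAMIC_STRATEGIES


@dataclass(frozen=True)
class CampaignSpec:
    """Configuration of one positive campaign.

    ``T`` is ignored by StatRandAll (everyone is targeted); ``t_r`` only
    applies to dynamic strategies; ``zeta`` to DynLocT/DynAdvLocT and
    ``z_neutral`` (the target number of neutral neighbors Z) to
    DynAdvLocT only.
    """

    strategy: str
    mu_plus: float
    T: int | None = None
    t_r: int = 1
    zeta: int = 0
    z_neutral: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}"
            )
        if not 0.0 <= self.mu_plus <= 1.0:
            raise ValueError(f"mu_plus must be in [0,1], got {self.mu_plus}")
        if self.strategy != "StatRandAll":
            if self.T is None or self.T < 1:
                raise ValueError(f"{self.strategy} requires a target size T >= 1")
        if self.t_r < 1:
            raise ValueError(f"t_r must be >= 1, got {self.t_r}")
        if self.zeta < 0 or self.z_neutral < 0:
            raise ValueError("zeta and Z must be >= 0")

    @property
    def is_dynamic(self) -> bool:
        return self.strategy in DYNAMIC_STRATEGIES


@dataclass
class TargetSet:
    """Indicator vector, per-agent positive allocation, and selection step."""

    indicators: np.ndarray  # bool per agent
    allocation: np.ndarray  # float per agent, sums to mu_plus * N
    selection_step: int = 0

    @property
    def size(self) -> int:
        return int(self.indicators.sum())

    def node_ids(self) -> np.ndarray:
        return np.flatnonzero(self.indicators)


def allocate_positive(
    indicators: np.ndarray, mu_plus: float, n: int
) -> np.ndarray:
    """Budget rule mu_i+ = T_i * mu+ * N / sum(T_i).

    Raises if the target set is empty while mu+ > 0, or if the per-target
    allocation exceeds 1 (not a valid probability).
    """
    indicators = np.asarray(indicators, dtype=bool)
    if len(indicators) != n:
        raise ValueError("indicator vector length must equal N")
    t_sum = int(indicators.sum())
    alloc = np.zeros(n, dtype=float)
    if mu_plus == 0:
        return alloc
    if t_sum == 0:
        raise ValueError("positive budget mu_plus > 0 with an empty target set")
    per_target = mu_plus * n / t_sum
    if per_target > 1.0:
        raise ValueError(
            f"per-target allocation mu_plus*N/|T| = {mu_plus}*{n}/{t_sum} "
            f"= {per_target:.4g} exceeds 1 and is not a valid probability"
        )
    alloc[indicators] = per_target
    return alloc


def _as_target_set(
    chosen: np.ndarray, mu_plus: float, n: int, step: int, nominal_t: int | None = None
) -> TargetSet:
    """Wrap a chosen node array into a TargetSet with its allocation.

    A dynamic strategy may come up short of its nominal T late in a run
    (fewer neutral agents remain than targets requested); the set may even
    be empty, making the campaign inert for the interval.  In the
    shortfall case the per-target allocation is capped at probability 1 --
    the excess budget is wasted rather than raising, since the shortfall
    is a state of the dynamics, not a misconfiguration.
    """
    ind = np.zeros(n, dtype=bool)
    ind[chosen] = True
    t_sum = int(ind.sum())
    if mu_plus == 0 or t_sum == 0:
        alloc = np.zeros(n, dtype=float)
    elif nominal_t is not None and t_sum < nominal_t:
        alloc = np.zeros(n, dtype=float)
        alloc[ind] = min(1.0, mu_plus * n / t_sum)
    else:
        alloc = allocate_positive(ind, mu_plus, n)
    return TargetSet(indicators=ind, allocation=alloc, selection_step=step)


def select_static_random(
    net: "ContactNetwork", t_size: int, mu_plus: float, rng: np.random.Generator
) -> TargetSet:
    """Fixed uniform sample of ``t_size`` agents from the whole population."""
    if t_size > net.n_nodes:
        raise ValueError(f"T={t_size} exceeds population size {net.n_nodes}")
    chosen = rng.choice(net.n_nodes, size=t_size, replace=False)
    return _as_target_set(chosen, mu_plus, net.n_nodes, 0)


def select_static_central(
    net: "ContactNetwork",
    centrality: np.ndarray,
    t_size: int,
    mu_plus: float,
    rng: np.random.Generator,
) -> TargetSet:
    """The ``t_size`` highest-betweenness nodes, boundary ties broken
    uniformly at random."""
    n = net.n_nodes
    if t_size > n:
        raise ValueError(f"T={t_size} exceeds population size {n}")
    if len(centrality) != n:
        raise ValueError("centrality table must cover every node")
    # random secondary key => uniform tie-breaking at the cut boundary
    tiebreak = rng.permutation(n)
    order = np.lexsort((tiebreak, -np.asarray(centrality, dtype=float)))
    return _as_target_set(order[:t_size], mu_plus, n, 0)


def select_dynamic_random(
    pop: Population, t_size: int, mu_plus: float, rng: np.random.Generator, step: int
) -> TargetSet:
    """Uniform sample of min(T, #neutral) currently neutral agents."""
    neutral = np.flatnonzero(pop.states == NEUTRAL)
    k = min(t_size, len(neutral))
    chosen = rng.choice(neutral, size=k, replace=False) if k else np.empty(0, int)
    return _as_target_set(chosen, mu_plus, pop.n, step, nominal_t=t_size)


def select_dyn_anti(
    net: "ContactNetwork",
    pop: Population,
    t_size: int,
    mu_plus: float,
    rng: np.random.Generator,
    step: int,
) -> TargetSet:
    """Uniform sample of neutral agents with >= 1 anti-vaccine neighbor,
    topped up with uniform random other neutral agents when fewer than T
    are eligible."""
    neutral = pop.states == NEUTRAL
    neg_counts = net.adjacency @ (pop.states == NEGATIVE).astype(np.int32)
    eligible = np.flatnonzero(neutral & (neg_counts >= 1))
    rest = np.flatnonzero(neutral & (neg_counts == 0))
    k = min(t_size, len(eligible))
    chosen = rng.choice(eligible, size=k, replace=False) if k else np.empty(0, int)
    short = t_size - k
    if short > 0 and len(rest):
        extra = rng.choice(rest, size=min(short, len(rest)), replace=False)
        chosen = np.concatenate([chosen, extra])
    return _as_target_set(chosen, mu_plus, pop.n, step, nominal_t=t_size)


def score_local(n_minus: np.ndarray | int, zeta: int) -> np.ndarray | int:
    """Single-objective score g_i(zeta) = |n_i^- - zeta|."""
    return np.abs(np.asarray(n_minus) - zeta)


def score_advanced(
    n_minus: np.ndarray | int, n_zero: np.ndarray | int, zeta: int, z_neutral: int
) -> np.ndarray | int:
    """Multi-objective score g_i(zeta, Z) = |n_i^- - zeta| + |n_i^0 - Z|."""
    return np.abs(np.asarray(n_minus) - zeta) + np.abs(np.asarray(n_zero) - z_neutral)


def select_by_score(
    node_ids: np.ndarray,
    scores: np.ndarray,
    t_size: int,
    pop: Population,
    mu_plus: float,
    rng: np.random.Generator,
    step: int,
) -> TargetSet:
    """Ascending-score selection of ``t_size`` agents.

    ``node_ids``/``scores`` are the scored (neutral) candidates.  Ties at
    the cut boundary are broken uniformly at random.  If fewer than T
    candidates were scored, the shortfall is filled uniformly at random
    from the remaining neutral agents.
    """
    node_ids = np.asarray(node_ids)
    scores = np.asarray(scores, dtype=float)
    k = min(t_size, len(node_ids))
    if k:
        tiebreak = rng.permutation(len(node_ids))
        order = np.lexsort((tiebreak, scores))
        chosen = node_ids[order[:k]]
    else:
        chosen = np.empty(0, int)
    short = t_size - k
    if short > 0:
        neutral = np.flatnonzero(pop.states == NEUTRAL)
        rest = np.setdiff1d(neutral, chosen, assume_unique=False)
        if len(rest):
            extra = rng.choice(rest, size=min(short, len(rest)), replace=False)
            chosen = np.concatenate([chosen, extra])
    return _as_target_set(chosen, mu_plus, pop.n, step, nominal_t=t_size)


def retargeting_schedule(spec: CampaignSpec, step: int) -> bool:
    """True when the target set must be (re)selected at ``step``.

    Dynamic strategies reselect at steps 0, t_r, 2*t_r, ...; static
    strategies select only at step 0.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    if not spec.is_dynamic:
        return step == 0
    return step % spec.t_r == 0


class CampaignState:
    """Stateful campaign engine driven by the opinion stage.

    Holds the current :class:`TargetSet` and recomputes it according to
    the strategy's retargeting schedule; exposes the per-agent positive
    allocation for each step.  Betweenness for StatCentT is computed once
    per network at first use.
    """

    def __init__(self, spec: CampaignSpec):
        self.spec = spec
        self.target_set: TargetSet | None = None
        self.history: list[tuple[int, np.ndarray]] = []
        self.record_history = False

    @property
    def mu_plus(self) -> float:
        return self.spec.mu_plus

    def _select(
        self,
        step: int,
        net: "ContactNetwork",
        pop: Population,
        rng: np.random.Generator,
    ) -> TargetSet:
        spec = self.spec
        n = pop.n
        if spec.strategy == "StatRandAll":
            ind = np.ones(n, dtype=bool)
            return TargetSet(ind, allocate_positive(ind, spec.mu_plus, n), step)
        if spec.strategy == "StatRandT":
            return select_static_random(net, spec.T, spec.mu_plus, rng)
        if spec.strategy == "StatCentT":
            centrality = betweenness_scores(net)
            return select_static_central(net, centrality, spec.T, spec.mu_plus, rng)
        if spec.strategy == "DynRandT":
            return select_dynamic_random(pop, spec.T, spec.mu_plus, rng, step)
        if spec.strategy == "DynAntiT":
            return select_dyn_anti(net, pop, spec.T, spec.mu_plus, rng, step)
        # score-based strategies: score every currently neutral agent
        neutral_ids = np.flatnonzero(pop.states == NEUTRAL)
        adj = net.adjacency
        n_minus = (adj @ (pop.states == NEGATIVE).astype(np.int32))[neutral_ids]
        if spec.strategy == "DynLocT":
            scores = score_local(n_minus, spec.zeta)
        else:  # DynAdvLocT
            n_zero = (adj @ (pop.states == NEUTRAL).astype(np.int32))[neutral_ids]
            scores = score_advanced(n_minus, n_zero, spec.zeta, spec.z_neutral)
        return select_by_score(
            neutral_ids, scores, spec.T, pop, spec.mu_plus, rng, step
        )

    def allocation_for_step(
        self,
        step: int,
        net: "ContactNetwork",
        pop: Population,
        rng: np.random.Generator,
    ) -> np.ndarray:
        if retargeting_schedule(self.spec, step) or self.target_set is None:
            self.target_set = self._select(step, net, pop, rng)
            if self.record_history:
                self.history.append((step, self.target_set.node_ids().copy()))
        return self.target_set.allocation


def make_campaign(spec: CampaignSpec | None) -> CampaignState | None:
    """Build the campaign engine for a spec (``None`` -> no campaign)."""
    return None if spec is None else CampaignState(spec)
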