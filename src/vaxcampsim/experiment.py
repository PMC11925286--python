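"""Scenario configuration, replication, aggregation and parameter sweeps.

A *scenario* is one fully specified parameter point.  Replication follows
the two-level design of the study: ``n_networks`` independent contact
networks are generated, the opinion stage and vaccination are run once per
network, and ``n_sir_runs`` independent SIR outbreaks are simulated on
each vaccinated network.  The reported epidemic size is the mean of S_r
pooled over all networks x runs, with a 95% normal-approximation
confidence interval; per-network means are kept so users can also form
network-level intervals or decompose variance.

All randomness derives from a single ``master_seed`` through
``numpy.random.SeedSequence`` spawning: one child stream per network
(driving network generation and the opinion stage) and one per SIR run.
Replicate streams are independent, so replicates may be evaluated in any
order; sweeps reuse the same spawning layout at every parameter point,
giving common random numbers across points.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .campaigns import CampaignSpec, CampaignState, make_campaign
from .network import ContactNetwork, components_of_subset, generate_watts_strogatz
from .opinion import DiffusionParams, OpinionTrajectory, Population, run_opinion_stage
from .sir import EpidemicResult, SIRParams, run_sir, vaccinate

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "AggregateResult",
    "run_replicate",
    "run_scenario",
    "run_sweep",
    "SWEEP_AXES",
]

SWEEP_AXES = ("omega", "omega_minus", "omega_plus", "mu_plus", "mu_minus",
              "t_r", "zeta", "Z", "T", "tau", "theta")


@dataclass(frozen=True)
class SimulationConfig:
    """One scenario: network, diffusion, campaign and SIR parameters plus
    the replication design."""

    n: int = 5000
    k: int = 10
    p: float = 0.01
    diffusion: DiffusionParams = field(
        default_factory=lambda: DiffusionParams(
            mu_minus=0.001, omega_minus=0.006, omega_plus=0.006, theta=2,
            tau=math.inf,
        )
    )
    campaign: CampaignSpec | None = None
    sir: SIRParams = field(default_factory=lambda: SIRParams(beta=0.1, gamma=0.1, i0=1))
    n_networks: int = 500
    n_sir_runs: int = 500
    master_seed: int = 0
    require_connected: bool = False
    reps_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_networks < 1 or self.n_sir_runs < 1:
            raise ValueError("replication counts must be >= 1")
        if self.reps_scale <= 0:
            raise ValueError("reps_scale must be positive")

    @property
    def effective_n_networks(self) -> int:
        return max(1, round(self.n_networks * self.reps_scale))

    @property
    def effective_n_sir_runs(self) -> int:
        return max(1, round(self.n_sir_runs * self.reps_scale))


@dataclass
class SimulationResult:
    """One replicate: final epidemic size plus diagnostics."""

    s_r: int
    n_anti: int
    epidemic: EpidemicResult
    trajectory: OpinionTrajectory
    population: Population
    network: ContactNetwork
    anti_cluster_sizes: list[int]


@dataclass
class AggregateResult:
    """Pooled mean epidemic size and 95% CI for one scenario."""

    mean_s_r: float
    ci95_halfwidth: float
    n_replicates: int
    scenario_key: dict
    per_network_means: np.ndarray
    replicates: np.ndarray  # shape (n_networks, n_sir_runs)


def _generate_network(
    config: SimulationConfig, rng: np.random.Generator
) -> ContactNetwork:
    while True:
        net = generate_watts_strogatz(config.n, config.k, config.p, rng)
        if not config.require_connected:
            return net
        comps = components_of_subset(net, range(net.n_nodes))
        if len(comps) == 1:
            return net


def _opinion_and_vaccination(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ContactNetwork, Population, OpinionTrajectory, np.ndarray, CampaignState | None]:
    net = _generate_network(config, rng)
    campaign = make_campaign(config.campaign)
    pop, traj = run_opinion_stage(net, config.diffusion, campaign, rng)
    susceptible = vaccinate(pop)
    return net, pop, traj, susceptible, campaign


def run_replicate(
    config: SimulationConfig, network_seed, sir_seed
) -> SimulationResult:
    """One network generation -> opinion stage -> vaccination -> one SIR run.

    ``network_seed`` drives the network and opinion stage; ``sir_seed``
    the outbreak, so several SIR runs can share one opinion realization.
    """
    rng = np.random.default_rng(network_seed)
    net, pop, traj, susceptible, _ = _opinion_and_vaccination(config, rng)
    epi = run_sir(net, susceptible, config.sir, np.random.default_rng(sir_seed))
    clusters = sorted(
        (len(c) for c in components_of_subset(net, susceptible)), reverse=True
    )
    return SimulationResult(
        s_r=epi.s_r,
        n_anti=len(susceptible),
        epidemic=epi,
        trajectory=traj,
        population=pop,
        network=net,
        anti_cluster_sizes=clusters,
    )


def run_scenario(
    config: SimulationConfig, scenario_key: dict | None = None
) -> AggregateResult:
    """Full replication of one scenario.

    The opinion-stage outcome is reused across the SIR runs on the same
    network; the CI pools all networks x runs replicates.
    """
    n_nets = config.effective_n_networks
    n_runs = config.effective_n_sir_runs
    root = np.random.SeedSequence(config.master_seed)
    net_seqs = root.spawn(n_nets)
    replicates = np.empty((n_nets, n_runs), dtype=np.int64)
    for i, net_seq in enumerate(net_seqs):
        children = net_seq.spawn(n_runs + 1)
        rng = np.random.default_rng(children[0])
        net, pop, traj, susceptible, _ = _opinion_and_vaccination(config, rng)
        for j in range(n_runs):
            epi = run_sir(net, susceptible, config.sir, np.random.default_rng(children[j + 1]))
            replicates[i, j] = epi.s_r
    flat = replicates.ravel().astype(float)
    mean = float(flat.mean())
    sd = float(flat.std(ddof=1)) if flat.size > 1 else 0.0
    ci95 = 1.96 * sd / math.sqrt(flat.size)
    return AggregateResult(
        mean_s_r=mean,
        ci95_halfwidth=ci95,
        n_replicates=int(flat.size),
        scenario_key=dict(scenario_key or {}),
        per_network_means=replicates.mean(axis=1),
        replicates=replicates,
    )


def _apply_axis(config: SimulationConfig, axis: str, value) -> SimulationConfig:
    d = config.diffusion
    c = config.campaign
    if axis == "omega":
        d = dataclasses.replace(d, omega_minus=value, omega_plus=value)
    elif axis in ("omega_minus", "omega_plus", "mu_minus", "theta", "tau"):
        d = dataclasses.replace(d, **{axis: value})
    elif axis in ("mu_plus", "t_r", "zeta", "T"):
        if c is None:
            raise ValueError(f"axis {axis!r} requires a campaign in the base config")
        c = dataclasses.replace(c, **{axis: value})
    elif axis == "Z":
        if c is None:
            raise ValueError("axis 'Z' requires a campaign in the base config")
        c = dataclasses.replace(c, z_neutral=value)
    else:
        raise ValueError(f"unknown sweep axis {axis!r}; choose from {SWEEP_AXES}")
    return dataclasses.replace(config, diffusion=d, campaign=c)


def run_sweep(
    config: SimulationConfig, axis: str, values: list
) -> list[AggregateResult]:
    """Run one scenario per value of ``axis``, in input order.

    Every point reuses the same seed-spawning layout (common random
    numbers), so differences between points are not confounded by network
    realizations.
    """
    results = []
    for v in values:
        point = _apply_axis(config, axis, v)
        results.append(run_scenario(point, scenario_key={axis: v}))
    return results
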