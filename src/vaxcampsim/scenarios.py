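"""Benchmark scenario catalogue.

The study conditions used throughout the package's benchmark experiments:
N=5000 Watts-Strogatz contact networks with mean degree 10 and rewiring
probability 0.01, negative general exposure mu- = 0.001, opinion threshold
theta = 2, and SIR with beta = gamma = 0.1 seeded at one random
anti-vaccine agent.  Each entry fixes one campaign configuration at one
parameter point; replication counts and the master seed are supplied by
the caller.

The opinion threshold default of 2 is the smallest value consistent with
complex contagion (at least two net exposures to commit) and is the value
under which the no-campaign benchmark reproduces its reference epidemic
size; see docs/methods.md for the calibration argument.
"""

from __future__ import annotations

import math

from .campaigns import CampaignSpec
from .experiment import SimulationConfig
from .opinion import DiffusionParams
from .sir import SIRParams

__all__ = ["benchmark_config", "BENCHMARKS"]

_INF = math.inf


def _diff(omega: float, tau) -> DiffusionParams:
    return DiffusionParams(mu_minus=0.001, omega_minus=omega,
                           omega_plus=omega, theta=2, tau=tau)


#: name -> (DiffusionParams, CampaignSpec | None)
BENCHMARKS: dict[str, tuple[DiffusionParams, CampaignSpec | None]] = {
    # short-run (tau=400) scenarios at the highest social rate omega=0.01
    "anti_only_tau400": (_diff(0.01, 400), None),
    "stat_rand_all": (_diff(0.01, 400), CampaignSpec("StatRandAll", 0.001)),
    "stat_rand_t": (_diff(0.01, 400), CampaignSpec("StatRandT", 0.001, T=500)),
    "stat_cent_t": (_diff(0.01, 400), CampaignSpec("StatCentT", 0.001, T=500)),
    # long-run (tau=inf) dynamic scenarios at omega=0.006
    "dyn_anti_t_fast": (
        _diff(0.006, _INF), CampaignSpec("DynAntiT", 0.001, T=50, t_r=1)),
    "dyn_rand_t_fast": (
        _diff(0.006, _INF), CampaignSpec("DynRandT", 0.001, T=50, t_r=1)),
    "dyn_anti_t_strong": (
        _diff(0.006, _INF), CampaignSpec("DynAntiT", 0.002, T=50, t_r=1)),
    "dyn_rand_t_strong": (
        _diff(0.006, _INF), CampaignSpec("DynRandT", 0.002, T=50, t_r=1)),
    "dyn_loc_t_zeta1": (
        _diff(0.006, _INF),
        CampaignSpec("DynLocT", 0.002, T=50, t_r=1, zeta=1)),
    "dyn_loc_t_zeta8": (
        _diff(0.006, _INF),
        CampaignSpec("DynLocT", 0.002, T=50, t_r=1, zeta=8)),
    "dyn_adv_loc_t_fast": (
        _diff(0.006, _INF),
        CampaignSpec("DynAdvLocT", 0.001, T=50, t_r=1, zeta=10, z_neutral=10)),
    # weak-budget cross-campaign comparison (mu+ = 0.0006)
    "dyn_adv_loc_t_slow_weak": (
        _diff(0.006, _INF),
        CampaignSpec("DynAdvLocT", 0.0006, T=50, t_r=20, zeta=10, z_neutral=10)),
    "stat_cent_t_weak": (
        _diff(0.006, _INF), CampaignSpec("StatCentT", 0.0006, T=500)),
    "dyn_anti_t_slow_weak": (
        _diff(0.006, _INF), CampaignSpec("DynAntiT", 0.0006, T=50, t_r=20)),
    # uniform campaign at the long-run dynamic setting (strategy-ordering
    # reference point: mu+ = mu- = 0.001, omega = 0.006)
    "stat_rand_all_long": (
        _diff(0.006, _INF), CampaignSpec("StatRandAll", 0.001)),
}


def benchmark_config(
    name: str,
    n_networks: int,
    n_sir_runs: int,
    master_seed: int,
) -> SimulationConfig:
    """Build the full configuration for a named benchmark scenario."""
    try:
        diffusion, campaign = BENCHMARKS[name]
    except KeyError:
        raise ValueError(
            f"unknown benchmark {name!r}; choose from {sorted(BENCHMARKS)}"
        ) from None
    return SimulationConfig(
        n=5000,
        k=10,
        p=0.01,
        diffusion=diffusion,
        campaign=campaign,
        sir=SIRParams(beta=0.1, gamma=0.1, i0=1),
        n_networks=n_networks,
        n_sir_runs=n_sir_runs,
        master_seed=master_seed,
    )
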