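# DynAntiT benchmark point: dynamic anti-neighbor targeting, fast updates
N: 5000
k: 10
p: 0.01
mu_minus: 0.001
mu_plus: 0.001
omega: 0.006
theta: 2
tau: inf
strategy: DynAntiT
T: 50
t_r: 1
beta: 0.1
gamma: 0.1
I0: 1
n_networks: 500
n_sir_runs: 500
master_seed: 1
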