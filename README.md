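# evograph

Moran evolutionary dynamics on graph-structured populations: exact and
Monte Carlo fixation probabilities under four update rules, classification
of graphs as amplifiers/suppressors of selection or fixation, and
long-term weak-mutation (origin-fixation) dynamics with steady-state
fitness statistics and effective-population-size estimation.

## Concepts

A population lives on an undirected, unweighted graph, one individual per
node. The update rule combines the order of birth and death events (`Bd`:
fitness-proportional birth then uniform neighbour death; `dB`: uniform
death then fitness-proportional neighbour birth) with the choice of which
daughter cell moves to the vacated node (`o` offspring, `p` parent). The
mover does not change the mutation-free dynamics but controls where the
first mutant appears: `Bd-o` and `dB-p` are temperature-initialised
(high-turnover nodes more likely), `Bd-p` and `dB-o` are uniform. Mixed
movement `Bd-mix:<λ>` / `dB-mix:<λ>` interpolates.

Modules:

- `evograph.graph_core` — `Graph`, named generators (star, cycle,
  complete, 2-D grid), connected Erdős-Rényi rejection sampling, node
  temperatures.
- `evograph.update_rules` — rules, initialisation distributions, one-step
  transition kernel on mutant configurations.
- `evograph.fixation_exact` — full-configuration absorbing-chain solver
  (any small connected graph), reduced-chain star solver (N up to ~10^4),
  complete-graph and star closed forms, large-N limits.
- `evograph.fixation_mc` — forward simulation of the update kernels.
- `evograph.classification` — fixation profiles over a fitness grid and
  the AoS / SoS / AoF / piecewise-AoF / SoF / isothermal / other
  classification relative to the complete graph; ER censuses.
- `evograph.longterm` — fixation-ratio Ψ, power-law exponent ν fitting,
  House-of-Cards steady states, discrete-fitness-chain stationary
  distributions (direct global-balance solve), origin-fixation Monte
  Carlo.
- `evograph.cli_io` — CLI, graph readers/writers (edge list, dense
  adjacency, named specs), TSV/JSON result writers.

## CLI

A single `evograph` executable with subcommands. Graphs are named specs
(`star:8`, `cycle:8`, `complete:8`, `grid2d:3x4:periodic`,
`er:8:0.5:<seed>`) or files (edge list or 0/1 adjacency matrix). Exit
codes: 0 success, 2 validation error, 3 capacity/sampling failure.

```sh
# fixation probabilities (exact solver) over a fitness list
evograph fixation --graph star:8 --rule dB-p --fprime 0.5,1,2 --method exact

# closed forms / reduced star chain / Monte Carlo
evograph fixation --graph complete:8 --rule dB-o --fprime 2 --method closed
evograph fixation --graph star:2000 --rule dB-p --fprime 0.8 --method reduced
evograph fixation --graph star:8 --rule dB-p --fprime 2 --method mc --reps 2000 --seed 1

# classify one graph; census a sample of connected ER graphs
evograph classify --graph star:8 --rule Bd-o
evograph census --n 8 --p 0.5 --samples 200 --rule dB-p --seed 7 --out-json census.json

# long-term steady state: discrete fitness chain or HoC interval
evograph longterm --graph complete:8 --rule dB-o --grid 0.5:2:0.25 --method solve
evograph longterm --graph star:8 --rule dB-p --hoc 1,10 --method mc --steps 100000 --seed 3
```

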