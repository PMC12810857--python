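# trigame

A tripartite evolutionary game of healthcare-safety supervision, built for
researchers and policy analysts who study how public participation shapes
medical compliance. Three bounded-rational populations interact: the
**public** chooses whether to participate in safety supervision (frequency
δ), **medical institutions** choose compliant or non-compliant care
(frequency η), and **government regulators** choose strict or lax
supervision (frequency ζ). The package provides the replicator dynamics of
this game, closed-form stability analysis of its corner equilibria,
parameter-effect experiments (sweeps, critical-threshold scans,
variance-based sensitivity indices), and three bundled case-study fixtures
(TB treatment adherence in Saudi Arabia, COVID-19 vaccination compliance in
Guangdong, antibiotic prescription supervision in rural Vietnam).

## The model

Each population's strategy frequency grows in proportion to the payoff
advantage of that strategy over its population mean (replicator dynamics):

```
dδ/dt = δ(1−δ) [ Ip1 − Ip2 + (1−η)(1−ζ) μ Bp ]
dη/dt = η(1−η) [ −Cm1 − Im2 + Cm2 + (1−ζ) Cc + δ μ Bm + ζ θ Vm2 ]
dζ/dt = ζ(1−ζ) [ W + (1−η) θ Vm2 + (1−η) δ μ Bg − (1−η) Ig2 ]
```

where μ is the exposure rate (probability that participation reveals a
violation), θ the penalty intensity scaling the medical risk Vm2 into the
fine θVm2, Bm the reputational damage of exposure, Cc the cost of capturing
a lax regulator, and the remaining constants are payoffs/costs in normalized
units (see `GameParameters`). The system has eight corner fixed points
E1(0,0,0) … E8(1,1,1); at a corner the Jacobian is diagonal, so a corner is
an evolutionarily stable strategy (ESS) exactly when its three diagonal
eigenvalues are negative (Lyapunov's first method).

Under the reference parameterization (`trigame.BASELINE`: Ip1=30, Ip2=20,
μ=0.8, Bp=15, Im1=40, Cm1=30, Im2=20, Cm2=15, θ=0.6, Vm2=20, Bm=70, Cc=15,
Ig1=30, W=25, Cg1=15, Ig2=20, Bg=25) the unique ESS is the fully cooperative
corner E8(1,1,1).

## Worked example

```python
from trigame import BASELINE, StrategyState, integrate, detect_convergence, ess_set

traj = integrate(StrategyState(0.5, 0.5, 0.5), BASELINE, horizon=200)
final = traj.final_state()
print(final.delta, final.eta, final.zeta)   # 0.9999999... 1.0 1.0
print(detect_convergence(traj))             # E8
print(ess_set(BASELINE))                    # {'E8'}
```

Starting from the midpoint of the strategy cube, participation, compliance
and strict supervision all converge to 1: the population ends at the
cooperative corner E8, the game's unique ESS. Lowering the reputational
damage and the penalty (`BASELINE.replace(bm=10, theta=0.3)`) flips the
outcome to E6(1,0,1) — the public still participates and regulators still
supervise, but compliance dies out. Running
`python examples/exposure_threshold.py` prints the critical exposure rate at
which the attractor flips:

```
published-table stability boundary: mu* = 0.2857 (= 2/7)
dynamic attractor flip:             mu* = 0.3282 (= 23/70)
```

(the two boundaries differ by a documented inconsistency in the published
eigenvalue table; see `docs/methods.md`). The `examples/` directory holds
one short narrative script per capability: baseline convergence, equilibrium
classification, the exposure threshold, sensitivity ranking, and the case
studies.

A thin CLI mirrors the library:

```sh
trigame simulate --init 0.5,0.5,0.5 --horizon 200 --out traj.csv
trigame stability --out stability.json
trigame sweep --param theta --grid 0.2:0.8:0.1 --metric final_eta --out sweep.csv
trigame sensitivity --n 256 --seed 7 --out sens.json
trigame cases run --name guangdong_covid --out case.csv
trigame sample-params --constraint cond2 --n 5 --seed 1 --out params.json
```

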