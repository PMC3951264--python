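# atherosim

A free-boundary finite-element simulator of early atherosclerotic plaque
growth, driven by the blood LDL/HDL profile.

Atherosclerosis begins when low-density lipoprotein (LDL) leaks through a
lesioned endothelium into the arterial intima and is oxidised by free
radicals.  Ox-LDL recruits monocytes, which become macrophages, ingest
the ox-LDL and turn into foam cells; cytokines (MCP-1, IL-12, IFN-γ,
PDGF) recruit and activate T cells and smooth muscle cells, while HDL
limits the inflammation.  `atherosim` integrates this 14-species
reaction–advection–diffusion network in an evolving 2D intima domain: the
cells form an incompressible mixture with the extracellular matrix
(`M + T + S + F + ρ = 1 g/cm³`), cell production drives a Darcy flow
`u = −∇σ` with `−Δσ = f + g`, and the lumen-facing free boundary moves
with `V_n = −∂σ/∂n` under the adhesion condition `σ = γκ`.

The headline observable is the plaque weight `W = ∫(M+T+S+F) dx`.  On top
of single scenarios the package builds the study's two main analyses:

* a **risk map** of the relative weight change after 100 days over the
  (LDL, HDL) plane, partitioned into high-risk (I), low-risk (II) and
  no-risk (III) regions, and
* a **global sensitivity study**: Latin hypercube sampling over the
  tabulated parameter ranges with partial rank correlation coefficients
  (PRCC) of each parameter against the final plaque weight.

The model equations, parameter provenance, numerics and the fixture
conventions are documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
from atherosim import run_scenario

high = run_scenario(L0=190, H0=40, horizon=300)   # mg/dL, days
low = run_scenario(L0=70, H0=60, horizon=300)
print(f"high-risk : W(300)/W(0) = {high.weights[-1]/high.w0:.2f}")
print(f"low-risk  : W(300)/W(0) = {low.weights[-1]/low.w0:.2f}")
```

prints (default fixture, 1.1k-node mesh, dt = 0.5 day):

```
high-risk : W(300)/W(0) = 2.09
low-risk  : W(300)/W(0) = 0.24
```

i.e. an established small plaque roughly doubles in 300 days under
(LDL, HDL) = (190, 40) mg/dL and loses three quarters of its weight under
(70, 60).  A reduced risk map and the sensitivity study:

```python
import numpy as np
from atherosim import sweep, run_sensitivity

rm = sweep(np.linspace(70, 190, 5), np.linspace(40, 60, 3), horizon=100, h=5e-3)
print(rm.labels)           # region I/II/III per grid cell
res, design, outputs = run_sensitivity(n=60, seed=1, horizon=100, h=5e-3, dt=1.0)
print(res.to_frame().sort_values("prcc"))
```

The risk-map labels reproduce the qualitative structure of the published
map — growth monotone increasing in LDL, decreasing in HDL, with
(190, 40) in region I and (70, 60) in region III — and the PRCC table
shows blood LDL and its influx rate as the strongest promoters and blood
HDL and its influx rate as the strongest protectors of plaque growth.

There is also a CLI:

```sh
atherosim simulate --L0 190 --H0 40 --days 300 --out results/
atherosim riskmap --l-grid 70:190:5 --h-grid 40:60:3 --days 100 --out results/
atherosim sensitivity --n 60 --seed 42 --days 100 --coarse --out results/
atherosim dump-defaults --out defaults.csv
```

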