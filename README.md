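# latticetx

Stochastic, 2-D on-lattice simulation of competition between drug-sensitive
and drug-resistant tumour cells under continuous and adaptive therapy,
together with its non-spatial Lotka–Volterra twin and machinery for fitting
the model to longitudinal tumour-burden series (e.g. normalised PSA from
intermittent androgen-deprivation trials).

## The model

A small region of tumour tissue is an `l × l` square lattice (no-flux
boundaries, single occupancy).  Each site is empty or holds one cell, either
drug-**sensitive** (S) or fully drug-**resistant** (R):

- Sensitive cells attempt division at rate `r_S` (d⁻¹), resistant cells at
  `r_R = (1 − c_R) r_S`, where `c_R ∈ [0, 1]` is the *cost of resistance*.
- A dividing cell places its daughter uniformly at random into an empty site
  of its von Neumann neighbourhood; with no empty neighbour the attempt is
  *blocked* — this crowding is the only interaction between cells.
- Both types die at rate `δ_T = d_T · r_S` (*turnover* `d_T` is expressed
  relative to the proliferation rate); dead cells are removed immediately.
- Drug `D(t) ∈ [0, D_max]` is spatially homogeneous and kills a sensitive
  cell *caught in mitosis* with probability `d_D D(t)/D_max`.

Two schedules are built in: **continuous** therapy at the maximum tolerated
dose, and **adaptive** therapy, which withdraws drug once the burden `N(t)`
has dropped 50% below its pre-treatment baseline and re-instates it when the
baseline is reached again (a 30% withdrawal variant is included).
*Progression* is a 20% rise of `N` above baseline, at least 150 days after
the start of treatment; *time to progression* (TTP) is its first occurrence.

The mean-field twin replaces the lattice with logistic competition at
carrying capacity `K = l²`:

    dS/dt = r_S (1 − (S+R)/K)(1 − 2 d_D D/D_max) S − δ_T S
    dR/dt = r_R (1 − (S+R)/K) R − δ_T R

Competition instruments (blocked-division fraction, resistant-neighbourhood
composition, per-capita net growth, nest components and convexity) quantify
how inter- and intra-specific crowding suppress the resistant population.

## Worked example

One matched pair — the same tumour (identical parameters, initial lattice
and random streams) treated once continuously and once adaptively:

```python
from latticetx import SimParams, matched_pair

params = SimParams(n0=0.75, f_R=0.001, c_R=0.0, d_T=0.0)  # 100x100 lattice
pair = matched_pair(params, "random", seed=1)
print(f"TTP continuous: {pair.ttp_CT:.0f} d")
print(f"TTP adaptive:   {pair.ttp_AT:.0f} d")
print(f"gain: {pair.gain_months:.1f} months over {pair.n_cycles_AT} cycles")
```

prints

```
TTP continuous: 1646 d
TTP adaptive:   2106 d
gain: 15.1 months over 6 cycles
```

Starting from 7500 cells (75% density, eight of them resistant), continuous
dosing clears the sensitive population and releases the resistant colonies,
which reach 120% of baseline after ~4.5 years; the adaptive controller
cycles the drug six times, keeping sensitive competitors in place to box the
resistant nests in, and delays progression by about 15 months.  The same
machinery drives parameter sweeps (`sweep`), nest-separation experiments
(`two_nests`), growth-law comparisons against the logistic closed form
(`growth_law_comparison`) and burden-series fitting (`fit_patient`).

A CLI mirrors the library:

```
latticetx simulate --config params.txt --protocol at50 --seed 1 --out run/
latticetx pair --config params.txt --seed 1
latticetx synthcohort --n 10 --noise 0.1 --seed 1 --out cohort.csv
latticetx fit --series cohort.csv --model 3 --engine ode --out fits/
```

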