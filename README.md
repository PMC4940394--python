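# dsdesign

System design space analysis of biochemical networks: deconstruct an
intractable nonlinear model into its tractable *dominant subsystems*,
enumerate every qualitatively distinct phenotype the architecture can
express, and then **predict** parameter values that realize phenotypes of
interest — multistable switches, co-localized regimes, counters — instead of
estimating parameters first and exploring locally.

The toolkit is aimed at systems and synthetic biologists working with
mechanistic ODE models built from chemical kinetics and rational
(Michaelis–Menten/Hill-type) rate laws: gene circuits, signalling cascades,
metabolic modules.

## The method

Any such model can be recast exactly into **generalized mass action (GMA)**
form — ODEs plus algebraic constraints in which every term is a product of
power laws:

```
dX_i/dt = Σ_k α_ik Π_j X_j^g_ijk  −  Σ_k β_ik Π_j X_j^h_ijk
      0 = Σ_k α_ik Π_j X_j^g_ijk  −  Σ_k β_ik Π_j X_j^h_ijk
```

Each multi-term denominator of a rational rate law becomes one auxiliary
variable with a zero-constraint. At any point of the combined state +
parameter space each equation has one dominant positive and one dominant
negative term; the index list `[p₁ q₁ … p_n q_n]` is the **case signature**.
Retaining only dominant terms yields an **S-system**, whose steady state is
linear in logarithms: solving `G y + a = H y + b` gives each dependent
variable as an affine function of the log-parameters, and the coefficient
matrix *is* the table of logarithmic gains `L(X_i, X_j) = ∂log X_i/∂log X_j`
— exact rationals determined by kinetic orders alone.

Dominance requirements are linear inequalities in log space. Substituting
the steady-state solution projects them onto parameter space: a case with a
non-empty **phenotypic polytope** (checked by LP feasibility) is a valid
phenotype, and the collection of valid cases is the model's **phenotypic
repertoire**. On top of this the toolkit computes:

* **local stability** — eigenvalues (and Routh counts) of the reduced,
  constraint-free S-system Jacobian at a predicted interior point;
* **global tolerances** — fold-change of each parameter from a reference
  point to the nearest phenotype boundary, by 1-D reduction of the rows;
* **parameter prediction** — vertex or max-min-slack interior points of a
  phenotype's polytope, optionally under power-law constraints/objectives;
* **ensembles** — case *intersections* (coexisting fixed points =
  multistability), *co-localizations* (replicated slice variables `$V_i`),
  and *arrangements* (order constraints among the replicas), plus a pruned
  breadth-first search for maximal stable intersections;
* **landscape analysis** — 2-D slice classification, stability maps,
  state-space trajectory classes, Newton-refined fixed points, stiff ODE
  simulation with bolus events, and basins of attraction.

## Worked example

Two circuit models ship as packaged fixtures: `simple_circuit`, a single
positively autoregulated gene whose activator X1 is lost to heterodimer
formation with a partner X2 and repressed by X3, and `memory_circuit`, two
such activators coupled by mutual heterodimer loss.

```python
from dsdesign import fixtures
from dsdesign.predict import make_intersection, measure_tolerances

ds = fixtures.SIMPLE_CIRCUIT.design_space()
ds.valid_cases()
# [1, 4, 7, 8, 9, 10, 11, 12, 15, 18]      10 phenotypes of 18 possible

case1 = ds(1)                               # signature [1111]
case1.ssystem.report()["solution"]
# {'X1': 'a1*b1^-1', 'X100': '1'}           basal synthesis / dilution

pvals = dict(fixtures.SIMPLE_CIRCUIT.default_parameters)
case1.ssystem.positive_roots(pvals)
# 0                                         locally stable

measure_tolerances(case1, pvals)["X3"]
# (1e-20, 10.0)    the repressor can fall without limit but a 10-fold
#                  rise flips the circuit into a different phenotype

make_intersection(ds([1, 4, 7])).is_valid()   # False
make_intersection(ds([1, 7, 8])).is_valid()   # True: two stable phenotypes
#                  plus an unstable separator coexist -> a bistable switch
```

The same pipeline on the memory circuit finds 59 valid phenotypes, 21 of
them stable and uncoupled from the repressor; at most four intersect at one
point (18 such quadrastable ensembles), and a predicted instance counts
0 → 1 → 2 → 1 → 0 through transient boluses on its two input channels:

```python
from dsdesign.counter import run_counter_demo
demo = run_counter_demo()
demo.bolus             # 275.0
demo.reporter_levels   # {'-+': 0.137, '++': 12.7, '+-': 88.5}
```

A command-line interface wraps the library:

```sh
dsdesign enumerate --model memory_circuit --out repertoire.csv
dsdesign predict --model simple_circuit --cases 8,12,15,18 \
    --colocalize X2 --constraint '$X2_0 < $X2_1'
dsdesign landscape --model simple_circuit --x X2 --y b1 \
    --x-range 1e-3 1e3 --y-range 1e-3 1e3 --pvals a1=0.32,rho1=100 \
    --out slice.csv --plot slice.png
```

## Layout

| module | contents |
| --- | --- |
| `dsdesign.parsing`, `dsdesign.gma` | equation dialect, GMA systems, evaluation |
| `dsdesign.recast` | rational rate laws → GMA with auxiliary variables |
| `dsdesign.cases`, `dsdesign.linsys`, `dsdesign.lp` | signatures, dominance/boundary polytopes, LP backend |
| `dsdesign.ssystems` | exact log-linear steady states, gains, stability |
| `dsdesign.predict` | parameter sets, tolerances, ensembles, searches |
| `dsdesign.landscape` | slices, fixed points, simulation, basins |
| `dsdesign.counter`, `dsdesign.fixtures` | packaged circuits and the counter demo |
| `dsdesign.cli` | `dsdesign` command-line tool |

See `docs/methods.md` for modelling assumptions, numerical choices, and
known limitations.
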