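# hsmkit

Qualitative analysis of **hybrid-system models (HSM)** of gene regulatory
networks: enumerate binding-affinity threshold orderings, build the
characteristic graph of qualitative states for each ordering, and detect and
classify all stable behaviours (attractors) — without knowing exact binding
constants or kinetic rates.

The package is aimed at systems biologists studying bistable or oscillatory
regulatory circuits when only the *relative order* of binding affinities is
(partially) known.  Its flagship application, shipped as an executable
fixture, is the phage λ lysis–lysogeny switch.

## The model class and the method

An HSM couples continuous protein concentrations with discrete binding-site
states.  Four kinds of elements define a model:

* **substances** — proteins with continuous concentrations;
* **binding sites** — each FREE or BOUND by one of its ligands.  A pair
  (protein *P*, site *s*) has an association threshold `s.as` and a
  dissociation threshold `s.dis < s.as`: *P* binds when its concentration
  rises to `s.as` and releases when it falls to `s.dis` (hysteresis);
* **control functions** — total discrete maps from input site states to a
  gene expression level (0/1);
* **substance generators** — genes: product grows monotonically while
  expressed, degrades while silent.

A **mode** is the vector of all site states.  Within a mode each protein
monotonically rises (↑) or falls (↓), so the only events are threshold
crossings.  Given a total preorder of each protein's thresholds (a
**threshold ordering**), the **characteristic graph** contains every
consistent mode and every guarded transition (e.g. `Cro ≥ bOR2.as`)
admissible under that ordering — a safe over-approximation of every numeric
run.  Stable behaviours are found by SCC analysis: an SCC is an **attractor
candidate** iff it has no *progress indicator*, i.e. no protein that rises in
every member mode with an association threshold still ahead, or falls in
every member mode with a site still occupied (either would force an exit).

When affinities are only partially ordered, the package enumerates **all**
threshold orderings consistent with the declared constraints (chains,
per-site closeness/adjacency, ties, explicitly admitted interleavings),
analyses every ordering, classifies the attractors across orderings
(behaviour types, binding-site variants, canonical graph signatures), and
mines the threshold inequalities shared by all orderings that produce each
behaviour.

A numeric event-driven simulator (piecewise-linear kinetics, exact event
times, hysteretic binding) validates the over-approximation: every simulated
mode sequence is a walk in the corresponding characteristic graph.

## Worked example

The built-in two-gene network: gene `s1` represses itself (site `b1`); gene
`s2` represses itself (site `b3`) and activates `s1` (site `b2`).  Only the
order of `s2`'s four thresholds is unknown:

```sh
hsmkit fixtures --name toy -o toy.json
hsmkit enumerate-orderings --model toy.json --substance s2
```

```
{"id": 1, "ordering": "b2.dis < b2.as < b3.dis < b3.as", "substance": "s2"}
{"id": 2, "ordering": "b2.dis < b3.dis < b2.as < b3.as", "substance": "s2"}
{"id": 3, "ordering": "b2.dis < b3.dis < b3.as < b2.as", "substance": "s2"}
{"id": 4, "ordering": "b3.dis < b2.dis < b2.as < b3.as", "substance": "s2"}
{"id": 5, "ordering": "b3.dis < b2.dis < b3.as < b2.as", "substance": "s2"}
{"id": 6, "ordering": "b3.dis < b3.as < b2.dis < b2.as", "substance": "s2"}
6 orderings
```

Six orderings are compatible with the implicit `dis < as` constraints.  The
third one is the interesting case — its characteristic graph holds **two**
attractors, so the initial site states decide the outcome:

```sh
hsmkit attractors --model toy.json --ordering 3 -o attractors.json
```

```
2 attractors -> attractors.json
```

`attractors.json` shows a 2-mode single cycle in which `s2` alone oscillates
across `b3` while `s1` decays (`b2` stays free, so `s1` is never activated),
and a 4-mode branched attractor in which `s2` holds `b2` and both genes
cycle.  Every other ordering yields a unique attractor.

The phage λ model (10 sites, 6 control functions, 11 genes) sweeps all 500
admissible orderings of Cro and repressor thresholds in about a minute:

```sh
hsmkit fixtures --name lambda -o lambda.json
hsmkit sweep --model lambda.json --fixture-constraints both -o sweep.csv
```

```
500 orderings, 4 behaviour types, 9 variants -> sweep.csv
```

Every one of the 500 graphs contains exactly two attractors.  The four
behaviour types are wild-type lysis (a 12-mode SCC with transitions by Cro,
CII and Q — Cro cycles between the `bOR2` thresholds), modified lysis (6
modes, no Q transitions: Q, N, cIII, xis and the structural proteins decay
to zero), wild-type lysogeny (repressor cycles across its `bOR2`; everything
else decays) and modified lysogeny (N, cIII, xis keep accumulating).
`hsmkit conditions` reports that wild-type lysis occurs exactly when both
Cro thresholds for `bOR2` lie below those for `bOL2`, and that placing
repressor's `bOR3` thresholds below its `bOL1` ones forces the modified
lysogeny.

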