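# Methods

## Model semantics

An HSM model is a tuple of substances, binding sites, control functions and
generators (`hsmkit.model`).  All shipped fixtures use binary expression
(0/1); the schema admits higher levels, and the analysis only distinguishes
level 0 (falling) from level > 0 (rising), so multi-level tables degrade
gracefully to their on/off projection.

**Thresholds and hysteresis.**  Every (substance, site) ligand pair owns a
dissociation and an association threshold with `dis < as` — an implicit,
always-on constraint.  A bound site stays bound while the ligand sits above
`dis`; a free site stays free below `as`.  Crossing is inclusive (`≥` binds,
`≤` releases).

**Mode consistency.**  Under a threshold ordering, a mode constrains each
substance *P* to the open interval above the highest `dis` of its bound
sites and below the lowest `as` of its free bindable sites; sites bound by
the other ligand impose nothing on *P*.  The mode is consistent iff every
interval is non-empty, evaluated on ranks (tied thresholds share a rank, so
a required strict gap between tied values is empty).  This prunes the mode
space sharply: the phage model has 3⁶·2⁴ = 11 664 raw site-state
combinations, of which roughly a tenth survive for a typical ordering.

**Directions.**  A substance rises iff its gene's control function returns a
positive level, falls otherwise; the `steady` label is reserved for
generator-less substances (validation normally requires one generator per
substance, so it appears only in deliberately degenerate models).  A gene
that is off labels its product falling even when the concentration is
asymptotically close to zero — the qualitative abstraction cannot witness
reaching zero in finite time, and this keeps the label a pure function of
the mode.  The numeric simulator's observational sequences do report `→`
when a concentration sits exactly at the zero floor.

**Events.**  A monotone concentration meets lower thresholds first, so a
rising substance can only cross the *minimal* uncrossed association rank
among its free bindable sites, and a falling one the *maximal* dissociation
rank among its bound sites.  Thresholds tied at that rank fire as one
compound event switching all tied sites simultaneously.  Events of
different substances are asynchronous (one edge each).  After a release,
the freed site may already lie below another ligand's implied concentration;
such modes are inconsistent and are completed by immediately binding the
offending sites ("cascade closure").  When a site is claimed by both
ligands at once the closure branches, one edge per consistent completion —
a conservative choice: the graph must over-approximate every run, and the
run-level outcome depends on rates the qualitative analysis does not see.

**Seeding.**  The default characteristic graph contains *every* consistent
mode (`seeds="all_consistent"`), which is the right domain for attractor
search.  `seeds="settled"` instead closes the set of modes reachable from
settled initial states (sites bound in ascending association order up to
some concentration cut) under events; it is the graph numeric runs can
actually realise and is used when comparing graph *structures* across
orderings — consistent-but-unsettleable modes (e.g. an outer site bound
while an inner one with a lower association threshold is free) would
otherwise pad some graphs with unreachable transients.  Attractor results
agree under either seeding for all shipped fixtures.

## Ordering enumeration

Constraints per substance: *chains* (strict rank order), *adjacency blocks*
(a immediately before b — used for "a site's threshold pair is so close that
no other threshold of the same protein falls between them"), *equalities*
(tied ranks) and *permitted interleavings*.  Adjacency blocks and equalities
are compiled into ordered units; enumeration is lexicographic backtracking
over topological orders of the unit DAG, so results are exhaustive,
duplicate-free and deterministically ordered (the two-site single-protein
case reproduces the canonical six-row table order).

Permitted interleavings are *explicit complete orderings*, validated
against the chains but exempt from adjacency.  The phage constraint set
admits two per protein — the fully cascade-aligned orderings in which the
bOR2 and bOL2 pairs interleave (`bOR2.dis < bOL2.dis < bOR2.as < bOL2.as`
and its mirror).  A looser reading — allowing the interleaved middle with
free placement of the outer site blocks — would admit 8 extra orderings per
protein (28 instead of 20 + 2 = 22) and break the published joint counts
(22 × 22 = 484, plus 16 tied variants, 500 in all); the explicit-ordering
semantics reproduces them exactly and is the package's fixed convention.

## Attractor detection and classification

SCCs come from networkx.  A *progress indicator* of an SCC is a substance
uniformly rising with some bindable site free in every member mode, or
uniformly falling with some site bound in every member mode — it is
guaranteed to cross a threshold and force an exit (this relies on the model
assumption that growth eventually crosses any association threshold ahead
and decay any dissociation threshold above zero).  An SCC is an attractor
iff it has no progress indicator and contains an internal edge or is a
steady sink.  Finality (no outgoing edge) is reported separately: a
candidate like the wild-type lysis SCC has exits whose traversal depends on
rate ratios, so non-final candidates are still attractors.

Three comparison granularities:

* **signature** — canonical form of the SCC subgraph, nodes labelled by
  direction vectors, edges by guard substance (site identities dropped).
  Canonicalisation is colour refinement plus individualisation with a
  minimal-encoding search — exact for graphs of attractor size;
* **behaviour class** — per-substance long-run fate: `decays` (uniformly
  falling, hence degrading to zero) vs `persists` (still produced, steadily
  or cyclically).  This is the biological *type* of a stable behaviour;
  signatures that differ only in fine cycle structure share a class.  The
  distinction matters for tied thresholds: when bOR2 ≡ bOL2 the lysis SCC
  toggles P_L with the Cro cycle (24 modes) — a different signature but the
  same fates as wild-type lysis, of which it is a variant;
* **fingerprint** — behaviour class plus the set of (site, ligand) pairs
  ever bound inside the attractor; distinguishes occupancy variants of one
  behaviour.  Across the 500-ordering phage sweep these granularities give
  5 signatures, 4 behaviour types and 9 fingerprints.

**Condition mining** intersects, per signature, the strict pairwise rank
relations holding in every ordering that produces it (`always`) and those
holding in none (`never`).  These are necessary-in-sample conditions;
sufficiency claims are checked against the sweep rows directly.

## The phage λ fixture

Ten sites (bOR1–3 and bOL1–3 bindable by Cro and repressor, bQ, bN,
bCII-1/2), six control functions, eleven genes; operons are several
generators sharing one control function (cro, cII, O, P ← P_R; N, cIII,
xis ← P_L).  Repressor's association thresholds ascend bOR1→bOR2→bOR3 and
bOL1→bOL2→bOL3 (descending affinity); Cro's are reversed.  CII's bCII-1
threshold pair lies above bCII-2's, fixing its ordering; N and Q have one
site each.

The control truth tables are a reconstruction from the switch's documented
wiring (the tables themselves are not printed anywhere reusable), validated
against the sweep statistics: P_R (and P_RN, additionally requiring N on
bN) need bOR1 and bOR2 free; P_L needs bOL1 and bOL2 free; P_int fires on
CII at bCII-2; P_Q on Q at bQ.  P_ME (driving cI) is on iff bOR3 is free
and bOR2 is either not repressor-bound or overridden by CII on bCII-1:
occupancy of bOR3 — Cro at low concentration or repressor's own negative
feedback at high — silences cI outright, and the CII trigger models
establishment of lysogeny.  An earlier candidate table in which CII's
trigger bypassed the bOR3 veto let cI fire inside the lysis cycle whenever
CII peaked, dragging repressor excursions into the lysis SCC and producing
a third attractor class — rejected because it contradicts every published
sweep statistic; the veto form reproduces all of them (2 attractors per
ordering; 12-mode lysis with {Cro, CII, Q} guards; 6-mode modified lysis
without Q; 2-mode lysogeny cycles).

## Numeric simulator

Piecewise-linear kinetics: growth `+g` while expressed, decay `−d` while
silent, floored at zero; both rates are per-gene positive constants.  Event
times are exact (`(threshold − c)/rate`); equal-time crossings fire as one
compound event; a release that leaves a site below another ligand's current
concentration is completed by an immediate (zero-duration) rebinding,
mirroring the graph's cascade closure.  No concentration cap is applied by
default, matching the eventual-crossing assumption; runs terminate at a
steady state (no pending crossings), an event budget, or a time horizon.
Simulation is deterministic given parameters and initial concentrations;
randomness exists only in the test helpers that draw rates, initial values
and order-preserving threshold jitter.

The central validation is conformance: for every run, consecutive modes
must be joined by a graph edge whose guard matches the crossing that
occurred (coincidental multi-substance crossings are accepted via any
sequential decomposition).  The test suite checks this on 100 random
two-gene runs across all six orderings.

## Synthetic models and scope of the tests

`random_model` draws random ligand assignments and random binary truth
tables — enough to property-test structural invariants (consistency of all
graph nodes, guard/state coherence of all edges, enumeration vs brute-force
permutation filtering, SCC vs transitive-closure reachability).  It does
not emulate biological network topology (no cascades, no operons, no
cooperative binding), so passing these tests certifies the machinery, not
biological realism; the biological claims are carried by the two curated
fixtures.

Problem sizes throughout (500 orderings × ~1 000–2 500-mode graphs for the
phage sweep; 100 numeric runs; permutation oracles up to 6 thresholds;
random digraphs up to 8 nodes) are desk-scale: the full suite runs in about
a minute and a half on one CPU.

## Known limitations

* Expression is effectively binary in the analysis; graded levels only
  affect the simulator through rates.
* The branching cascade closure may include release-then-rebind edges that a
  specific rate assignment can never realise (safe over-approximation, not
  exact reachability).
* Thresholds of different substances are never compared — concentrations
  live on separate scales; constraints across substances are out of scope.
* Stress-induced repressor degradation is not modelled; comparable regimes
  can be emulated through initial concentrations.
* The condition miner reports pairwise rank relations only; conditions that
  are inherently disjunctive across orderings must be read off the sweep.
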