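# Methods

## Model representation

A model is a set of metabolites (namespace-qualified ids with an `@<code>`
compartment suffix; one cytosol `c` and one extracellular compartment `e`
per organism), reactions (signed stoichiometry, flux bounds in
mmol·gDW⁻¹·h⁻¹, a boolean GPR string, EC annotations, and a *kind*), a gene
set, and an optional biomass objective. Reaction kinds are inferred on
read: the objective (or an id containing "biomass") is biomass;
single-metabolite reactions are boundary reactions, split into exchange
(`EX_` prefix, or extracellular metabolite) versus sink (`SK_`/`DM_`
prefix, or intracellular); a reaction moving one base species between
compartments is a transport. When a source omits bounds they default to
±1000, the community convention.

SBML L3+fbc I/O is delegated to COBRApy; internal ids are escaped
(`__<ord>__` per non-identifier character) into SBML SIds and unescaped on
read. A plain-text TSV-triplet dialect (metabolites/reactions/gprs) exists
for human-editable fixtures. The structural round-trip contract covers
ids, stoichiometry, bounds, GPR truth tables, formulas, charges, and
EC annotations.

## Dead-end metabolites

A metabolite is a dead end when it lacks any producer **or** any consumer
under the directions its reactions' bounds allow; boundary reactions count
as producers/consumers. This "either side missing" reading is one of
several in circulation (produced-only, consumed-only, either); it is the
most inclusive and makes the dead-end count a pure function of network
topology and bounds. Because merging tool views only ever adds
producers/consumers, consensus dead ends are always a subset of the dead
ends of every view containing the metabolite — an invariant the audit
function checks explicitly.

## Mass/charge balance

Per reaction, the signed sums coefficient × element-count over plain
Hill-style formulas; balanced iff every element sum and the charge sum are
zero. Exchange/sink/biomass reactions are exempt (unbalanced by design);
any missing or unparsable formula yields verdict "undetermined" rather than
a guess; unknown charges skip the charge component and record the reason.

## Namespace harmonization

Cross-reference tables (`source_namespace, source_id, common_id, kind`) are
static TSV inputs; consistent duplicate rows collapse, conflicting rows are
a hard error. Translation preserves compartment suffixes, fuses metabolites
that map to one common id (rewriting stoichiometries, dropping cancelled
terms, removing and logging reactions left empty), and never touches gene
sets. Unmapped ids are retained with an `unmapped:<tool>:` prefix rather
than dropped, so Jaccard comparisons penalise namespace gaps the same way
low inter-tool similarities do in practice; translation is idempotent
because common ids and already-prefixed ids are left alone.

## Consensus merging

Views are stripped of boundary and biomass reactions, then folded in a
fixed tool order (CarveMe-like first, then gapseq-like, then KBase-like —
the order only affects kept reaction ids, not the content digest).
Duplicates are detected by common reaction id or by canonical
stoichiometry: coefficients as exact rationals divided by the gcd of their
absolute values, listed in sorted metabolite order; the negated fingerprint
identifies reversed duplicates, which are merged as reversible. A merged
reaction takes the union of allowed directions, the OR of inequivalent
GPRs (truth-table equivalence decided by exhaustive enumeration up to 12
genes), and the union of EC annotations and source tools. An empty GPR
means "no recorded evidence", so OR-combining keeps the annotated rule
rather than degenerating to "always available". Metabolite attribute
conflicts resolve first-seen-wins and are logged; when duplicates disagree
on mass balance, the balanced variant's formula annotations are adopted.
The gene set is exactly the union of view gene sets.

## Flux computations

FBA, FVA, blocked reactions, and export ranges are linear programs on the
stoichiometric matrix solved with HiGHS (scipy), which is deterministic for
fixed input. A medium *sets* each exchange's uptake capacity
(lower bound = −rate) and closes uptake of non-medium metabolites — the
COBRApy convention, which the tests cross-check against COBRApy itself on
shared networks (agreement asserted to 1e-5; flux-zero tolerance 1e-6).
Blocked reactions use FVA with no growth requirement
(fraction_of_optimum = 0): the filter targets structural capability, not
optimal-state activity; the fraction is exposed for other readings. Export
flux ranges fix the objective at its optimum (fraction 1, with 1e-9 slack
against round-off) and min/maximise each sink; secretion is positive sink
flux, uptake is negative exchange flux.

## Gap-filling

One binary per candidate database reaction; objective Σ wᵢyᵢ with default
wᵢ = 1; gating constraints lᵢyᵢ ≤ vᵢ ≤ uᵢyᵢ; growth threshold
ε = 0.05 (an arbitrary but explicit "non-zero growth" cutoff — solutions
are insensitive to its exact value on these networks because feasibility,
not magnitude, drives selection). Candidate reactions enter with their GPRs
cleared: gap-filled content has no genetic support by definition. The
environment around the MILP gives free medium exchanges and free secretion
valves for extracellular metabolites lacking a zero-cost boundary;
candidate uptakes (community-pool metabolites) cost weight like any other
candidate. Among minimum-weight solutions the lexicographically smallest
reaction-id set is selected by a greedy fix-in pass (one MILP per
candidate, capped at 64 candidates), making results solver-order
independent. An LP relaxation (`relaxed=True`, y ∈ [0,1], selected when
y > 1e-6) is available as a faster non-exact switch. Infeasibility against
the full database is diagnosed per biomass precursor by demand-probe LPs
and reported as a typed error naming the unreachable precursors.

Permeable metabolites are extracellular species whose sink flux can exceed
1e-6 while biomass ≥ ε, with the metabolite's own uptake closed during the
probe so that re-exporting a medium component does not count as secretion
capability.

The community iteration processes members by abundance (descending or
ascending; ties broken by MAG id). The first member is gap-filled on the
rich initial medium, later members on the minimal base medium plus the
accumulated permeable pool offered as uptake candidates; sinks are added
for each member's permeable metabolites, the pool grows monotonically, and
the final medium is the base plus everything exported. An infeasible member
is recorded and skipped (fail-fast optional). Pearson correlation relates
abundance to added/imported/exported counts; constant vectors raise an
explicit undefined-statistic error.

## Comparison statistics

Jaccard similarity |A∩B|/|A∪B| (1 for two empty sets) over reaction,
metabolite, dead-end, or gene sets. EC subclasses are the first two numeric
fields of an EC number; incomplete codes (`3.-.-.-`) are excluded.
Enrichment of subclasses in a target reaction set against a background is
a hypergeometric upper tail P[X ≥ k] (scipy, exact against brute-force
enumeration to 1e-12 for N ≤ 12), with the population restricted to
annotated reactions, once-per-subclass counting of multi-EC reactions, and
Benjamini–Hochberg adjustment at α = 0.05. The pipeline's
"unblocked shared" variant requires a shared reaction to be unblocked in
both compared communities. Group contrasts use Kruskal–Wallis (≥3 groups;
H = 0, p = 1 when all observations are identical), Wilcoxon rank-sum
(two groups), and Pearson (paired numeric).

In the pipeline, structural counts and similarity matrices are computed on
the boundary-free network interiors (exchange/sink/biomass reactions
stripped from every approach), because the consensus is boundary-free by
construction and dead-end counts are only comparable across approaches
when all models are scored on the same footing.

Import/export membership is bound-based: imported = exchange permits
uptake, exported = sink permits secretion; exchanged = union-exported ∩
union-imported across the community. Bound semantics count capability, not
simultaneous flux — realised fluxes live in the export-range analysis.
Summaries report mean ± sample (n−1) standard deviation.

## Synthetic data

The generator emulates the study design, not biochemistry: a truth network
(nutrient uptakes → linear core → branches yielding one biomass precursor
and one secretable byproduct each; universal biomass over all precursors
plus nitrogen and a magnesium-like cofactor) that is connected, dead-end
free, element-balanced (C/H/O/N/Mg bookkeeping), and growth-capable on its
own media. The universal database holds the true interior reactions
(GPR-stripped), per-byproduct uptake + salvage routes (2 byp → precursor),
and connected decoys. Tool profiles degrade the truth: i.i.d. reaction
dropout outside a protected core, GPR clearing/rewiring, appended
dead-end-creating reactions, and relabelling into a per-tool namespace with
an emitted cross-reference table (appended artefacts deliberately missing
from the table — they have no common-namespace counterpart). Default
profiles reproduce the qualitative inter-tool ordering: the gapseq-like
view keeps the most reactions but accrues the most dead ends (12 appended
artefacts dominate kbase's dropout-induced dead ends), the carveme-like
view retains the most gene associations, the kbase-like view drops the
most reactions. A complementary-dropout option partitions the droppable
interior across views (no appended artefacts), which guarantees the
consensus heals every view's induced dead ends. Communities share one
metabolite universe; each non-first member loses one randomly chosen
branch, making its precursor gap-fillable de novo or by cross-feeding.
Abundances are log-normal (μ = 0, σ = 1), the typical shape of MAG
coverage sums. Problem sizes used throughout the tests and the acceptance
script (2–4 members, 2–4 branches of length 2–4, databases ≤ 60 reactions;
50 random gap-fill instances with ≤ 12 candidates) keep every exhaustive
oracle exact while exercising all code paths.

What passing tests on these fixtures show: the algorithms are correct on
networks whose ground truth is known. What they do not show: behaviour on
real reconstructions with thousands of reactions, compartment proliferation,
polymer/generic metabolites, incomplete formula annotation, or namespace
tables with partial coverage — there the same code runs, but no ground
truth exists to score it against.

## Known limitations

- Canonical-stoichiometry duplicate detection treats cofactor-variant
  reactions (NADH vs NADPH analogues) as distinct, as it should, but also
  treats lumped versus stepwise versions of a pathway as distinct; no
  semantic reaction matching is attempted.
- The exact lexicographic tie-break grows linearly in candidate count and
  is disabled above 64 candidates, where the (still deterministic) single
  MILP solution is returned.
- The community is a shared-medium iteration, not a joint stoichiometric
  matrix; no simultaneous community FBA is performed.
- GPR truth-table comparison falls back to normalized string equality
  beyond 12 genes.
- No thermodynamic constraints, loopless FVA, or flux sampling.
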