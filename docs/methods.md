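# Methods

## The module abstraction

An organelle module is a stoichiometric model with three structural
conventions layered on top: organism tags (`@Xxx_` reaction-id prefixes),
border reactions (`B_` prefixes) and a mode registry mapping each organism
symbol to its biomass reaction.  All analysis reduces to linear
programming over `S·v = 0` with flux bounds; the module machinery only
ever manipulates bounds, objectives and identifiers, never stoichiometry.

Tag grammar: a reaction id is `[@Tag_]* [B_] core_id`, tags are an
order-insensitive *set* (a reaction shared by two organisms stacks
prefixes, `@Chl_@Pha_…`), and the canonical serialization orders tags
alphabetically with `B_` after the tags.  Parsing is strict against the
model's registered organism set — an unknown `@Xxx_` prefix is an error,
which is what makes the tag system extensible without being silently
typo-tolerant.

Mode switching closes every tagged reaction not tagged for the active
organism to (0, 0) and restores the active organism's reactions to their
**default bounds**, captured when the reaction was loaded or built.  The
default bounds are the single source of truth for "enabled"; per-mode
bound overrides are supported but default to plain restoration.  In a
fused model, mode switching still toggles tagged reactions but never
touches the objective, which belongs to the exo-model.

## The LP engine

FBA problems are solved with HiGHS (`scipy.optimize.linprog`), which is
deterministic.  The *objective value* of an LP is unique but the optimal
flux vector generally is not, so any reported single flux goes through a
second LP: pin the objective to its optimum (within a relative band of
1e-7) and maximize or minimize the probe flux.  Reported fluxes are
therefore extreme values over the optimal face, not arbitrary vertex
reads.  Feasibility and optimality are left at the solver's defaults
(~1e-9); classification thresholds sit far above solver noise: a knockout
is *lethal* below 1e-6 absolute growth and *reduced* below
(1 − 1e-3) × wildtype.  These thresholds are declared package defaults —
they separate lethal from merely-degraded robustly on the bundled
fixtures, and are arguments, not constants, in the scan API.

Phase planes fix two control reactions (lower = upper = grid value) on a
caller-specified grid (20×20 default), re-optimize at each point and
restore bounds afterwards; infeasible points are NaN, which is the honest
encoding for "this flux combination is stoichiometrically impossible".

## The photosynthesis reconstruction

Every electron transfer in the chain is one reaction: 10 in PSII
(antenna absorption, energy transfer, charge separation, P680⁺
re-reduction by tyrosine Z, the lumped S-state water-oxidation cycle,
Pheo⁻→QA, two QA⁻→QB transfers, QB²⁻ protonation, PQ exchange at the QB
site), 7 in cytochrome b₆f (Qo-site plastoquinol oxidation bifurcating
into the high-potential ISP→cyt f→plastocyanin chain and the low-potential
bL→bH→Qi chain, two Qi-site reductions, Qi quinol release), 8 in PSI
(excitation, charge separation to A0, plastocyanin oxidation, then
A0→A1→FX→FA→FB→ferredoxin), and 3 at FNR (two ferredoxin electrons, then
hydride transfer to NADP⁺).  Two shuttle reactions move PQ/PQH₂ between
PSII and b₆f; one reaction each for ATP synthase and cyclic electron
transport complete the chain.  The identities of the intermediate carriers
are a documented canonical choice; tests assert only the reaction counts
and the per-complex net sums, which are the physically meaningful content:

* PSII, per 4 photons: 2 H₂O + 2 PQ + 4 H⁺(stroma) → O₂ + 4 H⁺(lumen) + 2 PQH₂
* b₆f, per PQH₂ (full Q cycle): PQH₂ + 2 PC_ox + 2 H⁺(stroma) → PQ + 2 PC_red + 4 H⁺(lumen)
* PSI, per photon: PC_red + Fd_ox → PC_ox + Fd_red
* FNR, per NADPH: 2 Fd_red + NADP⁺ + H⁺ → 2 Fd_ox + NADPH

Proton bookkeeping is the load-bearing design decision.  With 1 lumen
proton per electron from water oxidation and 2 per electron from the Q
cycle, 4 electrons of linear flow deposit 12 lumen protons; at 4 H⁺ per
ATP that is 3 ATP per 2 NADPH.  The Calvin–Benson cycle demands 9 ATP per
6 NADPH — the same 3:2 — so a closed-cofactor model needs no cyclic
electron transport at its optimum.  This is the unique simple stoichiometry
with that property, which is why 4 H⁺/ATP is the default; the ratio is a
spec parameter (`ETCSpec.h_per_atp`) and the consequences of moving it are
tested: at 14/3 H⁺/ATP the optimum needs cyclic flow and drops; at 3 the
chain over-produces ATP that has no sink and the closed model cannot run
at all.

Counting: the *photosynthesis* subsystem contains exactly 33 reactions —
10 + 7 + 8 + 3 transfers, ATP synthase, 2 PQ shuttles, cyclic transport,
and the photon-partition reaction `PSII_photon`.  The general photon
import (capped at 1000 mmol gDW⁻¹ h⁻¹) is labelled an exchange and sits
outside the count; PSI draws directly from the imported photon pool, so
there is a single partition reaction and the PSII partition flux is an
observable of its own.  `subsystem_summary` exposes both totals (the
34-reaction module includes the import).

Chain lengths beyond the canonical 10/7/8/3 are supported by splicing
extra one-electron relay carriers into a designated hop of each complex
(each relay adds one transfer reaction and one redox couple); counts below
the canonical minimum are rejected, since the documented carrier chain
cannot be shortened.  A balance audit table assigns every carrier species
a relative (H, O, charge) vector — redox couples differ by one electron of
charge, protonation states by (H, +1), ATP is referenced to
ADP + Pi − H₂O — and every reaction of the chain must conserve all three
exactly; photons carry nothing, so light input breaks no conservation law.

## The Calvin–Benson mini-model

Carbon fixation is lumped into two reactions: RuBisCO carboxylation
(CO₂ + RuBP → 2 PGA — the probe reaction for fixation flux) and a
reduction/regeneration lump (6 PGA + 9 ATP + 6 NADPH + 6 H⁺ + 3 H₂O →
DHAP + 3 RuBP + 9 ADP + 8 Pi + 6 NADP⁺).  Only the 3:9:6 totals per
triose are asserted; the full 11-enzyme cycle adds nothing at this
granularity.  The lump's 6 H⁺ and 3 H₂O make stromal protons and water
fully internal (ATP synthase returns n H⁺ and one condensation H₂O per
ATP; water oxidation consumes 2 per O₂), and the 8-vs-9 Pi split reflects
the phosphate exported in the triose: the ninth Pi re-enters through the
triose-phosphate/Pi translocator antiport.  Consequently the *only*
exchanges are photons, CO₂, O₂, cytosolic Pi, and the exported triose —
ATP, ADP, Pi(stromal), NADPH and NADP⁺ have no transport, which is the
constraint that forces the ETC onto the 9:6 supply ratio.

Under the default spec the optimum is triose = 1000/24 = 41.6̄
(24 photons per triose: 12 to PSII, 12 to PSI), RuBisCO = 125, PSII
photons = 500, ATP synthase = 375.  These values are exact LP results, not
fits.

## What the fixtures do and do not emulate

The builders produce the study conditions — chain stoichiometry, photon
cap, closed cofactor balance, KEGG-annotated cytosolic exchanges — but not
a real chloroplast's full reaction complement: no amino-acid, lipid or
pigment synthesis pathways stand behind the biomass assembly reactions, so
biomass-producing simulations on the bundled fixtures exercise the
machinery (modes, registry, objective switching), not physiological growth
rates.  The per-organism CPr/CML/CPi fraction tables shipped with
`BiomassSpec` are illustrative placeholders that sum to 1 and carry the
right species lists (e.g. the *Phaeodactylum* pigment pool is chlorophyll
*a* only, its carotenoid pathways being unmodelled); quantitative work
must override them from config.  The toy exo-model is likewise a minimal
witness for fusion semantics — its biomass is deliberately infeasible
without a plastid triose supply — not a cell model.

Likewise, passing tests on these fixtures demonstrate correctness of the
algorithms (matching, deletion, merging, toggling, probing) and of the
photosynthetic stoichiometry; they do not certify predictions about any
real organism.

## Fusion semantics

Exchange metabolites are the cytosolic species touched by at least one
border reaction.  Matching is by KEGG compound id against cytosolic exo
species (the "cytosol" compartment symbols are configurable, default
{c, cytosol, cytoplasm, cyt}); zero candidates, multiple candidates and
missing annotation are all reported, never guessed.  Merging renames
matched module species to exo ids, deletes border and module-biomass
reactions, unions genes by id, and keeps unmatched exchange metabolites as
disconnected species for debugging rather than deleting them.  Reaction-id
collisions keep both reactions, the module copy prefixed `CHL__` — merging
two reactions that merely share a name would silently conflate different
stoichiometries.  Conservation laws (merged counts = sums minus matches
and deletions) are asserted as properties.

## Numerical and degenerate-input choices

* Duplicate ids, dangling references, inverted bounds, unregistered tags
  and malformed KEGG ids are *report entries* from `validate`, not
  exceptions — a model under construction must be inspectable.
* SBML: written as L3V1+fbc v2; read back L3+fbc or L2 with COBRA-style
  notes and kinetic-law bounds.  `@` is not a legal SId character and is
  escaped as `__64__`.  Missing bounds default to (−1000, 1000) or
  (0, 1000) by the reversible flag, with a logged warning.
* KEGG records with polymeric (`n`) coefficients are rejected rather than
  approximated; ambiguous alias→compound lookups are left unresolved
  rather than first-matched.
* Empty models round-trip through SBML, SIF and the matrix builders as
  genuinely empty objects (0×0 matrix, empty file, zero components).

## Problem sizes

The bundled fixtures are intentionally small: the mini-model has 43
reactions and 69 metabolites, the toy exo-model 7 and 7, and the
LP-oracle property tests use random networks of at most 6 reactions so
that exhaustive vertex enumeration stays exact.  The whole suite and the
acceptance script run in seconds on one CPU.
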