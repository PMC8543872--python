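# Methods

## Problem and model

A genome-scale metabolic model defines a stoichiometric matrix S over
metabolites and reactions with flux bounds. Classical graph analysis
(GBA) turns the model into a directed metabolite graph and reads the
bow-tie structure — giant strongly connected component (GSC), IN, OUT
and isolated subset (IS) — off strongly connected components and
reachability. Many graph links do not correspond to feasible carbon
transfer (co-substrate links, antiporters walked twice, unbalanced
co-products), so this package also computes the bow-tie from
flux-balance pathway feasibility: a metabolite belongs to the core only
if a mass-balanced steady-state pathway (S·v = 0, bounds respected)
both produces it from a seed metabolite and consumes it back to the
seed, with an acceptable carbon yield. The two partitions are then
compared cell by cell.

## Pathway solves

For a source A and target B the model receives a sink for A (lower
bound −10 mmol/gDCW/h, upper bound 0, so it can only supply) and the
demand of B as objective. The demand optimum r_p is maximised, then a
parsimonious step minimises total absolute flux at the fixed optimum
(two-stage LP via COBRApy's `pfba`). A pathway exists iff
r_p > ε = 1e−6 mmol/gDCW/h; conceptually "no pathway" means a zero
rate, and ε is the LP-noise floor that operationalises zero. Carbon yield is

    Y_C = (r_p · C_p) / (r_s · C_s)

with C the *moiety* carbon number: for carrier-bound species (acyl-CoA,
acyl-ACP, methyl-THF, nucleotide-diphosphate sugars) only the carbons
outside the carrier count, because sinks are written `carrier → x` and
demands `x → carrier`, recycling the carrier group instead of forcing
its synthesis or catabolism.

Yields are bounded a priori by the degree-of-reduction balance. With
γ = 4C + H − 2O − 3N + 5P + 6S − charge (available electron equivalents
per mole; the charge term makes the values exact for the charged
species of BiGG models), the maximal yield from source to target is
min(1, γ_C(source)/γ_C(target)). The bound presumes the substrate is
the sole electron source, which preprocessing guarantees by closing all
reductant and carbon uptake.

## Preprocessing

Applied once per model, recorded in a registry, idempotent, and never
touching original reactions:

1. every boundary reaction of a carbon-containing species (including
   CO2 and bicarbonate) has its uptake direction closed; non-carbon
   nutrients (NH4, Pi, SO4, O2, water, protons, metals) keep model
   defaults so N/P/S in products can be sourced;
2. a reversible, element- and charge-balanced energy reaction
   `atp + h2o ⇌ adp + pi + h` is added (unless an equivalent exists) so
   pathways are not forced to carry the respiratory machinery for ATP
   balance — the textbook shorthand ADP + Pi ⇌ ATP is deliberately not
   used because it is elementally imbalanced and would corrupt the
   audit;
3. each free carrier species gets a demand, and every carbon metabolite
   gets exactly one irreversible demand (`x →`, or `x → carrier` for
   carrier-bound x), so reaction co-products can always be balanced.
   Demands only grow the feasible set; they add no carbon source.

Carrier detection combines an id-pattern match with element-wise
formula subtraction (the bound species must contain the whole carrier);
ambiguous matches are errors that require an override entry. The
balance audit (COBRApy `check_mass_balance` per reaction) skips
boundary/pseudo-reactions and any reaction touching species with
undefined or placeholder (R/X/Z) formulas — macromolecules such as
tRNAs are not imbalances. Models with more than 5 imbalanced reactions
are refused by the CLI unless forced, since imbalanced reactions
silently corrupt carbon yields.

## Sweep and classification

Solving all ~n² metabolite pairs is avoided through transitivity: the
12 biosynthetic precursors of central metabolism (e4p, pep, r5p, oaa,
3pg, pyr, akg, accoa, f6p, g6p, g3p, succoa; cytosolic species) are
solved pairwise (n·(n−1) LPs); if their feasibility digraph is strongly
connected any of them represents the core and pyruvate is taken,
otherwise the lexicographically first member of the largest strongly
connected component (lexicographic tie-breaks everywhere for
reproducibility). The sweep then solves seed→x and x→seed for every
carbon metabolite in sorted order.

Classification flags require both feasibility and carbon yield
≥ τ = 0.20: pathways below 20% yield are generally by-product or
CO2-refixation artefacts, not conversions. Raw (pre-threshold)
feasibility and yields are kept alongside for audit — produced/consumed
tallies are naturally reported pre-threshold while classification is
post-threshold — and both views are exposed. GSC = producible ∧ consumable,
IN = consumable only, OUT = producible only, IS = neither — a disjoint
cover by construction.

The IS substructure probe opens sinks for *all* IN members
simultaneously and tests each IS member's demand (set-level
producibility — a tractable approximation of per-substrate testing),
and conversely tests each IS member as sole substrate against the
moiety-carbon-weighted sum of all OUT demands; the carbon weighting
makes the objective maximise the yield numerator. Both probes use the
parsimonious step so degenerate alternate optima do not inflate the
uptake denominator.

## Graph construction

Only original model reactions contribute links (no boundary or added
pseudo-reactions). For each reaction the eligible endpoints are its
carbon substrates and products, excluding CO2, HCO3 and ACP. Currency
pairs are removed compartment-locally in rank order (hydride <
phosphate < amine < one-carbon < acetyl < CoA-thioester); a removal
that would leave no substrate×product pair is skipped and processing
stops, so every carbon reaction keeps at least one link. The acyl-CoA
pairs are encoded as acid couples (acetyl-CoA/acetate,
succinyl-CoA/succinate), not acyl-CoA/CoA: the thioester *is* the main
carbon species in synthase/lyase reactions and stripping it against
free CoA would delete real backbone links such as acetyl-CoA → citrate.
The default table covers the common E. coli couples and is replaceable
by a ranked TSV; genome-scale link counts are sensitive to the exact
pair list, which is why it is user-replaceable.
Duplicate directed links are merged with their contributor reactions
retained. The GSC is the largest SCC (ties: lexicographically smallest
member set, with a warning); IN/OUT are ancestor/descendant sets of an
arbitrary GSC node, which is invariant to the choice.

## Comparison

The confusion matrix is computed over the node set common to both
partitions (graph-excluded endpoint species simply drop out of the
comparison). Members of gGSC \ fGSC are labelled produced_only /
consumed_only / neither from the FBA flags, reproducing the mechanism
taxonomy of false cores: carbon-free co-substrate links, double-walked
antiporters and unsourceable co-substrates.

## Fixture generator

The fixtures are the package's study conditions: seven deterministic,
element- and charge-balanced miniature SBML models, each instantiating
one diagnosed failure mode with a hand-derived expected FBA partition,
GBA partition and key yields (documented per case in
`bowtieflux.fixtures`). Real formulas and charges are used for named
metabolites; where a real reaction would drag 21-carbon nicotinamide
cofactors into a 10-species model, a balanced lumped variant is used
(marked `_L`), chosen redox-self-sufficient so the degree-of-reduction
bound stays valid (e.g. lysine synthesis burns extra pyruvate to CO2
for electrons and sits exactly on the γ bound of 5/7). What fixtures do
not emulate: model scale (tens of LPs rather than ~3,400), formula
gaps, imbalanced legacy reactions, and the authors' full currency-pair
table — so passing fixtures validates the machinery and the diagnosed
mechanisms, not the exact BiGG-scale counts, which additionally depend
on the published pair list and LP tolerances.

## Numerical choices and limitations

GLPK through optlang (COBRApy default); feasibility ε = 1e−6, reported
fluxes truncated below 1e−9; yield-threshold comparisons use a 1e−12
slack so exact-boundary yields (e.g. 3/13 vs 0.20 in the co-substrate
fixture) are not lost to rounding. Alternate optima are not enumerated
— connectivity needs only existence, not uniqueness, of a pathway. No
loopless constraints, flux-variability analysis, atom mapping,
gap-filling or automatic curation of imbalanced reactions; patches to a
model are the user's responsibility. Near-threshold metabolites at
genome scale can shift classification by a few members between solvers
and tolerances.
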