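# Methods

## Scope and model structure

`coremetab` models a deliberately reduced slice of metabolism: glucose and
glycerol catabolism through glycolysis, the Entner–Doudoroff (ED) pathway,
the pentose phosphate pathway (PPP) and the TCA cycle; eight fermentation
routes named by end product; and the respiratory chain. Two compartments
only (cytosol `_c`, extracellular `_e`); no periplasm. All internal
reactions are element- and charge-balanced at pH-7 protonation states
(checked by `validate_template`, with exchanges and the biomass drain
exempt), and every internal flux is bounded at ±1000 mmol/gDW/h so the LP
can never be unbounded through an internal loop.

The proton-motive force is represented chemically: pumping reactions move
`h_c` to `h_e` on top of their balanced redox chemistry, and the ATP
synthase runs on the extracellular proton pool. Because the medium's proton
exchange is open, the binding constraint on energy conversion is the
cytosolic proton balance; no free proton uniporter exists (it would let the
synthase run as a perpetual motion machine), and electrogenic couplings are
written irreversibly where a reverse direction would create a
proton-from-nothing cycle (e.g. NADH dehydrogenase II).

## ETC stoichiometry and the yield calibration

Translocation stoichiometries: NADH dehydrogenase I 4 H+/2e, cytochrome bo
oxidase 4 H+/2e, cytochrome bd oxidase 2 H+/2e, nitrate reductase 2 H+/2e,
TMAO and fumarate reductases 0, ATP synthase 4 H+/ATP, membrane
transhydrogenase 2 H+/NADPH. With these values alone the aerobic glucose
optimum is 26 mmol ATP/mmol glucose (4 substrate-level + 88 H+/4). Two
efflux couplings complete the calibration, both with physiological
precedent:

* CO2 venting co-exports 1/3 H+ per CO2 (encoded integrally as
  `3 co2_c + h_c → 3 co2_e + h_e`): +2 H+ per fully oxidized glucose,
  hence the aerobic optimum 26.5;
* formate leaves by H+ symport (FocA-like), while acetate leaves as the
  bare anion and ethanol by passive diffusion: the mixed-acid optimum
  (1 acetate : 1 ethanol : 2 formate per glucose) is then 2.75, with the
  synthase running 0.25 ATP/glucose in reverse to expel the surplus
  cytosolic protons.

Both values are reproduced by the LP from stoichiometry alone; nothing in
the solver knows the targets. The same stoichiometry yields 20.5 (nitrate),
17.5 (TMAO) and 14.25 (aerobic glycerol, per mol) — the expected acceptor
and carbon-source ordering.

Clostridial solventogenesis needs an electron valve that NAD-coupled
chemistry cannot provide (every acetyl-CoA made via pyruvate dehydrogenase
arrives with 2 NADH, which ethanol alone can absorb). The template
therefore carries pyruvate:ferredoxin oxidoreductase and a ferredoxin
hydrogenase producing H2, which makes butyrate/butanol/acetone secretion
redox-feasible for genomes annotated with them. Sulphate-, iron- and
chromium-reduction chains are deliberately excluded (inconsistently
annotated in practice), as is any thermodynamic reversibility estimation —
reversibility is fixed per template record.

## Biomass objective

The biomass drain consumes the 12 central-carbon precursors (G6P, F6P,
R5P, E4P, GAP, 3PG, PEP, pyruvate, acetyl-CoA, 2-oxoglutarate,
oxaloacetate, succinyl-CoA) with the classic E. coli flux-balance
coefficients (mmol/gDW): 0.205, 0.071, 0.898, 0.361, 0.129, 1.496, 0.519,
2.833, 3.748, 1.079, 1.787, and 0.1 for succinyl-CoA (the canonical
twelfth precursor, absent from the 11-entry source table; 0.1 is a modest
value consistent with its small biosynthetic demand). CoA thioesters
return free CoA. Cofactor terms: 41.257 ATP hydrolyzed, 18.225 NADPH
consumed, 3.547 NADH released per gDW.

## Reconstruction, media, and numerical choices

A reaction enters a model iff its GPR evaluates true over the genome's
roles (exact string match after whitespace/case normalization), or it is
`spontaneous` (passive diffusion) or `universal` (exchanges, mineral
transport, ATP hydrolysis, biomass) — the latter two classes keep FBA
well-posed on any genome, including an empty one. The seven packaged media
are {glucose, glycerol} × {O2, nitrate, TMAO} plus glucose with no
acceptor; carbon uptake is fixed at 10 mmol/gDW/h (immaterial for per-mol
yields — asserted by the scale-invariance test), minerals and protons are
unbounded, and unlisted compounds may be secreted but not imported.

LPs are solved with HiGHS (`scipy.optimize.linprog`) at a feasibility
tolerance of 1e-9; producibility and growth use a flux threshold of 1e-6.
Yields are unique even when flux vectors are degenerate; no
flux-variability analysis is attempted. Gapfilling is a MILP (binary
indicator per absent template reaction, uniform costs, minimize the sum)
solved by HiGHS branch-and-bound. The indicator big-M is 100 and the
required growth flux 0.1 — chosen so the solver's 1e-6 row tolerance times
the big-M stays two orders of magnitude below the smallest precursor
demand, preventing flux leakage through closed candidates from faking
growth; a post-hoc LP verifies every returned solution and solutions of
size ≤ 4 are certified minimal by exhaustive subset search. Ties between
equal-cardinality optima are broken toward lexicographically smaller
reaction ids by a cost perturbation of 1e-7 per rank.

## Pathway rules and classification

A pathway is present iff every step of its rule has at least one member
reaction in the model. Rules ship as data (`pathway_rules.json`), not
code. Product transporters are rule steps for lactate, acetate, formate
and butyrate; butanediol, butanol and acetone diffuse and need none. The
gluconolactonase step is retained in the ED and PPP rules (its reaction is
reported to proceed spontaneously in some organisms; curators can edit the
JSON to exempt it). Respiration: a chain = terminal reductase +
quinone-reducing dehydrogenase + ATP synthase; aerobic and anaerobic
chains together give "facultative", neither gives "none". Boolean presence
and FBA capability can legitimately disagree (a gene-complete pathway may
lack an anaerobic electron sink); `consistency_report` lists such cases
rather than reconciling them.

## Co-occurrence and phylogenetic reports

Correlation of two 0/1 pathway columns is Pearson r (= the phi
coefficient); significance from t = r·√((n−2)/(1−r²)) on n−2 df, raw
p < 0.05 by default with Holm correction opt-in. Profiles sharing a 16S
sequence key are first reduced to their highest-quality representative,
and analyses can be stratified by model size (<93 / 93–133 / >133
reactions). Zero-variance columns give explicitly undefined entries.

Tree collapse replaces each maximal rooted clade whose leaf-pairwise
patristic diameter is strictly below the threshold (default 0.01) by its
highest-quality leaf (lexicographic fallback). The pass is iterated to a
fixed point, which makes the operation idempotent even when two clade
representatives land closer than the threshold; trees with a basal
multifurcation are midpoint-rooted first. The outlier report flags leaves
whose pathway vector differs from every neighbour within 5× the threshold
— the screen for mis-propagated annotations (e.g. the packaged
Bacteroides-like fixture, whose spurious generic ubiquinol-oxidase role
makes an obligate anaerobe classify as aerobic).

## Synthetic data and what the tests show

The generator emits the union of roles satisfying the GPRs of the
requested pathways/ETC variants (all alternatives of every step, the first
alternative of OR-type GPRs), applies independent per-role dropout
(default 0 — the zero-noise closed loop is exact by construction and
verified for 100 random specs), and pads with decoy roles matching no GPR.
Real annotation noise is not independent per role (errors propagate along
lineages and subsystems), so passing recovery tests bound only this
idealized noise model; the seven organism-like fixtures (curated role
lists with manifests) cover the structured failure modes instead — missing
anaplerosis, missing gluconolactonase, spurious oxidase, parasite-style
pathway loss. Corpus-scale statistics from thousands of genomes are out of
scope; the suite substitutes property-based checks (conservation,
monotonicity, brute-force minimality, α-level error control) at sizes of
50–1000 synthetic profiles and 100 random trees, which run in seconds.

## Known limitations

* Two compartments; no explicit membrane potential — electrogenic costs
  appear only through proton counts, so anion efflux is free of charge
  work.
* Single quinone pool (no menaquinone/ubiquinone distinction), one NADH
  dehydrogenase pair, no formate dehydrogenases or hydrogen uptake.
* The CO2/H+ co-export is a calibration device standing in for the
  aggregate of unmodeled chemiosmotic couplings; it is harmless (export
  only, requires net CO2 production) but not a literal transporter.
* Gapfill candidates come from the template universe only, additions only
  (no reversibility relaxation beyond pre-split directions), uniform
  costs.
* SBML export is not provided; models round-trip as JSON/TSV.
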