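"""Flux balance analysis: hand-derived toys, conservation properties, and
the organism-fixture yield structure."""

from itertools import combinations, product

import numpy as np
import pytest
from scipy import sparse

import coremetab as cm
from coremetab.fba import FBAResult, LPSystem, ObjectiveError, build_lp, maximize, optimize
from coremetab.template import Media


def make_lp(S, lower, upper, objective, reaction_ids=None):
    S = np.asarray(S, dtype=float)
    ids = reaction_ids or [f"v{j}" for j in range(S.shape[1])]
    return LPSystem(
        reaction_ids=ids,
        compound_ids=[f"m{i}" for i in range(S.shape[0])],
        S=sparse.csr_matrix(S),
        lower=np.asarray(lower, dtype=float),
        upper=np.asarray(upper, dtype=float),
        objective=np.asarray(objective, dtype=float),
        carbon_exchange=None,
        _col={rid: j for j, rid in enumerate(ids)},
    )


def vertex_enumeration_max(S, lower, upper, objective, tol=1e-8):
    """Brute-force LP oracle: enumerate candidate vertices of
    {Sv=0, l<=v<=u} by fixing all but rank(S) variables at a bound and
    solving for the rest."""
    S = np.asarray(S, dtype=float)
    m = np.linalg.matrix_rank(S) if S.size else 0
    n = S.shape[1]
    best = None
    for free in combinations(range(n), m):
        fixed = [j for j in range(n) if j not in free]
        for choice in product(*[(lower[j], upper[j]) for j in fixed]):
            v = np.empty(n)
            v[fixed] = choice
            if m:
                A = S[:, free]
                b = -S[:, fixed] @ np.asarray(choice)
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                if np.linalg.norm(A @ sol - b) > tol:
                    continue
                v[list(free)] = sol
            if np.all(v >= np.asarray(lower) - tol) and np.all(v <= np.asarray(upper) + tol):
                value = float(np.dot(objective, v))
                best = value if best is None or value > best else best
    return best


class TestToyLP:
    def test_three_reaction_toy_yield_two(self):
        # uptake (<=10) ; lumped glc -> 2 atp ; atp hydrolysis (objective)
        S = [[1, -1, 0], [0, 2, -1]]
        lp = make_lp(S, [0, 0, 0], [10, 1000, 1000], [0, 0, 1])
        result = maximize(lp)
        assert result.status == "optimal"
        assert result.objective_value == pytest.approx(20.0)
        assert result.objective_value / 10.0 == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_optimum_matches_vertex_enumeration(self, seed):
        """On random <=10-reaction toys the LP optimum equals the
        brute-force vertex-enumeration optimum."""
        rng = np.random.default_rng(seed)
        m, n = 3, 6
        S = rng.integers(-2, 3, size=(m, n)).astype(float)
        lower = np.where(rng.random(n) < 0.5, -5.0, 0.0)
        upper = np.full(n, 5.0)
        objective = rng.integers(-2, 3, size=n).astype(float)
        lp = make_lp(S, lower, upper, objective)
        result = maximize(lp)
        oracle = vertex_enumeration_max(S, lower, upper, objective)
        assert result.status == "optimal"
        assert oracle is not None
        assert result.objective_value == pytest.approx(oracle, abs=1e-6)


class TestYields:
    def test_aerobic_and_fermentative_anchor_yields(self, template, ecoli):
        aerobic = optimize(ecoli, template.media_library["glucose_o2"])
        ferment = optimize(ecoli, template.media_library["glucose_none"])
        assert aerobic.yield_per_carbon == pytest.approx(26.5, abs=1e-6)
        assert ferment.yield_per_carbon == pytest.approx(2.75, abs=1e-6)

    def test_clostridium_yield_invariant_to_acceptors(self, template, models):
        clos = models["clostridium_like"]
        media = [template.media_library[n] for n in ("glucose_none", "glucose_no3", "glucose_tmao")]
        table = cm.atp_yield_matrix([clos], media)
        yields = table["atp_yield"].to_numpy()
        assert np.allclose(yields, yields[0], atol=1e-6)

    def test_glycerol_per_mol_yield_below_glucose(self, template, ecoli):
        glc = optimize(ecoli, template.media_library["glucose_no3"])
        gly = optimize(ecoli, template.media_library["glycerol_no3"])
        assert gly.yield_per_carbon < glc.yield_per_carbon

    def test_empty_model_list_gives_empty_table(self, template):
        table = cm.atp_yield_matrix([], list(template.media_library.values()))
        assert len(table) == 0

    def test_atp_objective_has_single_nonzero_entry(self, template, ecoli):
        lp = build_lp(ecoli, template.media_library["glucose_o2"], "atp_hydrolysis")
        assert int(np.count_nonzero(lp.objective)) == 1
        assert lp.objective[lp.column("ATPM")] == 1.0

    def test_biomass_column_carries_twelve_precursors(self, template, ecoli):
        lp = build_lp(ecoli, template.media_library["glucose_o2"], "biomass")
        j = lp.column("BIOMASS")
        col = lp.S[:, j].toarray().ravel()
        consumed = {lp.compound_ids[i] for i in np.nonzero(col < 0)[0]}
        precursors = {cid for cid, _ in template.biomass.precursors}
        assert precursors <= consumed

    def test_drain_objective_adds_sink_column(self, template, ecoli):
        med = template.media_library["glucose_o2"]
        lp = build_lp(ecoli, med, ("drain", "oaa_c"))
        assert "DM_oaa_c" in lp.reaction_ids
        base = build_lp(ecoli, med, "atp_hydrolysis")
        assert len(lp.reaction_ids) == len(base.reaction_ids) + 1

    def test_unknown_drain_compound_rejected(self, template, ecoli):
        with pytest.raises(ObjectiveError):
            build_lp(ecoli, template.media_library["glucose_o2"], ("drain", "unobtainium_c"))


class TestConservation:
    def test_no_free_lunch_all_exchanges_closed(self, template, ecoli, closed_media):
        result = optimize(ecoli, closed_media)
        assert result.status == "optimal"
        assert result.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_scale_invariance_of_yield(self, template, ecoli):
        base = template.media_library["glucose_o2"]
        doubled = Media(
            name="glucose_o2_x2",
            exchange_bounds={**base.exchange_bounds, "glc__D_e": (20, 0)},
            carbon_source=base.carbon_source,
            electron_acceptor=base.electron_acceptor,
        )
        r1 = optimize(ecoli, base)
        r2 = optimize(ecoli, doubled)
        assert r2.objective_value == pytest.approx(2 * r1.objective_value, rel=1e-6)
        assert r2.yield_per_carbon == pytest.approx(r1.yield_per_carbon, rel=1e-6)

    def test_opening_acceptor_never_decreases_yield(self, template, ecoli):
        none = optimize(ecoli, template.media_library["glucose_none"]).objective_value
        for name in ("glucose_tmao", "glucose_no3", "glucose_o2"):
            with_acc = optimize(ecoli, template.media_library[name]).objective_value
            assert with_acc >= none - 1e-9

    def test_mixed_respiro_fermentative_optimum_exists(self, template, ecoli):
        """Under oxygen limitation the optimal flux state runs the terminal
        oxidases and secretes fermentation products simultaneously."""
        base = template.media_library["glucose_o2"]
        limited = Media(
            name="glucose_o2_limited",
            exchange_bounds={**base.exchange_bounds, "o2_e": (5, 1000)},
            carbon_source=base.carbon_source,
            electron_acceptor="o2_e",
        )
        r = optimize(ecoli, limited)
        oxidase = r.fluxes["CYTBO3"] + r.fluxes["CYTBD"]
        secretion = sum(
            r.fluxes[f"EX_{c}"] for c in ("ac_e", "etoh_e", "for_e", "lac__D_e")
        )
        assert oxidase > 1e-6 and secretion > 1e-6


class TestProducibility:
    def test_ecoli_produces_all_twelve_precursors(self, template, ecoli):
        prod = cm.precursor_producibility(ecoli, template.media_library["glucose_o2"])
        assert len(prod) == 12
        assert all(prod.values())

    def test_tca_deletion_breaks_oxoglutarate(self, template, ecoli):
        tca = {rid for rid in ecoli.reactions if "tca" in template.reactions[rid].pathway_tags}
        pruned = cm.CoreModel(
            genome_id="ecoli_no_tca",
            template=template,
            reactions={r: t for r, t in ecoli.reactions.items() if r not in tca},
        )
        prod = cm.precursor_producibility(pruned, template.media_library["glucose_o2"])
        assert prod["akg_c"] is False
        assert prod["g6p_c"] is True

    def test_closed_media_nothing_producible(self, template, ecoli, closed_media):
        prod = cm.precursor_producibility(ecoli, closed_media)
        assert not any(prod.values())


class TestIndependentSolverOracle:
    def test_aerobic_yield_reproduced_by_cobra_glpk(self, template, ecoli):
        """Cross-check the HiGHS LP against an entirely separate FBA stack
        (COBRApy with the GLPK solver) on the same stoichiometry."""
        cobra = pytest.importorskip("cobra")
        lp = build_lp(ecoli, template.media_library["glucose_o2"], "atp_hydrolysis")
        model = cobra.Model("ecoli_like")
        mets = {cid: cobra.Metabolite(cid) for cid in lp.compound_ids}
        rxns = []
        S = lp.S.tocsc()
        for j, rid in enumerate(lp.reaction_ids):
            rxn = cobra.Reaction(rid, lower_bound=lp.lower[j], upper_bound=lp.upper[j])
            col = S[:, j]
            rxn.add_metabolites(
                {mets[lp.compound_ids[i]]: float(v) for i, v in zip(col.indices, col.data)}
            )
            rxns.append(rxn)
        model.add_reactions(rxns)
        model.solver = "glpk"
        model.objective = "ATPM"
        solution = model.optimize()
        assert solution.status == "optimal"
        assert solution.objective_value / 10.0 == pytest.approx(26.5, abs=1e-6)
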