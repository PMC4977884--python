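"""Gapfilling: minimum-cardinality reaction additions restoring growth.

Finds the smallest set of template reactions absent from a core model whose
addition lets the model carry objective (biomass) flux on a medium. Posed as
a mixed-integer linear program: one binary indicator per candidate reaction,
big-M coupled to its flux, minimizing the indicator sum; solved by
branch-and-bound (HiGHS via :func:`scipy.optimize.milp`). Candidates are
restricted to the template universe. Ties between equal-cardinality optima
are broken toward lexicographically smaller reaction-id sets by an
index-ordered cost perturbation far below 1/n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp

from .fba import PRODUCIBILITY_EPS, optimize
from .reconstruct import CoreModel
from .template import DEFAULT_FLUX_BOUND, Media, Template

__all__ = ["GapfillSolution", "gapfill", "alternate_carbon_rescue", "RESCUE_SOURCES"]

#: growth flux the MILP must restore. Kept well above the solver's row
#: tolerance times the big-M so closed candidates cannot leak enough flux to
#: fake growth; any truly feasible addition set reaches this level at a
#: carbon uptake of 10 mmol/gDW/h.
GROWTH_TARGET = 0.1
#: big-M coupling candidate fluxes to their indicators. Candidate fluxes in
#: a minimal solution stay far below this at the growth target.
GAPFILL_BIG_M = 100.0

RESCUE_SOURCES = {
    "glycerol": "glyc_e",
    "lactate": "lac__D_e",
    "succinate": "succ_e",
    "ribose": "rib__D_e",
}


@dataclass
class GapfillSolution:
    status: str  # "optimal" | "already_feasible" | "unfillable"
    added_reaction_ids: frozenset[str]
    objective_flux_after: float
    minimal: bool | None = None  # exhaustively verified for solutions of size <= 4

    @property
    def ok(self) -> bool:
        return self.status in ("optimal", "already_feasible")


def _objective_flux(model: CoreModel, media: Media, objective) -> float:
    result = optimize(model, media, objective)
    return result.objective_value if result.optimal else 0.0


def gapfill(
    model: CoreModel,
    template: Template,
    media: Media,
    objective: str = "biomass",
    epsilon: float = PRODUCIBILITY_EPS,
    verify_minimal_up_to: int = 4,
    candidates: list[str] | None = None,
) -> GapfillSolution:
    """Cardinality-minimal addition set from the template universe.

    Returns an ``already_feasible`` empty solution if the model grows as-is,
    and an ``unfillable`` result (not an exception) when no addition set can
    restore growth (e.g. the carbon source is unusable by the template).
    """
    before = _objective_flux(model, media, objective)
    if before > epsilon:
        return GapfillSolution("already_feasible", frozenset(), before, minimal=True)

    if candidates is None:
        candidates = [
            rid
            for rid, rxn in template.reactions.items()
            if rid not in model.reactions and rxn.kind == "gene"
        ]
    candidates = sorted(set(candidates) - set(model.reactions))
    full = model.with_added(set(candidates))
    from .fba import build_lp  # deferred to keep module import-light

    lp = build_lp(full, media, objective)
    n = len(lp.reaction_ids)
    k = len(candidates)
    cand_col = np.array([lp.column(rid) for rid in candidates], dtype=int)

    # variables: [v (n fluxes), y (k binaries)]
    c = np.zeros(n + k)
    c[n:] = 1.0 + 1e-7 * np.arange(k)  # lexicographic tie-break perturbation

    constraints = [
        LinearConstraint(
            sparse.hstack([lp.S, sparse.csr_matrix((lp.S.shape[0], k))]),
            np.zeros(lp.S.shape[0]),
            np.zeros(lp.S.shape[0]),
        )
    ]
    # v_j - ub_j * y_j <= 0  and  v_j - lb_j * y_j >= 0 for candidates
    rows_u = sparse.lil_matrix((k, n + k))
    rows_l = sparse.lil_matrix((k, n + k))
    for i, j in enumerate(cand_col):
        rows_u[i, j] = 1.0
        rows_u[i, n + i] = -min(lp.upper[j], GAPFILL_BIG_M)
        rows_l[i, j] = 1.0
        rows_l[i, n + i] = -max(lp.lower[j], -GAPFILL_BIG_M)
    constraints.append(LinearConstraint(rows_u.tocsr(), -np.inf, np.zeros(k)))
    constraints.append(LinearConstraint(rows_l.tocsr(), np.zeros(k), np.inf))
    # objective flux >= growth target
    grow = sparse.lil_matrix((1, n + k))
    for rid, coeff in zip(lp.reaction_ids, lp.objective):
        if coeff:
            grow[0, lp.column(rid)] = coeff
    constraints.append(LinearConstraint(grow.tocsr(), GROWTH_TARGET, np.inf))

    lower = np.concatenate([lp.lower, np.zeros(k)])
    upper = np.concatenate([lp.upper, np.ones(k)])
    integrality = np.concatenate([np.zeros(n), np.ones(k)])
    res = milp(
        c=c,
        constraints=constraints,
        bounds=_bounds(lower, upper),
        integrality=integrality,
    )
    if res.status != 0 or res.x is None:
        return GapfillSolution("unfillable", frozenset(), 0.0)

    chosen = frozenset(
        candidates[i] for i in range(k) if res.x[n + i] > 0.5
    )
    after_model = model.with_added(set(chosen))
    after = _objective_flux(after_model, media, objective)
    if after <= epsilon:
        raise RuntimeError(
            f"gapfill solution {sorted(chosen)} failed post-verification "
            f"(flux {after:.3g}); MILP tolerances too loose for this instance"
        )
    minimal = None
    if len(chosen) <= verify_minimal_up_to:
        minimal = _verify_minimal(model, media, objective, chosen, epsilon)
    return GapfillSolution("optimal", chosen, after, minimal=minimal)


def _bounds(lower: np.ndarray, upper: np.ndarray):
    from scipy.optimize import Bounds

    return Bounds(lower, upper)


def _verify_minimal(model, media, objective, chosen, epsilon) -> bool:
    """No proper subset of the additions restores growth (exhaustive check)."""
    for size in range(len(chosen)):
        for subset in combinations(sorted(chosen), size):
            if _objective_flux(model.with_added(set(subset)), media, objective) > epsilon:
                return False
    return True


def alternate_carbon_rescue(
    model: CoreModel,
    template: Template,
    base_media_name: str = "glucose_o2",
    epsilon: float = PRODUCIBILITY_EPS,
) -> dict[str, bool]:
    """For a model that fails biomass on glucose: can any of glycerol,
    lactate, succinate or ribose support growth instead (un-gapfilled FBA)?

    Raises ``ValueError`` if the model already grows on glucose.
    """
    base = template.media_library[base_media_name]
    if _objective_flux(model, base, "biomass") > epsilon:
        raise ValueError(
            f"model {model.genome_id} grows on glucose; alternate-carbon rescue "
            "applies only to glucose-negative models"
        )
    out: dict[str, bool] = {}
    for source, compound_e in RESCUE_SOURCES.items():
        bounds = {k: v for k, v in base.exchange_bounds.items() if k != base.carbon_source}
        bounds[compound_e] = base.exchange_bounds[base.carbon_source]
        med = Media(
            name=f"{source}_{base.electron_acceptor or 'none'}",
            exchange_bounds=bounds,
            carbon_source=compound_e,
            electron_acceptor=base.electron_acceptor,
        )
        out[source] = _objective_flux(model, med, "biomass") > epsilon
    return out
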