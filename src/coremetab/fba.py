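"""Flux balance analysis on core models.

Assembles the stoichiometric linear program ``max c'v s.t. Sv = 0,
l <= v <= u`` for a core model under a medium and solves it with HiGHS
(:func:`scipy.optimize.linprog`). Steady state is enforced for every
compound, cytosolic and extracellular alike; extracellular species reach the
boundary only through exchange reactions, whose bounds the medium sets
(negative flux = uptake, positive = secretion).

Two stock objectives mirror the two objective functions of the pipeline:
the ATP hydrolysis reaction (ATP + H2O -> ADP + Pi + H+) and the
biomass-precursor drain. A per-compound drain objective supports precursor
producibility tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .reconstruct import CoreModel
from .template import DEFAULT_FLUX_BOUND, Media, Reaction, Template

__all__ = [
    "FEASIBILITY_TOL",
    "PRODUCIBILITY_EPS",
    "LPSystem",
    "FBAResult",
    "ObjectiveError",
    "build_lp",
    "maximize",
    "optimize",
    "atp_yield_matrix",
    "precursor_producibility",
]

#: LP feasibility/optimality tolerance
FEASIBILITY_TOL = 1e-9
#: flux threshold above which a drain counts as producible
PRODUCIBILITY_EPS = 1e-6

ATP_HYDROLYSIS_ID = "ATPM"
BIOMASS_ID = "BIOMASS"


class ObjectiveError(ValueError):
    """Objective references a reaction or compound absent from the model."""


@dataclass
class LPSystem:
    """The assembled LP: column order fixed by ``reaction_ids``."""

    reaction_ids: list[str]
    compound_ids: list[str]
    S: sparse.csr_matrix
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    carbon_exchange: str | None = None
    _col: dict[str, int] = field(default_factory=dict)

    def column(self, reaction_id: str) -> int:
        return self._col[reaction_id]


@dataclass
class FBAResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float]
    yield_per_carbon: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _model_reactions(model: CoreModel) -> list[Reaction]:
    template = model.template
    rxns = [template.reactions[rid] for rid in sorted(model.reactions)]
    rxns.append(template.biomass_reaction())
    return rxns


def _drain_reaction(template: Template, compound_id: str) -> Reaction:
    from .template import _COA_CARRIERS  # shared thioester convention

    if compound_id not in template.compounds:
        raise ObjectiveError(f"unknown compound for drain objective: {compound_id}")
    stoich = {compound_id: Fraction(-1)}
    if compound_id in _COA_CARRIERS:
        stoich[_COA_CARRIERS[compound_id]] = Fraction(1)
    return Reaction(
        id=f"DM_{compound_id}",
        name=f"Sink for {compound_id}",
        stoichiometry=stoich,
        lower=0.0,
        upper=DEFAULT_FLUX_BOUND,
        kind="universal",
    )


def build_lp(
    model: CoreModel,
    media: Media,
    objective: str | tuple[str, str] | Mapping[str, float] = "atp_hydrolysis",
) -> LPSystem:
    """Assemble the LP for ``model`` under ``media``.

    ``objective`` is ``"atp_hydrolysis"``, ``"biomass"``, ``("drain", cid)``
    for a single-compound sink, or an explicit reaction-id -> coefficient map.
    """
    template = model.template
    reactions = _model_reactions(model)

    if objective == "atp_hydrolysis":
        objective_map: Mapping[str, float] = {ATP_HYDROLYSIS_ID: 1.0}
    elif objective == "biomass":
        objective_map = {BIOMASS_ID: 1.0}
    elif isinstance(objective, tuple) and len(objective) == 2 and objective[0] == "drain":
        drain = _drain_reaction(template, objective[1])
        reactions.append(drain)
        objective_map = {drain.id: 1.0}
    elif isinstance(objective, Mapping):
        objective_map = objective
    else:
        raise ObjectiveError(f"unrecognized objective {objective!r}")

    ids = [r.id for r in reactions]
    col = {rid: j for j, rid in enumerate(ids)}
    for rid in objective_map:
        if rid not in col:
            raise ObjectiveError(f"objective reaction {rid} not in model")

    compound_ids = sorted({cid for r in reactions for cid in r.stoichiometry})
    row = {cid: i for i, cid in enumerate(compound_ids)}
    data, rows, cols = [], [], []
    lower = np.empty(len(reactions))
    upper = np.empty(len(reactions))
    carbon_exchange = None
    for j, rxn in enumerate(reactions):
        if rxn.is_exchange():
            species = next(iter(rxn.stoichiometry))
            uptake, secretion = media.bounds_for(species)
            lower[j], upper[j] = -uptake, secretion
            if species == media.carbon_source:
                carbon_exchange = rxn.id
        else:
            lower[j], upper[j] = rxn.lower, rxn.upper
        for cid, coeff in rxn.stoichiometry.items():
            rows.append(row[cid])
            cols.append(j)
            data.append(float(coeff))

    S = sparse.csr_matrix((data, (rows, cols)), shape=(len(compound_ids), len(reactions)))
    c = np.zeros(len(reactions))
    for rid, coeff in objective_map.items():
        c[col[rid]] = coeff
    return LPSystem(
        reaction_ids=ids,
        compound_ids=compound_ids,
        S=S,
        lower=lower,
        upper=upper,
        objective=c,
        carbon_exchange=carbon_exchange,
        _col=col,
    )


def maximize(lp: LPSystem) -> FBAResult:
    """Solve ``max c'v s.t. Sv = 0, l <= v <= u`` and normalize the optimum
    by carbon uptake when the medium defines a carbon source."""
    res = linprog(
        c=-lp.objective,
        A_eq=lp.S,
        b_eq=np.zeros(lp.S.shape[0]),
        bounds=np.column_stack([lp.lower, lp.upper]),
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    if res.status == 3:
        cycle = [rid for rid, c in zip(lp.reaction_ids, lp.objective) if c]
        raise RuntimeError(f"LP unbounded through objective reactions {cycle}")
    if res.status != 0 or res.x is None:
        return FBAResult(status="infeasible", objective_value=0.0, fluxes={})
    fluxes = dict(zip(lp.reaction_ids, res.x))
    value = float(-res.fun)
    carbon_yield = None
    if lp.carbon_exchange is not None:
        uptake = -fluxes[lp.carbon_exchange]
        if uptake > PRODUCIBILITY_EPS:
            carbon_yield = value / uptake
    return FBAResult(
        status="optimal", objective_value=value, fluxes=fluxes, yield_per_carbon=carbon_yield
    )


def optimize(
    model: CoreModel,
    media: Media,
    objective: str | tuple[str, str] | Mapping[str, float] = "atp_hydrolysis",
) -> FBAResult:
    """Convenience: build the LP and maximize in one call."""
    return maximize(build_lp(model, media, objective))


def atp_yield_matrix(
    models: Sequence[CoreModel], media: Sequence[Media]
) -> pd.DataFrame:
    """One row per (model, medium): ATP-hydrolysis optimum, per-carbon yield
    and solver status. Failed solves are recorded with yield 0 and flagged."""
    records = []
    for model in models:
        for med in media:
            result = optimize(model, med, "atp_hydrolysis")
            records.append(
                {
                    "genome_id": model.genome_id,
                    "media": med.name,
                    "status": result.status,
                    "atp_flux": result.objective_value if result.optimal else 0.0,
                    "atp_yield": (
                        result.yield_per_carbon
                        if result.optimal and result.yield_per_carbon is not None
                        else 0.0
                    ),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["genome_id", "media", "status", "atp_flux", "atp_yield"]
    )


def precursor_producibility(
    model: CoreModel, media: Media, epsilon: float = PRODUCIBILITY_EPS
) -> dict[str, bool]:
    """Per-precursor Boolean: producible iff the maximal drain flux of the
    precursor exceeds ``epsilon`` under the medium."""
    out: dict[str, bool] = {}
    for cid, _coeff in model.template.biomass.precursors:
        result = optimize(model, media, ("drain", cid))
        out[cid] = result.optimal and result.objective_value > epsilon
    return out
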