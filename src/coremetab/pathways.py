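"""Boolean pathway-presence rules, respiration classification, and
fermentation-product capability.

A pathway rule is an ordered list of steps; each step is a set of
alternative reaction ids. A pathway is called present iff every step has at
least one member reaction in the model — alternatives within a step are
allowed, but no step may be missing entirely.

The 12 pathways split into four glucose-oxidation routes (glycolysis,
Entner-Doudoroff, TCA cycle, pentose phosphate) and eight fermentation
routes named by end product (lactate, acetate, formate, ethanol,
2,3-butanediol, butyrate, butanol, acetone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .reconstruct import CoreModel
    from .template import Media, Template

__all__ = [
    "GLUCOSE_OXIDATION_PATHWAYS",
    "FERMENTATION_PATHWAYS",
    "PATHWAY_NAMES",
    "FERMENTATION_PRODUCTS",
    "PathwayRuleSet",
    "PathwayProfile",
    "determine_pathways",
    "classify_respiration",
    "fermentation_capability",
    "consistency_report",
]

GLUCOSE_OXIDATION_PATHWAYS = ("glycolysis", "entner_doudoroff", "tca", "pentose_phosphate")
FERMENTATION_PATHWAYS = (
    "lactate",
    "acetate",
    "formate",
    "ethanol",
    "butanediol",
    "butyrate",
    "butanol",
    "acetone",
)
PATHWAY_NAMES = GLUCOSE_OXIDATION_PATHWAYS + FERMENTATION_PATHWAYS

#: fermentation end product -> extracellular compound id
FERMENTATION_PRODUCTS: dict[str, str] = {
    "lactate": "lac__D_e",
    "acetate": "ac_e",
    "formate": "for_e",
    "ethanol": "etoh_e",
    "butanediol": "btd_e",
    "butyrate": "but_e",
    "butanol": "btoh_e",
    "acetone": "act_e",
}


@dataclass(frozen=True)
class PathwayRuleSet:
    """Exactly 12 named pathway rules; each rule an ordered tuple of steps,
    each step a frozenset of alternative reaction ids."""

    rules: Mapping[str, tuple[frozenset[str], ...]]

    def __post_init__(self):
        names = tuple(self.rules)
        if sorted(names) != sorted(PATHWAY_NAMES):
            raise ValueError(
                f"pathway rule set must define exactly the 12 pathways {sorted(PATHWAY_NAMES)}, "
                f"got {sorted(names)}"
            )

    @classmethod
    def from_dict(cls, raw: Mapping[str, list[list[str]]]) -> "PathwayRuleSet":
        return cls(
            rules={
                name: tuple(frozenset(step) for step in steps) for name, steps in raw.items()
            }
        )

    def to_dict(self) -> dict[str, list[list[str]]]:
        return {name: [sorted(step) for step in steps] for name, steps in self.rules.items()}

    def referenced_reactions(self) -> set[str]:
        out: set[str] = set()
        for steps in self.rules.values():
            for step in steps:
                out |= step
        return out


@dataclass
class PathwayProfile:
    genome_id: str
    presence: dict[str, bool]  # keys: the 12 pathway names
    respiration: str  # aerobic | anaerobic | facultative | none
    model_size: int
    seq_key: str | None = None
    quality: float | None = None

    def __post_init__(self):
        if sorted(self.presence) != sorted(PATHWAY_NAMES):
            raise ValueError("presence keys must be exactly the 12 pathway names")

    def vector(self) -> tuple[bool, ...]:
        return tuple(self.presence[name] for name in PATHWAY_NAMES)


def evaluate_rule(steps: Iterable[frozenset[str]], reaction_ids: set[str]) -> bool:
    """Present iff every step has at least one member reaction in the model."""
    return all(bool(step & reaction_ids) for step in steps)


def determine_pathways(model: "CoreModel", rules: PathwayRuleSet | None = None) -> PathwayProfile:
    """Evaluate the 12 Boolean pathway rules against a core model and
    classify its respiration type."""
    template = model.template
    if rules is None:
        rules = template.pathway_rules
    present = set(model.reactions)
    presence = {name: evaluate_rule(steps, present) for name, steps in rules.rules.items()}
    return PathwayProfile(
        genome_id=model.genome_id,
        presence=presence,
        respiration=classify_respiration(model),
        model_size=len(model.reactions),
        seq_key=model.seq_key,
        quality=model.quality,
    )


def classify_respiration(model: "CoreModel") -> str:
    """Classify respiration from ETC component tags.

    A chain requires a terminal reductase, an electron-donating dehydrogenase
    and the ATP synthase. Organisms with an aerobic chain only are aerobic,
    with an anaerobic chain only anaerobic, with both facultative; organisms
    with neither rely on substrate-level phosphorylation alone ("none").
    """
    tags = {
        model.template.reactions[rid].etc_tag
        for rid in model.reactions
        if model.template.reactions[rid].etc_tag
    }
    powered = "dehydrogenase" in tags and "atp_synthase" in tags
    aerobic = powered and "aerobic_terminal" in tags
    anaerobic = powered and "anaerobic_terminal" in tags
    if aerobic and anaerobic:
        return "facultative"
    if aerobic:
        return "aerobic"
    if anaerobic:
        return "anaerobic"
    return "none"


def fermentation_capability(
    model: "CoreModel", media: "Media", epsilon: float = 1e-6
) -> dict[str, bool]:
    """FBA test of the eight fermentation end products: a product is capable
    iff its maximal secretion flux under the (acceptor-free) medium exceeds
    ``epsilon``, i.e. the model can form it redox-balanced from the carbon
    source."""
    from .fba import build_lp, maximize  # deferred: fba imports template

    if media.electron_acceptor is not None:
        raise ValueError("fermentation capability requires an acceptor-free medium")
    out: dict[str, bool] = {}
    for product, compound_e in FERMENTATION_PRODUCTS.items():
        exchange = f"EX_{compound_e}"
        if exchange not in model.template.reactions:
            out[product] = False
            continue
        lp = build_lp(model, media, objective={exchange: 1.0})
        result = maximize(lp)
        out[product] = result.status == "optimal" and result.objective_value > epsilon
    return out


def consistency_report(model: "CoreModel", media: "Media") -> list[dict]:
    """Compare Boolean fermentation-pathway presence with FBA capability.

    A pathway can be gene-complete yet flux-incapable when the model lacks an
    electron sink to balance its redox demand (and vice versa a product can
    be reachable through reactions outside the named pathway). Such
    disagreements are reported rather than silently reconciled.
    """
    profile = determine_pathways(model)
    caps = fermentation_capability(model, media)
    substrate_reachable = (
        profile.presence["glycolysis"] or profile.presence["entner_doudoroff"]
    )
    report = []
    for product in FERMENTATION_PRODUCTS:
        boolean = profile.presence[product] and substrate_reachable
        if boolean != caps[product]:
            report.append(
                {
                    "genome_id": model.genome_id,
                    "pathway": product,
                    "boolean_present": profile.presence[product],
                    "fba_capable": caps[product],
                }
            )
    return report
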