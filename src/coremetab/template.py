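"""The core model template (CMT): curated universe of compounds, reactions,
GPR rules, biomass-precursor spec, pathway rules and packaged minimal media.

The template is the fixed reaction universe from which per-genome core models
are instantiated. It covers central carbon metabolism (glycolysis,
Entner-Doudoroff, TCA cycle, pentose phosphate), eight fermentation routes,
and explicit electron-transport-chain variants with proton-translocation
stoichiometry, in a two-compartment world (cytosol ``_c``, extracellular
``_e``). The proton-motive force is represented by distinct cytosolic and
extracellular proton species; every internal reaction is element- and
charge-balanced with translocated protons counted in their destination
compartment.

On disk a template is a directory::

    compounds.tsv       id, name, formula, charge, compartment
    reactions.tsv       id, name, equation, lower, upper, kind, gpr,
                        pathway_tags, etc_tag, proton_translocation
    biomass.json        12 precursors + ATP/NADH/NADPH cofactor terms
    pathway_rules.json  12 Boolean pathway rules (ordered steps of
                        alternative reaction ids)
    media/*.json        the packaged minimal media

Equations use a ``n A + m B <=> k C`` dialect with explicit compartment
suffixes; ``=>`` marks irreversible reactions and coefficients may be
rational (``1/3``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

from ._formula import FormulaError, parse_formula
from .gpr import GprExpr, parse_gpr
from .pathways import PathwayRuleSet

__all__ = [
    "Compound",
    "Reaction",
    "BiomassSpec",
    "Media",
    "Template",
    "ValidationFinding",
    "ValidationReport",
    "TemplateParseError",
    "TemplateIntegrityError",
    "load_template",
    "write_template",
    "load_packaged_template",
]

COMPARTMENTS = {"cytosol": "_c", "extracellular": "_e"}
REACTION_KINDS = {"gene", "spontaneous", "universal"}
ETC_TAGS = {"aerobic_terminal", "anaerobic_terminal", "dehydrogenase", "atp_synthase"}

#: default flux cap on internal reactions (prevents unbounded internal loops)
DEFAULT_FLUX_BOUND = 1000.0


class TemplateParseError(ValueError):
    """Malformed template file; message names the offending record."""


class TemplateIntegrityError(ValueError):
    """Cross-reference failure (dangling compound, missing rule target ...)."""


@dataclass(frozen=True)
class Compound:
    id: str
    name: str
    formula: str
    charge: int
    compartment: str  # "cytosol" | "extracellular"

    @property
    def elements(self) -> dict[str, int]:
        return parse_formula(self.formula)


@dataclass
class Reaction:
    id: str
    name: str
    stoichiometry: dict[str, Fraction]  # compound id -> signed coefficient
    lower: float
    upper: float
    kind: str = "gene"  # gene | spontaneous | universal
    gpr: GprExpr | None = None
    pathway_tags: frozenset[str] = frozenset()
    etc_tag: str | None = None
    proton_translocation: int = 0

    @property
    def reversible(self) -> bool:
        return self.lower < 0

    def is_exchange(self) -> bool:
        """Exchange: a single extracellular species crossing the boundary."""
        return len(self.stoichiometry) == 1 and next(iter(self.stoichiometry)).endswith("_e")


@dataclass(frozen=True)
class BiomassSpec:
    """Biomass-precursor drain: 12 central-carbon precursors plus ATP,
    NADH and NADPH cofactor terms (mmol per gDW biomass)."""

    precursors: tuple[tuple[str, float], ...]
    atp: float
    nadh: float
    nadph: float

    def __post_init__(self):
        if len(self.precursors) != 12:
            raise TemplateIntegrityError(
                f"biomass spec must name exactly 12 precursors, got {len(self.precursors)}"
            )
        if any(coeff == 0 for _, coeff in self.precursors):
            raise TemplateIntegrityError("biomass precursor coefficients must be nonzero")


@dataclass(frozen=True)
class Media:
    """A named minimal medium: per-exchange (max uptake, max secretion) bounds
    in mmol/gDW/h. Compounds not listed may be secreted freely but not taken up."""

    name: str
    exchange_bounds: Mapping[str, tuple[float, float]]
    carbon_source: str
    electron_acceptor: str | None = None

    def bounds_for(self, compound_id: str) -> tuple[float, float]:
        return tuple(self.exchange_bounds.get(compound_id, (0.0, DEFAULT_FLUX_BOUND)))


# CoA thioester precursors whose drain returns free CoA (the acetyl/succinyl
# moiety is what biomass consumes; the carrier is recycled).
_COA_CARRIERS = {"accoa_c": "coa_c", "succoa_c": "coa_c"}


@dataclass
class Template:
    compounds: dict[str, Compound]
    reactions: dict[str, Reaction]
    biomass: BiomassSpec
    pathway_rules: PathwayRuleSet
    media_library: dict[str, Media]
    role_index: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.role_index:
            self.role_index = self._build_role_index()

    def _build_role_index(self) -> dict[str, set[str]]:
        index: dict[str, set[str]] = {}
        for rxn in self.reactions.values():
            if rxn.gpr is not None:
                for role in rxn.gpr.leaves():
                    index.setdefault(role, set()).add(rxn.id)
        return index

    # -- convenience views -------------------------------------------------
    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange()]

    def always_included_ids(self) -> set[str]:
        """Reactions present in every model: universal housekeeping
        (exchanges, ATP hydrolysis, mineral transport, biomass) and
        spontaneous (passive diffusion) reactions."""
        return {r.id for r in self.reactions.values() if r.kind in ("universal", "spontaneous")}

    def biomass_reaction(self) -> Reaction:
        """Assemble the biomass drain reaction from the precursor spec."""
        stoich: dict[str, Fraction] = {}

        def add(cid: str, coeff: float) -> None:
            stoich[cid] = stoich.get(cid, Fraction(0)) + Fraction(str(coeff))

        for cid, coeff in self.biomass.precursors:
            add(cid, -coeff)
            if cid in _COA_CARRIERS:
                add(_COA_CARRIERS[cid], coeff)
        # growth-associated ATP hydrolysis
        add("atp_c", -self.biomass.atp)
        add("h2o_c", -self.biomass.atp)
        add("adp_c", self.biomass.atp)
        add("pi_c", self.biomass.atp)
        add("h_c", self.biomass.atp)
        # requirement r consumes r units of the reduced cofactor and returns
        # the oxidized form; a negative requirement (NADH here) is a release
        add("nadph_c", -self.biomass.nadph)
        add("nadp_c", self.biomass.nadph)
        add("nadh_c", -self.biomass.nadh)
        add("nad_c", self.biomass.nadh)
        return Reaction(
            id="BIOMASS",
            name="Biomass precursor drain (Varma-Palsson stoichiometry)",
            stoichiometry=stoich,
            lower=0.0,
            upper=DEFAULT_FLUX_BOUND,
            kind="universal",
        )


@dataclass(frozen=True)
class ValidationFinding:
    reaction_id: str
    kind: str  # "element" | "charge" | "reference"
    detail: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding]

    @property
    def ok(self) -> bool:
        return not self.findings

    def __iter__(self):
        return iter(self.findings)

    def __len__(self):
        return len(self.findings)


# --------------------------------------------------------------------------
# equation dialect


def parse_equation(text: str) -> tuple[dict[str, Fraction], bool]:
    """Parse ``2 a_c + b_c <=> c_c`` into (stoichiometry, reversible).

    An empty side (``glc__D_e <=>``) denotes an exchange with the boundary.
    """
    if "<=>" in text:
        arrow, reversible = "<=>", True
    elif "=>" in text:
        arrow, reversible = "=>", False
    else:
        raise TemplateParseError(f"equation has no arrow: {text!r}")
    left, right = text.split(arrow)
    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                raise TemplateParseError(f"empty term in equation: {text!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, cid = Fraction(1), parts[0]
            elif len(parts) == 2:
                try:
                    coeff = Fraction(parts[0])
                except ValueError as exc:
                    raise TemplateParseError(f"bad coefficient {parts[0]!r} in {text!r}") from exc
                cid = parts[1]
            else:
                raise TemplateParseError(f"bad term {term!r} in equation {text!r}")
            stoich[cid] = stoich.get(cid, Fraction(0)) + sign * coeff
            if stoich[cid] == 0:
                del stoich[cid]

    add_side(left, -1)
    add_side(right, +1)
    if not stoich:
        raise TemplateParseError(f"equation has no species: {text!r}")
    return stoich, reversible


def unparse_equation(stoich: Mapping[str, Fraction], reversible: bool) -> str:
    def fmt(cid: str, coeff: Fraction) -> str:
        mag = abs(coeff)
        return cid if mag == 1 else f"{mag} {cid}"

    lhs = [fmt(c, k) for c, k in sorted(stoich.items()) if k < 0]
    rhs = [fmt(c, k) for c, k in sorted(stoich.items()) if k > 0]
    arrow = "<=>" if reversible else "=>"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


# --------------------------------------------------------------------------
# loading / writing


def _read_tsv(path: Path) -> list[dict[str, str]]:
    lines = path.read_text().splitlines()
    if not lines:
        raise TemplateParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise TemplateParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        records.append(dict(zip(header, fields)))
    return records


def load_template(path: str | Path) -> Template:
    """Load and cross-reference a template directory. Raises
    :class:`TemplateParseError` on malformed records and
    :class:`TemplateIntegrityError` on dangling references."""
    path = Path(path)
    compounds: dict[str, Compound] = {}
    for rec in _read_tsv(path / "compounds.tsv"):
        cid = rec["id"]
        if cid in compounds:
            raise TemplateIntegrityError(f"duplicate compound id {cid}")
        if rec["compartment"] not in COMPARTMENTS:
            raise TemplateParseError(f"compound {cid}: bad compartment {rec['compartment']!r}")
        if not cid.endswith(COMPARTMENTS[rec["compartment"]]):
            raise TemplateIntegrityError(
                f"compound {cid}: id suffix does not match compartment {rec['compartment']}"
            )
        try:
            parse_formula(rec["formula"])
        except FormulaError as exc:
            raise TemplateParseError(f"compound {cid}: {exc}") from exc
        compounds[cid] = Compound(
            id=cid,
            name=rec["name"],
            formula=rec["formula"],
            charge=int(rec["charge"]),
            compartment=rec["compartment"],
        )

    reactions: dict[str, Reaction] = {}
    for rec in _read_tsv(path / "reactions.tsv"):
        rid = rec["id"]
        if rid in reactions:
            raise TemplateIntegrityError(f"duplicate reaction id {rid}")
        stoich, reversible = parse_equation(rec["equation"])
        for cid in stoich:
            if cid not in compounds:
                raise TemplateIntegrityError(f"reaction {rid}: unknown compound {cid}")
        lower = float(rec["lower"]) if rec.get("lower") else (-DEFAULT_FLUX_BOUND if reversible else 0.0)
        upper = float(rec["upper"]) if rec.get("upper") else DEFAULT_FLUX_BOUND
        if lower > upper:
            raise TemplateIntegrityError(f"reaction {rid}: lower bound exceeds upper bound")
        kind = rec.get("kind", "gene") or "gene"
        if kind not in REACTION_KINDS:
            raise TemplateParseError(f"reaction {rid}: bad kind {kind!r}")
        gpr_text = rec.get("gpr", "").strip()
        if kind == "gene" and not gpr_text:
            raise TemplateParseError(f"reaction {rid}: gene reaction without GPR")
        gpr = parse_gpr(gpr_text) if gpr_text else None
        etc_tag = rec.get("etc_tag", "").strip() or None
        if etc_tag is not None and etc_tag not in ETC_TAGS:
            raise TemplateParseError(f"reaction {rid}: bad etc_tag {etc_tag!r}")
        tags = frozenset(t for t in rec.get("pathway_tags", "").split(";") if t)
        reactions[rid] = Reaction(
            id=rid,
            name=rec["name"],
            stoichiometry=stoich,
            lower=lower,
            upper=upper,
            kind=kind,
            gpr=gpr,
            pathway_tags=tags,
            etc_tag=etc_tag,
            proton_translocation=int(rec.get("proton_translocation", "0") or 0),
        )
    if not reactions:
        raise TemplateIntegrityError("empty reaction table: biomass precursors unresolvable")

    biomass_raw = json.loads((path / "biomass.json").read_text())
    precursors = tuple((p["compound"], float(p["coefficient"])) for p in biomass_raw["precursors"])
    for cid, _ in precursors:
        if cid not in compounds:
            raise TemplateIntegrityError(f"biomass precursor {cid} not in compound table")
    biomass = BiomassSpec(
        precursors=precursors,
        atp=float(biomass_raw["cofactors"]["atp"]),
        nadh=float(biomass_raw["cofactors"]["nadh"]),
        nadph=float(biomass_raw["cofactors"]["nadph"]),
    )

    rules = PathwayRuleSet.from_dict(json.loads((path / "pathway_rules.json").read_text()))
    for pathway, steps in rules.rules.items():
        for step in steps:
            for rid in step:
                if rid not in reactions:
                    raise TemplateIntegrityError(
                        f"pathway rule {pathway}: unknown reaction {rid}"
                    )

    media_library: dict[str, Media] = {}
    for media_path in sorted((path / "media").glob("*.json")):
        raw = json.loads(media_path.read_text())
        med = Media(
            name=raw["name"],
            exchange_bounds={k: tuple(v) for k, v in raw["exchange_bounds"].items()},
            carbon_source=raw["carbon_source"],
            electron_acceptor=raw.get("electron_acceptor"),
        )
        if med.bounds_for(med.carbon_source)[0] <= 0:
            raise TemplateIntegrityError(f"medium {med.name}: carbon source has no uptake")
        media_library[med.name] = med

    return Template(
        compounds=compounds,
        reactions=reactions,
        biomass=biomass,
        pathway_rules=rules,
        media_library=media_library,
    )


def write_template(template: Template, path: str | Path) -> None:
    """Write a template back to disk (loss-free round-trip with the loader)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "media").mkdir(exist_ok=True)

    rows = ["id\tname\tformula\tcharge\tcompartment"]
    for c in template.compounds.values():
        rows.append(f"{c.id}\t{c.name}\t{c.formula}\t{c.charge}\t{c.compartment}")
    (path / "compounds.tsv").write_text("\n".join(rows) + "\n")

    rows = ["id\tname\tequation\tlower\tupper\tkind\tgpr\tpathway_tags\tetc_tag\tproton_translocation"]
    for r in template.reactions.values():
        rows.append(
            "\t".join(
                [
                    r.id,
                    r.name,
                    unparse_equation(r.stoichiometry, r.reversible),
                    format(r.lower, "g"),
                    format(r.upper, "g"),
                    r.kind,
                    r.gpr.unparse() if r.gpr is not None else "",
                    ";".join(sorted(r.pathway_tags)),
                    r.etc_tag or "",
                    str(r.proton_translocation),
                ]
            )
        )
    (path / "reactions.tsv").write_text("\n".join(rows) + "\n")

    (path / "biomass.json").write_text(
        json.dumps(
            {
                "precursors": [
                    {"compound": cid, "coefficient": coeff}
                    for cid, coeff in template.biomass.precursors
                ],
                "cofactors": {
                    "atp": template.biomass.atp,
                    "nadh": template.biomass.nadh,
                    "nadph": template.biomass.nadph,
                },
            },
            indent=1,
        )
    )
    (path / "pathway_rules.json").write_text(json.dumps(template.pathway_rules.to_dict(), indent=1))
    for med in template.media_library.values():
        (path / "media" / f"{med.name}.json").write_text(
            json.dumps(
                {
                    "name": med.name,
                    "carbon_source": med.carbon_source,
                    "electron_acceptor": med.electron_acceptor,
                    "exchange_bounds": {k: list(v) for k, v in med.exchange_bounds.items()},
                },
                indent=1,
            )
        )


def load_packaged_template() -> Template:
    """Load the template packaged with coremetab."""
    return load_template(Path(__file__).parent / "data")


# --------------------------------------------------------------------------
# validation


def _balance(template: Template, rxn: Reaction) -> tuple[dict[str, Fraction], Fraction]:
    elements: dict[str, Fraction] = {}
    charge = Fraction(0)
    for cid, coeff in rxn.stoichiometry.items():
        compound = template.compounds[cid]
        for element, count in compound.elements.items():
            elements[element] = elements.get(element, Fraction(0)) + coeff * count
        charge += coeff * compound.charge
    return {e: v for e, v in elements.items() if v != 0}, charge


def validate_template(template: Template) -> ValidationReport:
    """Check element and charge conservation for every internal reaction.

    Exchange reactions, sinks and the biomass drain are exempt: they cross
    the system boundary by construction. Translocated protons are counted in
    their destination compartment, i.e. ``h_c`` and ``h_e`` both contribute
    H/+1, so a pumping reaction balances iff it conserves protons globally.
    """
    findings: list[ValidationFinding] = []
    for rxn in template.reactions.values():
        if rxn.is_exchange() or rxn.id == "BIOMASS":
            continue
        imbalance, charge = _balance(template, rxn)
        for element, value in sorted(imbalance.items()):
            findings.append(
                ValidationFinding(rxn.id, "element", f"element {element} off by {value}")
            )
        if charge != 0:
            findings.append(ValidationFinding(rxn.id, "charge", f"charge off by {charge}"))
    return ValidationReport(findings)
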