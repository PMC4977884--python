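"""Synthetic annotation sets and packaged organism-like fixtures.

The generator emulates RAST-style functional-role sets with known ground
truth: a :class:`GenomeSpec` names the energy pathways and ETC variants a
synthetic genome should carry; the emitted role set is the union of roles
satisfying the GPRs of those pathways' reactions, optionally thinned by
independent per-role dropout (annotation-noise model, default 0) and padded
with decoy roles that match no template GPR. The seed fully determines the
output.

Seven curated organism-like fixtures (E. coli-like, B. subtilis-like,
Clostridium-like, Pseudomonas-like, parasite-like, Acinetobacter-like,
Bacteroides-like) ship as role TSVs with manifests recording expected
reactions, pathway vector, respiration class and, where anchored, ATP
yields. Fixture files are package data regenerable from the in-code
definitions — no network fetch ever.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gpr import And, GprExpr, Or, Role
from .pathways import PATHWAY_NAMES
from .reconstruct import AnnotationSet
from .template import Template

__all__ = [
    "GenomeSpec",
    "TruthRecord",
    "ETC_PROFILE_REACTIONS",
    "generate_annotation_set",
    "random_genome_spec",
    "FIXTURE_NAMES",
    "load_fixture",
    "fixture_manifest",
    "write_fixture_files",
]

#: ETC variant -> reactions whose roles the variant contributes
ETC_PROFILE_REACTIONS: dict[str, tuple[str, ...]] = {
    "aerobic": ("NADH16", "CYTBO3", "ATPS4r"),
    "nitrate": ("NADH16", "NTRAR", "NARK", "ATPS4r"),
    "tmao": ("NADH16", "TMAOR", "ATPS4r"),
    "fumarate": ("NADH5", "FRD2", "ATPS4r"),
}

#: reactions every synthetic genome carries (substrate uptake)
_BASE_REACTIONS = ("GLCpts",)


@dataclass(frozen=True)
class GenomeSpec:
    genome_id: str
    pathways_present: frozenset[str]
    etc_profile: frozenset[str] = frozenset()
    role_dropout_prob: float = 0.0
    decoy_role_count: int = 0
    seed: int = 0

    def __post_init__(self):
        unknown = self.pathways_present - set(PATHWAY_NAMES)
        if unknown:
            raise ValueError(f"unknown pathways {sorted(unknown)}")
        unknown = self.etc_profile - set(ETC_PROFILE_REACTIONS)
        if unknown:
            raise ValueError(f"unknown ETC profiles {sorted(unknown)}")
        if not 0.0 <= self.role_dropout_prob <= 1.0:
            raise ValueError("role_dropout_prob must be in [0, 1]")


@dataclass
class TruthRecord:
    genome_id: str
    pathways_present: frozenset[str]
    etc_profile: frozenset[str]
    dropped_roles: frozenset[str]
    decoy_roles: frozenset[str]

    def presence_vector(self) -> dict[str, bool]:
        return {name: name in self.pathways_present for name in PATHWAY_NAMES}


def satisfying_roles(expr: GprExpr) -> set[str]:
    """A deterministic satisfying role set: all terms of an AND, the first
    alternative of an OR."""
    if isinstance(expr, Role):
        return {expr.name}
    if isinstance(expr, And):
        out: set[str] = set()
        for term in expr.terms:
            out |= satisfying_roles(term)
        return out
    if isinstance(expr, Or):
        return satisfying_roles(expr.terms[0])
    raise TypeError(type(expr))


def roles_for_reactions(template: Template, reaction_ids) -> set[str]:
    roles: set[str] = set()
    for rid in reaction_ids:
        rxn = template.reactions[rid]
        if rxn.gpr is not None:
            roles |= satisfying_roles(rxn.gpr)
    return roles


def generate_annotation_set(
    spec: GenomeSpec, template: Template
) -> tuple[AnnotationSet, TruthRecord]:
    """Emit the role set implied by the spec, with dropout noise and decoys.

    Same seed, same spec -> identical output.
    """
    rng = np.random.default_rng(spec.seed)
    reaction_ids: set[str] = set(_BASE_REACTIONS)
    for pathway in spec.pathways_present:
        for step in template.pathway_rules.rules[pathway]:
            reaction_ids |= step
    for variant in spec.etc_profile:
        reaction_ids |= set(ETC_PROFILE_REACTIONS[variant])
    roles = roles_for_reactions(template, reaction_ids)

    dropped = frozenset(
        role for role in sorted(roles) if rng.random() < spec.role_dropout_prob
    )
    decoys = frozenset(
        f"hypothetical protein decoy{rng.integers(0, 10**8):08d}"
        for _ in range(spec.decoy_role_count)
    )
    annotation = AnnotationSet(
        genome_id=spec.genome_id,
        roles=frozenset(roles - dropped) | decoys,
        seq_key=None,
        quality=None,
    )
    truth = TruthRecord(
        genome_id=spec.genome_id,
        pathways_present=spec.pathways_present,
        etc_profile=spec.etc_profile,
        dropped_roles=dropped,
        decoy_roles=decoys,
    )
    return annotation, truth


def random_genome_spec(
    genome_id: str,
    rng: np.random.Generator,
    role_dropout_prob: float = 0.0,
    decoy_role_count: int = 0,
) -> GenomeSpec:
    """A random pathway/ETC combination (for property tests and corpora)."""
    pathways = frozenset(
        name for name in PATHWAY_NAMES if rng.random() < 0.5
    )
    etc = frozenset(
        name for name in ETC_PROFILE_REACTIONS if rng.random() < 0.3
    )
    return GenomeSpec(
        genome_id=genome_id,
        pathways_present=pathways,
        etc_profile=etc,
        role_dropout_prob=role_dropout_prob,
        decoy_role_count=decoy_role_count,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# --------------------------------------------------------------------------
# packaged organism-like fixtures


@dataclass(frozen=True)
class _FixtureDef:
    taxon_label: str
    seq_key: str
    quality: float
    reactions: tuple[str, ...]  # expected gene_associated reactions
    pathways: dict[str, bool] = field(default_factory=dict)
    respiration: str = "none"
    atp_yields: dict[str, float] = field(default_factory=dict)
    extra_roles: tuple[str, ...] = ()
    skip_default_roles_for: tuple[str, ...] = ()
    notes: str = ""


def _pathway_flags(present: set[str]) -> dict[str, bool]:
    return {name: name in present for name in PATHWAY_NAMES}


_GLYCOLYSIS = ("PGI", "PFK", "FBA", "TPI", "GAPD", "PGK", "PGM", "ENO", "PYK")
_PPP = ("G6PDH2r", "PGL", "GND", "RPI", "RPE", "TKT1", "TALA", "TKT2")
_TCA = ("CS", "ACONT", "ICDHyr", "AKGDH", "SUCOAS", "SUCDi", "FUM", "MDH")
_BUT_COMMON = ("ACACT1r", "HACD1", "ECOAH1", "BCD")

FIXTURES: dict[str, _FixtureDef] = {
    "ecoli_like": _FixtureDef(
        taxon_label="Escherichia coli K-12-like",
        seq_key="16S:0001",
        quality=0.99,
        reactions=(
            ("GLCpts", "GLCt2", "GLK") + _GLYCOLYSIS + ("FBP", "PPCK")
            + _PPP + ("EDD", "EDA")
            + ("PDH", "PFL") + _TCA + ("PPC",)
            + ("NADH16", "NADH5", "CYTBO3", "CYTBD", "NTRAR", "TMAOR", "FRD2",
               "ATPS4r", "THD2", "UDHA", "NARK")
            + ("LDH_D", "LACD2", "PTA", "ACKr", "ACALD", "ALCD2x")
            + ("GLYK", "G3PD7", "RIBt2", "RBK", "SUCCt2", "SUCCt_out", "LACt2r",
               "ACt_out", "FORt_out")
        ),
        pathways=_pathway_flags(
            {"glycolysis", "entner_doudoroff", "tca", "pentose_phosphate",
             "lactate", "acetate", "formate", "ethanol"}
        ),
        respiration="facultative",
        atp_yields={"glucose_o2": 26.5, "glucose_none": 2.75},
        notes="Facultative anaerobe; mixed-acid fermenter; full glucose-oxidation repertoire.",
    ),
    "bsubtilis_like": _FixtureDef(
        taxon_label="Bacillus subtilis-like",
        seq_key="16S:0002",
        quality=0.95,
        reactions=(
            ("GLCpts",) + _GLYCOLYSIS + ("FBP", "PPCK") + _PPP
            + ("PDH",) + _TCA + ("PC",)
            + ("NADH5", "CYTBD", "NTRAR", "NARK", "ATPS4r", "UDHA")
            + ("LDH_D", "LACt2r", "PTA", "ACKr", "ACt_out",
               "ALS", "ALDC", "BTDD", "ACALD", "ALCD2x")
            + ("GLYK", "G3PD7", "RIBt2", "RBK")
        ),
        pathways=_pathway_flags(
            {"glycolysis", "tca", "pentose_phosphate",
             "lactate", "acetate", "ethanol", "butanediol"}
        ),
        respiration="facultative",
        notes=(
            "Labelled an obligate aerobe in the public domain, yet carries a "
            "nitrate respiratory chain; Gram-positive anaplerosis via pyruvate carboxylase."
        ),
    ),
    "clostridium_like": _FixtureDef(
        taxon_label="Clostridium acetobutylicum-like",
        seq_key="16S:0003",
        quality=0.90,
        reactions=(
            ("GLCpts",) + _GLYCOLYSIS + _PPP
            + ("PFOR", "HYDA", "PC")
            + ("LDH_D", "LACt2r", "PTA", "ACKr", "ACt_out", "ACALD", "ALCD2x")
            + _BUT_COMMON + ("PTB", "BUK", "BUTt_out", "BTALDH", "BTOLDH",
                             "CTFAB", "ADC", "ATPS4r")
        ),
        pathways=_pathway_flags(
            {"glycolysis", "pentose_phosphate", "lactate", "acetate",
             "ethanol", "butyrate", "butanol", "acetone"}
        ),
        respiration="none",
        notes="Obligate fermenter: no respiratory chain; solventogenic ABE pathways.",
    ),
    "pseudomonas_like": _FixtureDef(
        taxon_label="Pseudomonas-like",
        seq_key="16S:0004",
        quality=0.92,
        reactions=(
            ("GLCt2", "GLK", "PGI", "FBA", "TPI", "GAPD", "PGK", "PGM", "ENO",
             "PYK", "FBP", "PPCK")
            + ("G6PDH2r", "PGL", "EDD", "EDA", "RPI", "RPE", "TKT1", "TALA", "TKT2")
            + ("PDH",) + _TCA + ("PPC",)
            + ("NADH16", "CYTBO3", "CYTBD", "NTRAR", "NARK", "ATPS4r", "THD2", "UDHA")
            + ("LDH_D", "LACt2r", "LACD2", "PTA", "ACKr", "ACt_out")
            + ("GLYK", "G3PD7", "SUCCt2", "SUCCt_out")
        ),
        pathways=_pathway_flags({"entner_doudoroff", "tca", "lactate", "acetate"}),
        respiration="facultative",
        notes="Entner-Doudoroff glucose oxidation (no phosphofructokinase); denitrifier-style nitrate chain.",
    ),
    "parasite_like": _FixtureDef(
        taxon_label="Mycoplasma-like reduced genome",
        seq_key="16S:0005",
        quality=0.60,
        reactions=(
            ("GLCpts",) + _GLYCOLYSIS
            + ("PDH", "LDH_D", "LACt2r", "PTA", "ACKr", "ACt_out", "ACALD", "ALCD2x")
        ),
        pathways=_pathway_flags({"glycolysis", "lactate", "acetate", "ethanol"}),
        respiration="none",
        notes=(
            "Parasite-style gene loss: no TCA cycle or pentose phosphate pathway, so "
            "several biomass precursors are unproducible and gapfilling is required."
        ),
    ),
    "acinetobacter_like": _FixtureDef(
        taxon_label="Acinetobacter-like",
        seq_key="16S:0006",
        quality=0.88,
        reactions=(
            ("GLCt2", "GLK", "PGI", "FBA", "TPI", "GAPD", "PGK", "PGM", "ENO",
             "PYK", "FBP", "PPCK")
            + ("G6PDH2r", "GND", "EDD", "EDA", "RPI", "RPE", "TKT1", "TALA", "TKT2")
            + ("PDH",) + _TCA + ("PPC",)
            + ("NADH16", "CYTBD", "ATPS4r", "UDHA")
            + ("PTA", "ACKr", "ACt_out")
        ),
        pathways=_pathway_flags({"tca", "acetate"}),
        respiration="aerobic",
        notes=(
            "All Entner-Doudoroff enzymes annotated except the gluconolactonase "
            "step, so the ED pathway is called absent (the lactone hydrolysis may "
            "in fact proceed spontaneously in vivo)."
        ),
    ),
    "bacteroides_like": _FixtureDef(
        taxon_label="Bacteroides-like obligate anaerobe",
        seq_key="16S:0007",
        quality=0.85,
        reactions=(
            ("GLCpts",) + _GLYCOLYSIS + _PPP
            + ("PDH", "PFL")
            + ("LDH_D", "LACt2r", "PTA", "ACKr", "ACt_out", "FORt_out",
               "ACALD", "ALCD2x")
            + ("NADH5", "CYTBO3", "ATPS4r")
        ),
        pathways=_pathway_flags(
            {"glycolysis", "pentose_phosphate", "lactate", "acetate",
             "formate", "ethanol"}
        ),
        respiration="aerobic",
        extra_roles=("Ubiquinol cytochrome oxidase",),
        skip_default_roles_for=("CYTBO3",),
        notes=(
            "Obligate anaerobe carrying a spurious generic ubiquinol-oxidase "
            "annotation, so it is classified aerobic; the phylogenetic outlier "
            "report is the intended catch for this error."
        ),
    ),
}

FIXTURE_NAMES = tuple(FIXTURES)

_FIXTURE_DIR = Path(__file__).parent / "data" / "fixtures"


def fixture_roles(name: str, template: Template) -> set[str]:
    """Derive a fixture's role set from its reaction list and overrides."""
    fx = FIXTURES[name]
    rids = [r for r in fx.reactions if r not in fx.skip_default_roles_for]
    roles = roles_for_reactions(template, rids)
    roles |= {r.lower() for r in fx.extra_roles}
    return roles


def load_fixture(name: str, directory: Path | None = None) -> AnnotationSet:
    """Load a packaged fixture's annotation set."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    fx = FIXTURES[name]
    directory = directory or _FIXTURE_DIR
    annotation = AnnotationSet.from_tsv(directory / f"{name}.tsv")
    return AnnotationSet(
        genome_id=annotation.genome_id,
        roles=annotation.roles,
        taxon_label=fx.taxon_label,
        seq_key=fx.seq_key,
        quality=fx.quality,
    )


def fixture_manifest(name: str, directory: Path | None = None) -> dict:
    """The fixture's expectations: reactions, pathway vector, respiration,
    anchored ATP yields."""
    directory = directory or _FIXTURE_DIR
    return json.loads((directory / f"{name}.manifest.json").read_text())


def write_fixture_files(template: Template, directory: Path | None = None) -> None:
    """(Re)generate the packaged fixture TSVs and manifests from the in-code
    definitions."""
    directory = directory or _FIXTURE_DIR
    directory.mkdir(parents=True, exist_ok=True)
    for name, fx in FIXTURES.items():
        roles = sorted(fixture_roles(name, template))
        lines = [f"{name}\t{role}" for role in roles]
        (directory / f"{name}.tsv").write_text("\n".join(lines) + "\n")
        manifest = {
            "genome_id": name,
            "taxon_label": fx.taxon_label,
            "seq_key": fx.seq_key,
            "quality": fx.quality,
            "reactions": sorted(fx.reactions),
            "pathways": fx.pathways,
            "respiration": fx.respiration,
            "atp_yields": fx.atp_yields,
            "notes": fx.notes,
        }
        (directory / f"{name}.manifest.json").write_text(json.dumps(manifest, indent=1))
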