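"""Per-genome core model reconstruction: evaluate the template's GPR rules
against a genome's functional-role annotation set.

A reaction enters the model iff its GPR Boolean evaluates true over the
genome's roles, or it is spontaneous/universal. Role strings that match no
GPR leaf are ignored (and reported), never fatal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .gpr import normalize_role
from .template import Template

__all__ = ["AnnotationSet", "CoreModel", "ModelStats", "build_core_model", "model_stats"]

logger = logging.getLogger(__name__)

EVIDENCE_TAGS = ("gene_associated", "spontaneous", "universal", "gapfilled")


@dataclass
class AnnotationSet:
    """A genome's RAST-style annotation: a set of functional-role strings."""

    genome_id: str
    roles: frozenset[str]
    taxon_label: str | None = None
    seq_key: str | None = None  # 16S-identity key for deduplication
    quality: float | None = None

    @classmethod
    def from_tsv(cls, path: str | Path, genome_id: str | None = None) -> "AnnotationSet":
        """Two-column TSV (genome_id, role); single-genome files may omit the
        first column's repetition by passing ``genome_id`` explicitly."""
        path = Path(path)
        roles: set[str] = set()
        gid = genome_id
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            if gid is None:
                gid = fields[0]
            roles.add(fields[1])
        if gid is None:
            raise ValueError(f"{path}: no records and no genome_id given")
        return cls(genome_id=gid, roles=frozenset(roles))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnotationSet":
        raw = json.loads(Path(path).read_text())
        return cls(
            genome_id=raw["genome_id"],
            roles=frozenset(raw["roles"]),
            taxon_label=raw.get("taxon_label"),
            seq_key=raw.get("seq_key"),
            quality=raw.get("quality"),
        )

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{self.genome_id}\t{role}" for role in sorted(self.roles)]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class CoreModel:
    """One genome's reaction subset of the template, with per-reaction
    evidence tags."""

    genome_id: str
    template: Template
    reactions: dict[str, str] = field(default_factory=dict)  # reaction id -> evidence tag
    unmatched_roles: frozenset[str] = frozenset()
    seq_key: str | None = None
    quality: float | None = None

    def with_added(self, reaction_ids: set[str], tag: str = "gapfilled") -> "CoreModel":
        new = dict(self.reactions)
        for rid in reaction_ids:
            if rid not in new:
                new[rid] = tag
        return CoreModel(
            genome_id=self.genome_id,
            template=self.template,
            reactions=new,
            unmatched_roles=self.unmatched_roles,
            seq_key=self.seq_key,
            quality=self.quality,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"genome_id": self.genome_id, "reactions": dict(sorted(self.reactions.items()))},
                indent=1,
            )
        )


@dataclass(frozen=True)
class ModelStats:
    total: int
    gene_associated: int
    spontaneous: int
    universal: int
    gapfilled: int


def build_core_model(template: Template, annotation: AnnotationSet) -> CoreModel:
    """Deterministically instantiate a core model from an annotation set.

    Evidence tags record why each reaction is present. Unknown roles (no GPR
    leaf matches) are collected on the model and logged.
    """
    roles = frozenset(normalize_role(r) for r in annotation.roles)
    reactions: dict[str, str] = {}
    for rxn in template.reactions.values():
        if rxn.kind == "universal":
            reactions[rxn.id] = "universal"
        elif rxn.kind == "spontaneous":
            reactions[rxn.id] = "spontaneous"
        elif rxn.gpr is not None and rxn.gpr.evaluate(roles):
            reactions[rxn.id] = "gene_associated"
    known_roles = set(template.role_index)
    unmatched = roles - known_roles
    if unmatched:
        logger.info(
            "genome %s: %d role(s) match no template GPR", annotation.genome_id, len(unmatched)
        )
    return CoreModel(
        genome_id=annotation.genome_id,
        template=template,
        reactions=reactions,
        unmatched_roles=frozenset(unmatched),
        seq_key=annotation.seq_key,
        quality=annotation.quality,
    )


def model_stats(model: CoreModel) -> ModelStats:
    """Reaction counts by evidence tag; counts sum to total."""
    counts = {tag: 0 for tag in EVIDENCE_TAGS}
    for tag in model.reactions.values():
        counts[tag] += 1
    return ModelStats(
        total=len(model.reactions),
        gene_associated=counts["gene_associated"],
        spontaneous=counts["spontaneous"],
        universal=counts["universal"],
        gapfilled=counts["gapfilled"],
    )
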