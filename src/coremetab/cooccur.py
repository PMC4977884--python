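"""Pairwise co-occurrence of pathway presence/absence across many profiles.

The correlation of two 0/1 pathway vectors is the Pearson coefficient, which
on binary data equals the phi coefficient of the 2x2 contingency table,
r = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)). Significance comes from the
t statistic t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom. Analyses
can be stratified by model size class (small < 93 reactions, medium 93-133,
large > 133) to control for the higher chance of co-occurrence in larger
models, after deduplicating profiles that share a 16S sequence key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pathways import PATHWAY_NAMES, PathwayProfile

__all__ = [
    "SIZE_CLASSES",
    "CooccurrenceResult",
    "deduplicate",
    "assign_size_classes",
    "pairwise_cooccurrence",
    "summarize",
    "holm_adjust",
]

logger = logging.getLogger(__name__)

SIZE_CLASSES = ("small", "medium", "large")
ALPHA = 0.05


def deduplicate(profiles: Sequence[PathwayProfile]) -> list[PathwayProfile]:
    """One representative per distinct 16S sequence key: highest quality,
    ties broken by genome_id order. Profiles without a key are retained."""
    by_key: dict[str, PathwayProfile] = {}
    keyless: list[PathwayProfile] = []
    for profile in profiles:
        if profile.seq_key is None:
            keyless.append(profile)
            continue
        incumbent = by_key.get(profile.seq_key)
        if incumbent is None:
            by_key[profile.seq_key] = profile
        else:
            q_new = profile.quality if profile.quality is not None else float("-inf")
            q_old = incumbent.quality if incumbent.quality is not None else float("-inf")
            if q_new > q_old or (q_new == q_old and profile.genome_id < incumbent.genome_id):
                by_key[profile.seq_key] = profile
    if keyless:
        logger.info("%d profile(s) lack a sequence key; retained as-is", len(keyless))
    # preserve input order among the retained
    retained = {id(p) for p in by_key.values()} | {id(p) for p in keyless}
    return [p for p in profiles if id(p) in retained]


def assign_size_classes(profiles: Sequence[PathwayProfile]) -> list[str]:
    """small: <93 reactions; medium: 93-133 inclusive; large: >133."""
    out = []
    for profile in profiles:
        if profile.model_size < 93:
            out.append("small")
        elif profile.model_size <= 133:
            out.append("medium")
        else:
            out.append("large")
    return out


@dataclass
class CooccurrenceResult:
    size_class: str  # small | medium | large | all
    n: int
    table: pd.DataFrame  # long format: pathway_a, pathway_b, r, p, defined, significant
    r_matrix: pd.DataFrame  # 12x12 symmetric, unit diagonal

    def pair(self, a: str, b: str) -> pd.Series:
        mask = (
            (self.table.pathway_a == min(a, b)) & (self.table.pathway_b == max(a, b))
        )
        return self.table[mask].iloc[0]


def pairwise_cooccurrence(
    profiles: Sequence[PathwayProfile],
    size_class: str = "all",
    alpha: float = ALPHA,
) -> CooccurrenceResult:
    """Phi/Pearson correlation and p-value for every unordered pathway pair.

    Pairs where either pathway has zero variance are flagged undefined
    (``defined=False``, r and p NaN) instead of propagating NaN silently.
    """
    if size_class != "all":
        classes = assign_size_classes(profiles)
        profiles = [p for p, c in zip(profiles, classes) if c == size_class]
    n = len(profiles)
    if n < 3:
        raise ValueError(f"need at least 3 profiles, got {n}")
    X = np.array([[p.presence[name] for name in PATHWAY_NAMES] for p in profiles], dtype=float)
    records = []
    r_matrix = np.eye(len(PATHWAY_NAMES))
    for (i, a), (j, b) in combinations(enumerate(PATHWAY_NAMES), 2):
        x, y = X[:, i], X[:, j]
        if x.std() == 0 or y.std() == 0:
            records.append(
                {"pathway_a": min(a, b), "pathway_b": max(a, b), "r": np.nan, "p": np.nan,
                 "defined": False, "significant": False}
            )
            r_matrix[i, j] = r_matrix[j, i] = np.nan
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        r = max(-1.0, min(1.0, r))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        records.append(
            {"pathway_a": min(a, b), "pathway_b": max(a, b), "r": r, "p": p,
             "defined": True, "significant": p < alpha}
        )
        r_matrix[i, j] = r_matrix[j, i] = r
    table = pd.DataFrame.from_records(records)
    return CooccurrenceResult(
        size_class=size_class,
        n=n,
        table=table,
        r_matrix=pd.DataFrame(r_matrix, index=PATHWAY_NAMES, columns=PATHWAY_NAMES),
    )


def holm_adjust(result: CooccurrenceResult, alpha: float = ALPHA) -> CooccurrenceResult:
    """Optional Holm step-down correction of the per-pair p-values (the
    default analysis reports raw p < alpha)."""
    table = result.table.copy()
    defined = table[table.defined].sort_values("p")
    m = len(defined)
    significant = pd.Series(False, index=table.index)
    for rank, (idx, row) in enumerate(defined.iterrows()):
        if row.p <= alpha / (m - rank):
            significant[idx] = True
        else:
            break
    table["significant"] = significant
    return CooccurrenceResult(result.size_class, result.n, table, result.r_matrix)


def summarize(results: Iterable[CooccurrenceResult]) -> pd.DataFrame:
    """Per class: the fraction of significant pairs whose correlation is
    positive (the headline co-occurrence statistic), plus counts."""
    rows = []
    for res in results:
        sig = res.table[res.table.defined & res.table.significant]
        positive = (sig.r > 0).sum()
        rows.append(
            {
                "size_class": res.size_class,
                "n_profiles": res.n,
                "n_significant": len(sig),
                "n_positive": int(positive),
                "fraction_positive": float(positive / len(sig)) if len(sig) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def consistent_across_classes(results_by_class: dict[str, CooccurrenceResult]) -> pd.DataFrame:
    """A pair is 'consistent' when its sign and significance agree across
    the small/medium/large classes (bold-outline criterion)."""
    base = None
    frames = []
    for cls in SIZE_CLASSES:
        t = results_by_class[cls].table[["pathway_a", "pathway_b", "r", "significant"]].copy()
        t[f"sign_{cls}"] = np.sign(t.pop("r"))
        t = t.rename(columns={"significant": f"sig_{cls}"})
        frames.append(t)
        base = t[["pathway_a", "pathway_b"]] if base is None else base
    merged = frames[0]
    for f in frames[1:]:
        merged = merged.merge(f, on=["pathway_a", "pathway_b"])
    merged["consistent"] = (
        (merged.sign_small == merged.sign_medium)
        & (merged.sign_medium == merged.sign_large)
        & (merged.sig_small == merged.sig_medium)
        & (merged.sig_medium == merged.sig_large)
    )
    return merged
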