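"""Transcription-factor family assignment from DNA-binding-domain hits.

Genes are assigned to TF families from a precomputed domain-hit table
(hmmscan/BLAST-style: gene, model, e-value, score).  A family is defined by
a rule — a set of required DBD models plus an optional set of forbidden
models, in the style of plant TF databases — and a gene qualifies for a
family when, among its hits passing the e-value cutoff (default 1e-10), all
required models are present and no forbidden model is.  Among qualifying
families the one supported by the best (smallest) e-value wins; ties break
by larger score, then lexicographic family name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DomainHit",
    "FamilyRule",
    "TFAssignment",
    "assign_tf_families",
    "family_distribution",
    "DEFAULT_EVALUE_CUTOFF",
    "default_family_rules",
]

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_CUTOFF = 1e-10


class RuleTableError(ValueError):
    """Raised on an empty or inconsistent family rule table."""


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    model_id: str
    e_value: float
    score: float

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError(f"e-value must be positive, got {self.e_value}")


@dataclass(frozen=True)
class FamilyRule:
    family_name: str
    required_models: frozenset[str]
    forbidden_models: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.required_models:
            raise RuleTableError(f"family {self.family_name}: no required models")
        if self.required_models & self.forbidden_models:
            raise RuleTableError(
                f"family {self.family_name}: required and forbidden models overlap"
            )


@dataclass
class TFAssignment:
    gene_id: str
    family: str | None
    best_hit: DomainHit | None = None
    evidence: list[DomainHit] = field(default_factory=list)

    @property
    def assigned(self) -> bool:
        return self.family is not None


def default_family_rules() -> list[FamilyRule]:
    """Small illustrative rule set over common plant DBD models.

    A deliberately compact, user-replaceable subset of a required+forbidden
    family scheme; real analyses should load the full rule table of their
    reference TF database.
    """
    req = {
        "bHLH": ["HLH"],
        "NAC": ["NAM"],
        "ERF": ["AP2"],
        "C2H2": ["zf-C2H2"],
        "Dof": ["Zf-Dof"],
        "MYB": ["Myb_DNA-binding"],
        "LBD": ["DUF260"],
        "WRKY": ["WRKY"],
        "bZIP": ["bZIP_1"],
        "GATA": ["GATA"],
        "GRAS": ["GRAS"],
        "HSF": ["HSF_DNA-bind"],
        "SBP": ["SBP"],
        "ARF": ["Auxin_resp"],
    }
    forb = {"ERF": ["B3"], "MYB": ["SWIRM"]}
    return [
        FamilyRule(name, frozenset(models), frozenset(forb.get(name, ())))
        for name, models in req.items()
    ]


def _qualifying_family(
    hits: list[DomainHit], rules: list[FamilyRule]
) -> tuple[str, DomainHit] | None:
    models = {h.model_id for h in hits}
    best: tuple[float, float, str, DomainHit] | None = None
    for rule in rules:
        if not rule.required_models <= models:
            continue
        if rule.forbidden_models & models:
            continue
        support = min(
            (h for h in hits if h.model_id in rule.required_models),
            key=lambda h: (h.e_value, -h.score),
        )
        key = (support.e_value, -support.score, rule.family_name)
        if best is None or key < (best[0], best[1], best[2]):
            best = (*key, support)
    if best is None:
        return None
    return best[2], best[3]


def assign_tf_families(
    hits: list[DomainHit],
    rules: list[FamilyRule],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[TFAssignment]:
    """Assign each gene appearing in `hits` to at most one TF family.

    Hits with e-value above the cutoff are discarded first; hits to models
    no rule references are logged and ignored.  Output order follows first
    appearance of each gene in the hit list; the assignment itself is
    invariant to hit order.
    """
    if not rules:
        raise RuleTableError("family rule table is empty")
    known = set().union(*(r.required_models | r.forbidden_models for r in rules))
    unknown = {h.model_id for h in hits} - known
    if unknown:
        logger.info("ignoring %d hits to models without rules: %s",
                    sum(h.model_id in unknown for h in hits), sorted(unknown))
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    out = []
    for gene, gene_hits in by_gene.items():
        kept = sorted(
            (h for h in gene_hits
             if h.e_value <= evalue_cutoff and h.model_id in known),
            key=lambda h: (h.e_value, -h.score, h.model_id),
        )
        call = _qualifying_family(kept, rules)
        if call is None:
            out.append(TFAssignment(gene, None, None, kept))
        else:
            out.append(TFAssignment(gene, call[0], call[1], kept))
    return out


def family_distribution(assignments: list[TFAssignment]) -> pd.Series:
    """Counts per family over assigned genes, sorted by descending count."""
    counts: dict[str, int] = {}
    for a in assignments:
        if a.assigned:
            counts[a.family] = counts.get(a.family, 0) + 1
    s = pd.Series(counts, dtype=int, name="n_genes")
    s.index.name = "family"
    return s.sort_values(ascending=False, kind="stable")


def assignments_to_frame(assignments: list[TFAssignment]) -> pd.DataFrame:
    """Tabular gene→family view with best-hit evidence columns."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "gene_id": a.gene_id,
                "family": a.family if a.assigned else "unassigned",
                "best_model": a.best_hit.model_id if a.best_hit else "",
                "best_evalue": a.best_hit.e_value if a.best_hit else float("nan"),
                "best_score": a.best_hit.score if a.best_hit else float("nan"),
                "n_hits": len(a.evidence),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
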