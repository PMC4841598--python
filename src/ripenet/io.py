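"""Readers and writers for the pipeline's on-disk formats.

Everything on disk is plain text: TSV for matrices and tables, a
whitespace-delimited hmmscan-style table for domain hits, GMT or
two-column TSV for term sets, YAML for run configuration and JSON for the
run manifest and synthetic truth.  Loaders enforce type invariants at the
boundary (unique gene ids, non-negative integer counts, positive lengths
and library sizes, aligned sample axes) and name the offending row in
errors.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .de import CountMatrix
from .tf import DomainHit, FamilyRule

__all__ = [
    "RunConfig",
    "read_count_matrix",
    "write_count_matrix",
    "read_expression",
    "write_table",
    "read_traits",
    "read_domain_hits",
    "read_family_rules",
    "write_family_rules",
    "read_gene_list",
    "read_term_table",
]

logger = logging.getLogger(__name__)


class LoadError(ValueError):
    """Raised when an input file violates a format or type invariant."""


def _read_tsv_matrix(path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        row = int(np.nonzero(df.index.duplicated())[0][0]) + 2
        raise LoadError(f"{what} {path}: duplicate gene id {dup!r} at line {row}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise LoadError(
                f"{what} {path}: non-numeric cell in column {col!r} at line {row}"
            )
        df[col] = coerced
    return df


def read_count_matrix(
    counts_path,
    lengths_path,
    libsizes_path=None,
) -> CountMatrix:
    """Load counts (TSV, gene id column first), lengths and library sizes.

    Without a library-size table, sizes are derived from column sums (and
    logged, since derived totals ignore reads on filtered genes).
    """
    counts = _read_tsv_matrix(counts_path, "count table")
    if (counts.to_numpy() < 0).any():
        bad = counts.index[(counts < 0).any(axis=1)][0]
        row = int(counts.index.get_loc(bad)) + 2
        raise LoadError(f"count table {counts_path}: negative count for gene "
                        f"{bad!r} at line {row}")
    if not np.allclose(counts.to_numpy() % 1, 0):
        raise LoadError(f"count table {counts_path}: non-integer counts")
    lengths = _read_tsv_matrix(lengths_path, "gene length table").iloc[:, 0]
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise LoadError(
            f"gene length table {lengths_path}: no length for gene {missing[0]!r}"
        )
    if libsizes_path is not None:
        libs = _read_tsv_matrix(libsizes_path, "library size table").iloc[:, 0]
        missing = counts.columns.difference(libs.index)
        if len(missing):
            raise LoadError(
                f"library size table {libsizes_path}: no size for sample "
                f"{missing[0]!r}"
            )
    else:
        libs = counts.sum(axis=0)
        logger.info("library sizes derived from count column sums: %s",
                    libs.to_dict())
    return CountMatrix(
        counts=counts.astype(np.int64),
        library_sizes=libs.loc[counts.columns],
        gene_lengths=lengths.loc[counts.index],
    )


def write_count_matrix(cm: CountMatrix, counts_path, lengths_path, libsizes_path):
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.gene_lengths.rename("length_bp").rename_axis("gene_id").to_csv(
        lengths_path, sep="\t"
    )
    cm.library_sizes.rename("library_size").rename_axis("sample").to_csv(
        libsizes_path, sep="\t"
    )


def read_expression(path) -> pd.DataFrame:
    """Genes x samples expression (RPKM) TSV."""
    df = _read_tsv_matrix(path, "expression table")
    if (df.to_numpy() < 0).any():
        bad = df.index[(df < 0).any(axis=1)][0]
        raise LoadError(f"expression table {path}: negative value for gene {bad!r}")
    return df


def read_traits(path) -> pd.DataFrame:
    """Samples x traits TSV (rows = samples)."""
    return _read_tsv_matrix(path, "trait table")


def write_table(df: pd.DataFrame, path, index_label: str | None = "gene_id"):
    df.to_csv(path, sep="\t", index_label=index_label)


def read_domain_hits(path) -> list[DomainHit]:
    """Whitespace/tab-delimited hits: gene, model, e-value, score.

    Lines starting with ``#`` are comments (hmmscan --tblout style).
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise LoadError(f"domain hits {path}: line {lineno}: expected "
                                f"4 fields, got {len(parts)}")
            gene, model, ev, score = parts[:4]
            try:
                hits.append(DomainHit(gene, model, float(ev), float(score)))
            except ValueError as exc:
                raise LoadError(f"domain hits {path}: line {lineno}: {exc}") from exc
    return hits


def write_domain_hits(hits: list[DomainHit], path):
    with open(path, "w") as fh:
        fh.write("# gene_id model_id e_value score\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.model_id}\t{h.e_value:.3e}\t{h.score:.1f}\n")


def read_family_rules(path) -> list[FamilyRule]:
    """TSV rule table: family, required models (comma), forbidden (comma)."""
    df = pd.read_csv(path, sep="\t")
    rules = []
    for _, row in df.iterrows():
        forb = row.get("forbidden_models", "")
        forb = "" if pd.isna(forb) else str(forb)
        rules.append(
            FamilyRule(
                family_name=str(row["family"]),
                required_models=frozenset(
                    m for m in str(row["required_models"]).split(",") if m
                ),
                forbidden_models=frozenset(m for m in forb.split(",") if m),
            )
        )
    return rules


def write_family_rules(rules: list[FamilyRule], path):
    pd.DataFrame(
        {
            "family": [r.family_name for r in rules],
            "required_models": [",".join(sorted(r.required_models)) for r in rules],
            "forbidden_models": [",".join(sorted(r.forbidden_models)) for r in rules],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_term_table(path) -> dict[str, set]:
    """GMT (term, description, genes...) or two-column gene→term TSV."""
    path = Path(path)
    terms: dict[str, set] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise LoadError(f"GMT {path}: line {lineno}: expected "
                                    "term, description and at least one gene")
                terms[parts[0]] = set(g for g in parts[2:] if g)
        return terms
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise LoadError(f"term table {path}: need gene and term columns")
    gcol, tcol = df.columns[:2]
    for _, row in df.iterrows():
        terms.setdefault(str(row[tcol]), set()).add(str(row[gcol]))
    return terms


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    # inputs (None = simulate with the default preset)
    counts: str | None = None
    lengths: str | None = None
    libsizes: str | None = None
    traits: str | None = None
    hits: str | None = None
    rules: str | None = None
    terms: str | None = None
    out_dir: str = "ripenet_out"
    # DE thresholds
    fdr_cut: float = 0.001
    lfc_cut: float = 1.0
    rpkm_log_floor: float = 0.001
    # network
    soft_power: int = 6
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    max_block_size: int = 19000
    rpkm_floor: float = 0.3
    # validation / downstream
    permutations: int = 999
    cluster_k: int = 6
    enrich_cut: float = 0.01
    evalue_cutoff: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fdr_cut <= 1 or not 0 <= self.enrich_cut <= 1:
            raise LoadError("fdr_cut and enrich_cut must lie in [0, 1]")
        if self.permutations < 1 or self.cluster_k < 1:
            raise LoadError("permutations and cluster_k must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))
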