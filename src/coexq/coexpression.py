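"""Mean-normalized expression profiles and the Δsum co-expression ranking.

A gene's profile is its TPM vector rescaled relative to its own mean:

    z(g, s) = (x(g, s) - m(g)) / m(g)

with ``m(g)`` the gene's arithmetic mean over the samples in the matrix.
The transform is dimensionless and scale-free — multiplying a gene's TPM
row by any positive constant leaves z unchanged — so highly and weakly
expressed genes become directly comparable.  Each z-row sums to zero by
construction and is bounded below by −1.

The Δsum between two genes is the L1 distance between their z-rows,

    Δsum(a, b) = Σ_s |z_a(s) − z_b(s)|,

a metric on profiles.  Ranking all genes by Δsum against a query gene
yields its co-expression list; the query itself always heads the list
with Δsum exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import (
    ExpressionMatrix,
    MatrixValidationError,
    drop_unexpressed,
    gene_means,
    subset_samples,
)

__all__ = [
    "NormalizedProfileMatrix",
    "normalize_profiles",
    "delta_sum",
    "CoexpressionRanking",
    "rank_coexpressed",
    "profiles_for_samples",
]


@dataclass(frozen=True)
class NormalizedProfileMatrix:
    """Per-gene mean-normalized profiles (z-values), genes × samples."""

    z: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.z.to_numpy()
        if not np.isfinite(values).all():
            raise MatrixValidationError("non-finite normalized values")
        if (values < -1.0 - 1e-12).any():
            raise MatrixValidationError(
                "normalized values below -1; input was not a valid TPM matrix"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.z.index]

    @property
    def sample_labels(self) -> list[str]:
        return [str(s) for s in self.z.columns]

    def profile(self, gene: str) -> pd.Series:
        if gene not in self.z.index:
            raise KeyError(f"unknown gene: {gene}")
        return self.z.loc[gene]


def normalize_profiles(matrix: ExpressionMatrix) -> NormalizedProfileMatrix:
    """Compute z(g, s) = (x(g, s) − m(g)) / m(g) for every gene.

    Requires all gene means to be strictly positive; run
    :func:`coexq.expression_io.drop_unexpressed` first.
    """
    means = gene_means(matrix)
    zero = means[means == 0]
    if len(zero):
        raise MatrixValidationError(
            f"{len(zero)} gene(s) with zero mean (e.g. {zero.index[0]}); "
            "run drop_unexpressed before normalizing"
        )
    z = matrix.data.sub(means, axis=0).div(means, axis=0)
    return NormalizedProfileMatrix(z)


def delta_sum(profile_a: pd.Series, profile_b: pd.Series) -> float:
    """L1 distance between two z-profiles over an identical ordered sample set."""
    if list(profile_a.index) != list(profile_b.index):
        only_a = set(profile_a.index) - set(profile_b.index)
        only_b = set(profile_b.index) - set(profile_a.index)
        if only_a or only_b:
            raise MatrixValidationError(
                "profiles cover different samples; "
                f"only in first: {sorted(map(str, only_a))}, "
                f"only in second: {sorted(map(str, only_b))}"
            )
        raise MatrixValidationError("profiles list samples in different orders")
    return float(np.abs(profile_a.to_numpy() - profile_b.to_numpy()).sum())


@dataclass(frozen=True)
class CoexpressionRanking:
    """Ordered (gene_id, Δsum) table for a query gene.

    ``entries`` has columns ``rank`` (1-based), ``gene_id`` and ``dsum``,
    sorted by Δsum ascending with ties broken lexicographically by gene
    identifier; the query gene is always first with Δsum 0.
    """

    query_gene: str
    entries: pd.DataFrame
    sample_labels: list[str] = field(default_factory=list)


def rank_coexpressed(
    z: NormalizedProfileMatrix, query: str, top_k: int | None = None
) -> CoexpressionRanking:
    """Rank every gene by its Δsum to ``query``'s profile.

    The query heads the ranking with Δsum exactly 0 (it is forced to 0,
    not merely computed, so the self-identity holds to the bit).  With
    ``top_k`` the ranking is truncated to its first ``top_k`` entries,
    which always include the query.
    """
    if query not in z.z.index:
        raise KeyError(f"query gene {query!r} not present in the matrix")
    if top_k is not None and top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")

    q = z.z.loc[query].to_numpy()
    dsums = np.abs(z.z.to_numpy() - q).sum(axis=1)
    table = pd.DataFrame({"gene_id": z.gene_ids, "dsum": dsums})
    table.loc[table["gene_id"] == query, "dsum"] = 0.0
    # deterministic order: Δsum ascending, then gene id; query pinned first
    table["_is_query"] = (table["gene_id"] != query).astype(int)
    table = table.sort_values(
        ["_is_query", "dsum", "gene_id"], kind="mergesort"
    ).drop(columns="_is_query")
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    if top_k is not None:
        table = table.head(top_k)
    return CoexpressionRanking(
        query_gene=query,
        entries=table.reset_index(drop=True),
        sample_labels=z.sample_labels,
    )


def profiles_for_samples(
    matrix: ExpressionMatrix,
    samples: list[str] | None = None,
    *,
    mean_scope: str = "subset",
) -> NormalizedProfileMatrix:
    """Filter, normalize and (optionally) subset in one call.

    ``mean_scope`` resolves the ambiguity of which samples the per-gene
    mean is taken over when ranking is restricted to a sample subset:

    - ``"subset"`` (default): restrict to ``samples`` first, then drop
      zero-mean genes and normalize — means reflect the subset only.
    - ``"full"``: drop zero-mean genes and normalize over *all* samples
      of ``matrix``, then restrict the z-columns to ``samples`` (z-rows
      then no longer sum to zero over the kept columns).
    """
    if mean_scope not in ("subset", "full"):
        raise ValueError(f"mean_scope must be 'subset' or 'full', got {mean_scope!r}")
    if samples is None:
        return normalize_profiles(drop_unexpressed(matrix))
    if mean_scope == "subset":
        sub = subset_samples(matrix, samples)
        return normalize_profiles(drop_unexpressed(sub))
    z_full = normalize_profiles(drop_unexpressed(matrix))
    unknown = [s for s in samples if s not in z_full.z.columns]
    if unknown:
        raise MatrixValidationError(f"unknown sample label(s): {', '.join(unknown)}")
    return NormalizedProfileMatrix(z_full.z.loc[:, list(samples)])
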