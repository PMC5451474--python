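"""Cataloguing of DE miRNAs by developmental stage group.

The eight stages are split into the embryonic group G1 (35E, 49E, 63E, 77E)
and the postnatal group G2 (2P, 28P, 90P, 180P).  A miRNA enters a group's
up (or down) set when it is flagged DE in that direction in at least one
stage of the group.  The module also provides Venn overlaps between sets,
top-abundance rankings, PCA ordination of the DE expression submatrix, and
a generic one-sided hypergeometric term-enrichment test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import CountMatrix
from .de_test import SignificanceCriteria, adjust_fdr, test_matrix

__all__ = [
    "StageGrouping",
    "DECatalog",
    "OrdinationResult",
    "classify_groups",
    "venn_overlap",
    "top_abundant",
    "pca_ordination",
    "enrich_terms",
    "pooled_group_test",
]

EMBRYONIC_STAGES = ("35E", "49E", "63E", "77E")
POSTNATAL_STAGES = ("2P", "28P", "90P", "180P")


@dataclass(frozen=True)
class StageGrouping:
    g1: tuple[str, ...] = EMBRYONIC_STAGES
    g2: tuple[str, ...] = POSTNATAL_STAGES

    def __post_init__(self) -> None:
        if set(self.g1) & set(self.g2):
            raise ValueError("stage groups must be disjoint")
        if not self.g1 or not self.g2:
            raise ValueError("both stage groups must be non-empty")

    def group_of(self, stage: str) -> str:
        if stage in self.g1:
            return "G1"
        if stage in self.g2:
            return "G2"
        raise ValueError(f"stage label {stage!r} absent from grouping")


@dataclass
class DECatalog:
    """G1/G2 x up/down DE sets with per-stage membership records."""

    sets: dict[str, set[str]]
    stage_table: pd.DataFrame
    membership: pd.DataFrame
    dual_direction: dict[str, set[str]] = field(default_factory=dict)

    def overlap(self, set_a: str, set_b: str) -> tuple[int, int, int]:
        return venn_overlap(self, set_a, set_b)


def classify_groups(results: pd.DataFrame, grouping: StageGrouping = StageGrouping()) -> DECatalog:
    """Build the DE catalogue from per-stage test results.

    ``results`` needs columns ``mirna_id``, ``stage``, ``direction``
    (``up``/``down``, oriented so "up" means higher in the reference breed)
    and boolean ``significant``.  A miRNA flagged in opposite directions at
    different stages of one group is kept in both of that group's sets and
    reported via ``dual_direction`` (with a warning), never silently
    dropped.
    """
    required = {"mirna_id", "stage", "direction", "significant"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    for stage in results["stage"].unique():
        grouping.group_of(stage)  # raises on unknown stage

    sig = results[results["significant"] & results["direction"].isin(["up", "down"])]
    sets: dict[str, set[str]] = {
        "G1_up": set(), "G1_down": set(), "G2_up": set(), "G2_down": set()
    }
    for _, row in sig.iterrows():
        group = grouping.group_of(row["stage"])
        sets[f"{group}_{row['direction']}"].add(row["mirna_id"])

    dual = {
        g: sets[f"{g}_up"] & sets[f"{g}_down"] for g in ("G1", "G2")
        if sets[f"{g}_up"] & sets[f"{g}_down"]
    }
    for g, ids in dual.items():
        warnings.warn(
            f"{len(ids)} miRNA(s) flagged in both directions within {g}: "
            f"{sorted(ids)[:5]}...", stacklevel=2,
        )

    rows = []
    stage_order = list(grouping.g1) + list(grouping.g2)
    for stage in stage_order:
        here = sig[sig["stage"] == stage]
        n_up = here[here["direction"] == "up"]["mirna_id"].nunique()
        n_down = here[here["direction"] == "down"]["mirna_id"].nunique()
        rows.append({"stage": stage, "n_up": n_up, "n_down": n_down, "n_total": n_up + n_down})
    for g in ("G1", "G2"):
        up, down = sets[f"{g}_up"], sets[f"{g}_down"]
        rows.append({"stage": g, "n_up": len(up), "n_down": len(down), "n_total": len(up | down)})
    stage_table = pd.DataFrame(rows)

    membership = (
        sig[["mirna_id", "stage", "direction"]]
        .drop_duplicates()
        .sort_values(["mirna_id", "stage", "direction"])
        .reset_index(drop=True)
    )
    return DECatalog(sets=sets, stage_table=stage_table, membership=membership,
                     dual_direction=dual)


def venn_overlap(catalog: DECatalog, set_a: str, set_b: str) -> tuple[int, int, int]:
    """Return ``(only_a, shared, only_b)`` counts for two named sets."""
    for name in (set_a, set_b):
        if name not in catalog.sets:
            raise KeyError(f"unknown set name {name!r}; have {sorted(catalog.sets)}")
    a, b = catalog.sets[set_a], catalog.sets[set_b]
    shared = len(a & b)
    return len(a) - shared, shared, len(b) - shared


def top_abundant(
    tpm: pd.DataFrame,
    mirnas: set[str],
    columns: list[str],
    k: int = 10,
    rank_stat: str = "mean",
) -> pd.DataFrame:
    """Rank a miRNA set by abundance over the given library columns.

    ``rank_stat`` is ``mean`` or ``max`` over the columns; ties break
    deterministically by miRNA id.  Returns at most ``k`` rows (the whole
    set when it is smaller).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if rank_stat not in ("mean", "max"):
        raise ValueError(f"unknown rank_stat {rank_stat!r}")
    present = sorted(m for m in mirnas if m in tpm.index)
    if not present:
        return pd.DataFrame(columns=["mirna_id", "abundance"])
    sub = tpm.loc[present, columns]
    stat = sub.mean(axis=1) if rank_stat == "mean" else sub.max(axis=1)
    out = pd.DataFrame({"mirna_id": stat.index, "abundance": stat.to_numpy()})
    out = out.sort_values(["abundance", "mirna_id"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    return out.head(k)


@dataclass
class OrdinationResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # features x components
    variance_fractions: np.ndarray


def pca_ordination(matrix: pd.DataFrame, log2_pseudocount: float | None = 1.0) -> OrdinationResult:
    """PCA of an expression submatrix (features x libraries).

    Libraries are the observations, features (miRNAs) the variables;
    variables are mean-centred (covariance PCA, no unit-variance scaling),
    optionally after a log2(x + pseudocount) transform.  The decomposition
    is the SVD of the centred matrix; per component, the loading of largest
    magnitude is made positive (deterministic sign convention).
    """
    if matrix.shape[1] < 2:
        raise ValueError("ordination requires at least 2 samples")
    if matrix.shape[0] < 2:
        raise ValueError("ordination requires at least 2 features")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    if log2_pseudocount is not None:
        x = np.log2(x + log2_pseudocount)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    total = float((s**2).sum())
    frac = s**2 / total if total > 0 else np.zeros_like(s)
    comp = [f"PC{i+1}" for i in range(len(s))]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp),
        loadings=pd.DataFrame(vt.T, index=matrix.index, columns=comp),
        variance_fractions=frac,
    )


def enrich_terms(
    selection: set[str],
    universe: set[str],
    annotation: dict[str, set[str]],
    fdr_mode: str = "monotone",
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each term in a selection.

    For a term annotating K of the M universe members, with n selected and
    k of them in the term, ``p = P(X >= k)`` for X hypergeometric(M, K, n).
    Adjusted p-values use the rank-based FDR (monotone step-up by default).
    """
    outside = selection - universe
    if outside:
        raise ValueError(f"selection members outside universe: {sorted(outside)[:5]}")
    m = len(universe)
    n = len(selection)
    rows = []
    for term in sorted(annotation):
        members = annotation[term] & universe
        k_term = len(members)
        overlap = len(members & selection)
        p = float(hypergeom.sf(overlap - 1, m, k_term, n)) if k_term else 1.0
        rows.append({"term": term, "term_size": k_term, "overlap": overlap, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = adjust_fdr(out["p"].to_numpy(), mode=fdr_mode)
    else:
        out["fdr"] = []
    return out


def pooled_group_test(
    counts: CountMatrix,
    grouping: StageGrouping,
    breeds: tuple[str, str],
    criteria: SignificanceCriteria,
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Alternative group-level mode: pool tag counts over each group's stages.

    Sums the counts of each breed across a group's stages into one pooled
    library per breed and runs a single exact test per group.  Comparisons
    are oriented (pooled breed2, pooled breed1) so "up" means higher in the
    first-listed breed.
    """
    pooled = {}
    sizes = {}
    for group, stages in (("G1", grouping.g1), ("G2", grouping.g2)):
        for breed in breeds:
            cols = [f"{breed}_{s}" for s in stages]
            missing = [c for c in cols if c not in counts.counts.columns]
            if missing:
                raise KeyError(f"missing libraries for pooled test: {missing}")
            label = f"{breed}_{group}"
            pooled[label] = counts.counts[cols].sum(axis=1)
            sizes[label] = float(counts.library_sizes[cols].sum())
    pooled_cm = CountMatrix(pd.DataFrame(pooled), pd.Series(sizes))
    comparisons = [
        (f"{breeds[1]}_G1", f"{breeds[0]}_G1"),
        (f"{breeds[1]}_G2", f"{breeds[0]}_G2"),
    ]
    res = test_matrix(pooled_cm, comparisons, criteria, pseudo=pseudo)
    res["group"] = res["comparison"].str.extract(r"_(G[12])$")[0]
    return res
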