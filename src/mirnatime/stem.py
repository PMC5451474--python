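"""Short time-series profile clustering (STEM-style).

Model profiles are integer-valued template series of length T that start at
0 and change by at most ``c`` units between consecutive time points, giving
a universe of ``(2c+1)**(T-1)`` candidates.  A subset of ``m``
representatives is chosen by greedy max-min selection under the distance
``1 - Pearson r``; each gene's (log2, first-point-anchored) series is
assigned to the representative it correlates with best.  Profile
significance compares the observed assignment count with the expectation
under random permutation of the time points: with T = 4 all 24 orderings
are enumerated, and the observed count is tested against a binomial tail on
the permutation-estimated expectation, Bonferroni-corrected over the
selected profiles.

Defaults c = 2 and m = 50 are the classic STEM v1.1 settings for 4-8 time
points.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "ModelProfile",
    "generate_model_profiles",
    "select_representative_profiles",
    "transform_series",
    "assign_profiles",
    "profile_significance",
]

DEFAULT_C = 2
DEFAULT_M = 50


@dataclass(frozen=True)
class ModelProfile:
    id: int
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.values[0] != 0:
            raise ValueError("model profiles start at 0")

    @property
    def is_flat(self) -> bool:
        return len(set(self.values)) == 1


def generate_model_profiles(t: int, c: int = DEFAULT_C) -> list[ModelProfile]:
    """Enumerate all ``(2c+1)**(t-1)`` profiles, in lexicographic order of
    their difference vectors (ids dense from 0)."""
    if t < 2:
        raise ValueError("need at least 2 time points")
    if c < 1:
        raise ValueError("max unit change c must be >= 1")
    profiles = []
    for pid, diffs in enumerate(itertools.product(range(-c, c + 1), repeat=t - 1)):
        values = (0, *np.cumsum(diffs).tolist())
        profiles.append(ModelProfile(id=pid, values=values))
    return profiles


def _profile_matrix(profiles: list[ModelProfile]) -> np.ndarray:
    return np.array([p.values for p in profiles], dtype=float)


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; returns (standardized, constant_mask)."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    return xc / safe[:, None], constant


def select_representative_profiles(
    candidates: list[ModelProfile], m: int
) -> list[ModelProfile]:
    """Greedy max-min selection of ``m`` representatives.

    The all-flat profile has undefined correlation and is excluded from
    selection.  The first pick is the candidate with the largest summed
    distance to all others; each subsequent pick maximizes the minimum
    distance (1 - Pearson r) to the already-selected set.  Ties break by
    lowest profile id.  When ``m`` covers all (non-flat) candidates they are
    all returned.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    cands = sorted((p for p in candidates if not p.is_flat), key=lambda p: p.id)
    if not cands:
        return []
    if m >= len(cands):
        return cands
    std, _ = _standardize_rows(_profile_matrix(cands))
    corr = np.clip(std @ std.T, -1.0, 1.0)
    dist = 1.0 - corr
    # argmax returns the first (lowest-id) maximizer: candidates are id-sorted
    selected = [int(np.argmax(dist.sum(axis=1)))]
    min_dist = dist[selected[0]].copy()
    while len(selected) < m:
        min_dist[selected] = -np.inf
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
    return [cands[i] for i in selected]


def transform_series(series: np.ndarray) -> np.ndarray:
    """Anchor each series at 0 by subtracting its first time point.

    Matches the profile convention (profiles start at 0); idempotent.
    """
    arr = np.asarray(series, dtype=float)
    return arr - arr[..., :1]


def assign_profiles(series: pd.DataFrame, profiles: list[ModelProfile]) -> pd.DataFrame:
    """Assign each gene series to its best-correlated profile.

    ``series`` rows are genes, columns the T time points (already on the
    log2 scale; the first-point anchoring does not change Pearson r).
    Zero-variance (constant) series have undefined correlation and are
    excluded with a reason rather than forced into a profile.  Correlation
    ties break to the lowest profile id.
    """
    usable = sorted((p for p in profiles if not p.is_flat), key=lambda p: p.id)
    if not usable:
        raise ValueError("need at least one non-flat profile")
    pmat = _profile_matrix(usable)
    if pmat.shape[1] != series.shape[1]:
        raise ValueError(
            f"series length {series.shape[1]} does not match profile length {pmat.shape[1]}"
        )
    pstd, _ = _standardize_rows(pmat)
    gstd, constant = _standardize_rows(transform_series(series.to_numpy(dtype=float)))
    r = np.clip(gstd @ pstd.T, -1.0, 1.0)
    best = np.argmax(r, axis=1)  # first maximizer = lowest profile id
    ids = np.array([p.id for p in usable])
    out = pd.DataFrame(
        {
            "gene_id": series.index,
            "profile_id": pd.array(ids[best], dtype="Int64"),
            "r": r[np.arange(len(best)), best],
            "excluded": constant,
            "reason": np.where(constant, "constant series", ""),
        }
    )
    out.loc[out["excluded"], "profile_id"] = pd.NA
    out.loc[out["excluded"], "r"] = np.nan
    return out


def _assignment_counts(gstd: np.ndarray, pstd: np.ndarray, ids: np.ndarray,
                       n_profiles: int) -> np.ndarray:
    r = gstd @ pstd.T
    best = np.argmax(r, axis=1)
    return np.bincount(best, minlength=n_profiles)


def profile_significance(
    series: pd.DataFrame,
    profiles: list[ModelProfile],
    n_permutations: int | None = None,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation-calibrated enrichment of genes per model profile.

    Every permutation of the T time points is applied to the gene series
    (exhaustively when T! <= 120, i.e. up to T = 5; otherwise
    ``n_permutations`` orderings sampled with ``seed``), the series are
    re-anchored, and genes are re-assigned.  The mean assigned count over
    permutations is the expected count E_i; the observed count O_i is tested
    with ``p = P(Bin(n, E_i/n) >= O_i)`` where n is the number of assigned
    genes, Bonferroni-corrected over the selected profiles.
    """
    usable = sorted((p for p in profiles if not p.is_flat), key=lambda p: p.id)
    if not usable:
        raise ValueError("need at least one non-flat profile")
    t = series.shape[1]
    pstd, _ = _standardize_rows(_profile_matrix(usable))
    gmat = series.to_numpy(dtype=float)
    gstd, constant = _standardize_rows(gmat)
    gstd = gstd[~constant]
    n = gstd.shape[0]
    if n == 0:
        raise ValueError("no assignable (non-constant) gene series")
    ids = np.array([p.id for p in usable])
    k = len(usable)

    observed = _assignment_counts(gstd, pstd, ids, k)

    if n_permutations is None and math.factorial(t) <= 120:
        perms = list(itertools.permutations(range(t)))
    else:
        n_perm = n_permutations or 200
        rng = np.random.default_rng(seed)
        perms = [tuple(rng.permutation(t)) for _ in range(n_perm)]

    counts = np.zeros(k)
    for perm in perms:
        permuted = gmat[~constant][:, perm]
        pg, pc = _standardize_rows(permuted)
        # a permutation cannot make a non-constant series constant
        counts += _assignment_counts(pg, pstd, ids, k)
    expected = counts / len(perms)

    p = binom.sf(observed - 1, n, np.clip(expected / n, 0.0, 1.0))
    corrected = np.minimum(1.0, p * k)
    return pd.DataFrame(
        {
            "profile_id": ids,
            "observed": observed,
            "expected": expected,
            "p": p,
            "p_corrected": corrected,
            "significant": corrected < alpha,
        }
    )
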