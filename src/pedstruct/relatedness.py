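"""Inbreeding, coancestry, relatedness and their per-generation rates.

Core identities.  With ``A`` the numerator (additive) relationship matrix:

* inbreeding ``F_i = A_ii - 1`` — probability the two alleles at a locus in
  ``i`` are identical by descent;
* coancestry ``f_xy = A_xy / 2`` and ``f_xx = (1 + F_x) / 2``;
* average relatedness ``AR_i = mean_j A_ij`` over the whole pedigree
  including ``i`` itself.

``F`` is computed with the Meuwissen-Luo traversal of the ``L D L'``
decomposition of ``A`` (linear memory, no dense matrix).  Matrix-vector
products ``A v`` use Colleau's indirect method (two sparse triangular sweeps
plus a diagonal scale), which yields exact population means of coancestry,
``AR`` and subpopulation cross-coancestries in ``O(n)`` per product.

Per-generation rates normalize by pedigree depth ``t`` (equivalent
generations): ``dF = 1 - (1 - F)^(1/(t-1))`` and, for a pair ``(a, b)``,
``dC = 1 - (1 - f_ab)^(1/((t_a + t_b)/2))``.  The non-random mating degree
``alpha`` solves ``(1 - F) = (1 - C)(1 - alpha)``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import demography
from .pedigree import Pedigree

DENSE_LIMIT = 4000          # build the dense A only below this size
HIGH_INBREEDING = 0.10      # threshold above which an animal counts as highly inbred
PAIR_SAMPLE = 2_000_000     # pairs sampled for the dC mean on large references
DENSE_PAIR_LIMIT = 2000     # all pairs used when the reference is at most this big


def _mendelian_variances(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Diagonal D of A = T D T' (within-family segregation variances)."""
    s, m = ped.sire, ped.dam
    Fs = np.where(s >= 0, F[np.clip(s, 0, None)], -1.0)
    Fm = np.where(m >= 0, F[np.clip(m, 0, None)], -1.0)
    return 0.5 - 0.25 * (Fs + Fm)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-individual inbreeding coefficients (Meuwissen-Luo traversal).

    For each animal the algorithm expands ``A_ii = sum_j L_ij^2 D_j`` over
    its ancestors only, processing them in decreasing topological index via a
    heap; memory stays linear in pedigree size.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    D = np.empty(n)
    for i in range(n):
        s, m = sire[i], dam[i]
        D[i] = 0.5 - 0.25 * ((F[s] if s >= 0 else -1.0) + (F[m] if m >= 0 else -1.0))
        if s < 0 and m < 0:
            continue  # founder: F = 0
        # expand ancestors of i, largest index first
        coef = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            L = coef.pop(j)
            a_ii += L * L * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p in coef:
                        coef[p] += 0.5 * L
                    else:
                        coef[p] = 0.5 * L
                        heapq.heappush(heap, -p)
        F[i] = a_ii - 1.0
    return F


def relationship_times(ped: Pedigree, v: np.ndarray, F: np.ndarray | None = None) -> np.ndarray:
    """Indirect product ``A v`` (Colleau): backward sweep, scale by D, forward.

    Never materializes ``A``; cost is two passes over the pedigree.
    """
    if F is None:
        F = inbreeding(ped)
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    D = _mendelian_variances(ped, F)
    w = np.asarray(v, dtype=float).copy()
    for i in range(n - 1, -1, -1):          # w = T' v
        wi = w[i]
        if wi != 0.0:
            if sire[i] >= 0:
                w[sire[i]] += 0.5 * wi
            if dam[i] >= 0:
                w[dam[i]] += 0.5 * wi
    w *= D                                   # w = D T' v
    u = np.zeros(n)
    for i in range(n):                       # u = T w = A v
        t = w[i]
        if sire[i] >= 0:
            t += 0.5 * u[sire[i]]
        if dam[i] >= 0:
            t += 0.5 * u[dam[i]]
        u[i] = t
    return u


def additive_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    Intended for small/medium pedigrees (guarded at ``DENSE_LIMIT``); all
    exact population means in this package go through
    :func:`relationship_times` instead.
    """
    n = len(ped)
    if n > DENSE_LIMIT:
        raise ValueError(f"dense A requested for n={n} > {DENSE_LIMIT}")
    A = np.zeros((n, n))
    for i in range(n):
        s, m = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if m >= 0:
            row += 0.5 * A[m, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, m] if (s >= 0 and m >= 0) else 0.0)
    return A


def kinship(ped: Pedigree, a: str, b: str, _memo: dict | None = None) -> float:
    """Coancestry f_ab by the classical recursive definition (memoized)."""
    i, j = ped.index(a), ped.index(b)
    memo: dict[tuple[int, int], float] = {} if _memo is None else _memo
    sire, dam = ped.sire, ped.dam

    def f(x: int, y: int) -> float:
        if x < 0 or y < 0:
            return 0.0
        if x > y:
            x, y = y, x
        key = (x, y)
        if key in memo:
            return memo[key]
        if x == y:
            val = 0.5 * (1.0 + f(sire[x], dam[x]))
        else:
            # y is never an ancestor of x because x <= y in topological order
            val = 0.5 * (f(x, sire[y]) + f(x, dam[y]))
        memo[key] = val
        return val

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * len(ped) + 100))
    try:
        return f(i, j)
    finally:
        sys.setrecursionlimit(old)


def coancestry(ped: Pedigree, pairs) -> np.ndarray | float:
    """Coancestries for explicit id pairs, or the all-pairs mean.

    ``pairs="all"`` returns the mean over all ordered pairs of the pedigree
    including self-pairs (exact, via the indirect method).
    """
    if isinstance(pairs, str) and pairs == "all":
        return mean_coancestry(ped)
    memo: dict = {}
    return np.array([kinship(ped, a, b, _memo=memo) for a, b in pairs])


def mean_coancestry(
    ped: Pedigree, reference: np.ndarray | None = None, F: np.ndarray | None = None
) -> float:
    """Exact mean coancestry over ordered pairs (self-pairs included).

    ``reference`` is a boolean mask or index array; defaults to all animals.
    """
    n = len(ped)
    v = np.zeros(n)
    if reference is None:
        v[:] = 1.0 / n
    else:
        idx = np.asarray(reference)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        if len(idx) == 0:
            raise ValueError("empty reference")
        v[idx] = 1.0 / len(idx)
    u = relationship_times(ped, v, F=F)
    return 0.5 * float(v @ u)


def average_relatedness(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """AR_i = mean_j A_ij over the whole pedigree, one indirect product."""
    n = len(ped)
    return relationship_times(ped, np.full(n, 1.0 / n), F=F)


def rate_of_inbreeding(F, t):
    """Individual per-generation rate dF = 1 - (1-F)^(1/(t-1)).

    For pedigrees no deeper than one generation (t <= 1) the rate is defined
    as F itself.  Vectorized over arrays.
    """
    F = np.asarray(F, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(F >= 1.0):
        raise ValueError("inbreeding coefficient must be < 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        dF = np.where(t > 1.0, 1.0 - (1.0 - F) ** (1.0 / np.maximum(t - 1.0, 1e-300)), F)
    return dF if dF.ndim else float(dF)


def rate_of_coancestry(f_ab, t_a, t_b):
    """Pairwise rate dC = 1 - (1 - f_ab)^(1/((t_a+t_b)/2)); symmetric in (a,b)."""
    f_ab = np.asarray(f_ab, dtype=float)
    tm = (np.asarray(t_a, dtype=float) + np.asarray(t_b, dtype=float)) / 2.0
    if np.any(f_ab >= 1.0):
        raise ValueError("coancestry must be < 1")
    if np.any(tm <= 0.0):
        raise ValueError("mean equivalent generations must be positive")
    dC = 1.0 - (1.0 - f_ab) ** (1.0 / tm)
    return dC if dC.ndim else float(dC)


def nonrandom_mating(F_bar: float, C_bar: float) -> float:
    """Degree of assortative mating: alpha = 1 - (1-F)/(1-C).

    Negative values indicate disassortative (coancestry-avoiding) mating.
    """
    if C_bar >= 1.0:
        raise ValueError("mean coancestry of 1 leaves alpha undefined")
    return 1.0 - (1.0 - F_bar) / (1.0 - C_bar)


def founder_contribution_vectors(ped: Pedigree) -> list[dict[int, float]]:
    """Per-animal sparse map founder index -> expected genome proportion.

    Unknown-parent slots contribute to no founder, so the proportions sum to
    the traced fraction of the pedigree (1 at full completeness).
    """
    out: list[dict[int, float]] = []
    founder = ped.is_founder
    for i in range(len(ped)):
        if founder[i]:
            out.append({i: 1.0})
            continue
        c: dict[int, float] = {}
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                for k, v in out[p].items():
                    c[k] = c.get(k, 0.0) + 0.5 * v
        out.append(c)
    return out


def genetic_conservation_index(ped: Pedigree, ids=None) -> np.ndarray:
    """GCI_i = 1 / sum_k p_k^2 over founder contributions p to individual i.

    A founder (no known ancestors) is its own sole founder: GCI = 1.
    """
    contribs = founder_contribution_vectors(ped)
    idx = list(range(len(ped))) if ids is None else [ped.index(a) for a in ids]
    out = np.empty(len(idx))
    for pos, i in enumerate(idx):
        ssq = sum(v * v for v in contribs[i].values())
        out[pos] = 1.0 / ssq if ssq > 0 else 1.0
    return out


@dataclass
class DiversitySummary:
    """Population-level diversity metrics plus the per-individual table."""

    n_reference: int
    mean_F: float
    mean_C: float                  # over ordered reference pairs incl. self-pairs
    mean_dF: float
    mean_dC: float                 # over distinct reference pairs
    alpha: float
    pct_inbred: float
    pct_highly_inbred: float
    max_F: float
    mean_AR: float
    mean_GCI: float
    per_individual: pd.DataFrame   # F, AR, dF, GCI, equivalent_generations


def _pairwise_mean_dC(
    ped: Pedigree,
    ref_idx: np.ndarray,
    t: np.ndarray,
    F: np.ndarray,
    seed: int = 0,
) -> float:
    """Mean pairwise rate of coancestry over the reference.

    All distinct pairs when the reference is small enough for a dense A;
    otherwise a seeded random sample of ``PAIR_SAMPLE`` pairs using the
    recursive kinship (documented: the source analyses do not state their
    pairing scheme).
    """
    m = len(ref_idx)
    if m < 2:
        return 0.0
    if m <= DENSE_PAIR_LIMIT and len(ped) <= DENSE_LIMIT:
        A = additive_matrix(ped)
        iu = np.triu_indices(m, k=1)
        f = 0.5 * A[np.ix_(ref_idx, ref_idx)][iu]
        tm = (t[ref_idx][iu[0]] + t[ref_idx][iu[1]]) / 2.0
        ok = tm > 0
        if not ok.any():
            return 0.0
        return float(np.mean(1.0 - (1.0 - f[ok]) ** (1.0 / tm[ok])))
    rng = np.random.default_rng(seed)
    n_pairs = min(PAIR_SAMPLE, m * (m - 1) // 2)
    memo: dict = {}
    vals = []
    for _ in range(n_pairs):
        i, j = rng.choice(m, size=2, replace=False)
        a, b = ref_idx[i], ref_idx[j]
        fab = kinship(ped, ped.ids[a], ped.ids[b], _memo=memo)
        tm = (t[a] + t[b]) / 2.0
        if tm > 0:
            vals.append(1.0 - (1.0 - fab) ** (1.0 / tm))
    return float(np.mean(vals)) if vals else 0.0


def diversity_summary(
    ped: Pedigree, reference: np.ndarray | None = None, seed: int = 0
) -> DiversitySummary:
    """All Table-4-style diversity statistics for a reference population.

    ``reference`` is a boolean mask over the pedigree (defaults to the focal
    animals).  ``mean_C`` includes self-pairs (the convention under which
    founder genome equivalents recover n for unrelated founders); the
    pairwise rate ``mean_dC`` uses distinct pairs only, since self-pairs are
    not matings.
    """
    ref = ped.focal if reference is None else np.asarray(reference, dtype=bool)
    ref_idx = np.flatnonzero(ref)
    if len(ref_idx) == 0:
        raise ValueError("empty reference population")
    F = inbreeding(ped)
    AR = average_relatedness(ped, F=F)
    t = demography.generation_numbers(ped)["equivalent_generations"].to_numpy()
    GCI = genetic_conservation_index(ped)
    dF = rate_of_inbreeding(F, t)

    Fr = F[ref_idx]
    mean_F = float(Fr.mean())
    mean_C = mean_coancestry(ped, ref_idx, F=F)
    mean_dC = _pairwise_mean_dC(ped, ref_idx, t, F, seed=seed)
    per = pd.DataFrame(
        {
            "id": [ped.ids[i] for i in ref_idx],
            "F": Fr,
            "AR": AR[ref_idx],
            "dF": np.asarray(dF)[ref_idx],
            "GCI": GCI[ref_idx],
            "equivalent_generations": t[ref_idx],
        }
    ).set_index("id")
    return DiversitySummary(
        n_reference=len(ref_idx),
        mean_F=mean_F,
        mean_C=mean_C,
        mean_dF=float(np.asarray(dF)[ref_idx].mean()),
        mean_dC=mean_dC,
        alpha=nonrandom_mating(mean_F, mean_C),
        pct_inbred=float(100.0 * (Fr > 0).mean()),
        pct_highly_inbred=float(100.0 * (Fr > HIGH_INBREEDING).mean()),
        max_F=float(Fr.max()),
        mean_AR=float(AR[ref_idx].mean()),
        mean_GCI=float(GCI[ref_idx].mean()),
        per_individual=per,
    )
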