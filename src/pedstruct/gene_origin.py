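"""Probabilities of gene origin: founders, ancestors, founder genomes.

Founders are animals with both parents unknown; the *actual base population*
counts an animal with exactly one unknown parent as half a founder.  The
probability ``q_k`` that a gene sampled in the reference population
originates from founder ``k`` gives the effective number of founders
``fe = 1 / sum q_k^2``.

The effective number of ancestors ``fa`` corrects ``fe`` for pedigree
bottlenecks: ancestors (founders or not) are picked greedily by their
*marginal* contribution to the reference — contribution through paths not
intercepted by previously selected ancestors — and ``fa = 1 / sum p_k^2``.

The founder genome equivalent ``fg = 1 / (2 C_ref)`` (inverse of twice the
mean reference coancestry, self-pairs included) additionally accounts for
random loss of founder alleles by drift; it can also be estimated by gene
dropping.  In studbook-like populations (many founders, right-skewed parent
usage) the ordering ``fg <= fa <= fe`` holds; with very small founder pools
and near-equal contributions fa and fe converge and the greedy marginal
decomposition can cross fe at the second decimal.

Diversity bookkeeping: ``GD = 1 - 1/(2 fg)`` (all loss), ``GD* = 1 - 1/(2 fe)``
(loss from unequal founder contributions only), ``GD* - GD`` the drift
component, and the effective number of non-founders
``Nef = 1 / (1/fg - 1/fe)`` locating the loss in post-founder generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import relatedness
from .pedigree import Pedigree

MARGINAL_TOL = 1e-8  # stop ancestor selection below this residual contribution


@dataclass
class GeneOriginReport:
    n_founders: int
    base_population: int          # >= 1 unknown parent
    actual_base: float            # one unknown parent counts 0.5
    n_ancestors_selected: int
    fe: float
    fa: float
    fg: float
    nef: float
    gd: float
    gd_star: float
    founder_probabilities: dict[str, float] = field(default_factory=dict)
    marginal_contributions: list[tuple[str, float]] = field(default_factory=list)


def _reference_indices(ped: Pedigree, reference) -> np.ndarray:
    if reference is None:
        idx = ped.focal_indices
    elif isinstance(reference, np.ndarray) and reference.dtype == bool:
        idx = np.flatnonzero(reference)
    else:
        idx = np.array([ped.index(a) for a in reference])
    if len(idx) == 0:
        raise ValueError("empty reference population")
    return idx


def _raw_contributions(ped: Pedigree, ref_idx: np.ndarray, blocked: set[int] = frozenset()) -> np.ndarray:
    """Expected genetic contribution of every animal to the reference mean.

    Backward gene-flow sweep: each animal passes half of its accumulated
    weight to each known parent.  Animals in ``blocked`` do not pass weight
    upward (their ancestry is treated as already accounted for) — this is
    what makes repeated sweeps yield *marginal* contributions.
    """
    n = len(ped)
    w = np.zeros(n)
    w[ref_idx] = 1.0 / len(ref_idx)
    for i in range(n - 1, -1, -1):
        wi = w[i]
        if wi == 0.0 or i in blocked:
            continue
        if ped.sire[i] >= 0:
            w[ped.sire[i]] += 0.5 * wi
        if ped.dam[i] >= 0:
            w[ped.dam[i]] += 0.5 * wi
    return w


def founder_accounting(ped: Pedigree, reference=None):
    """Founder counts and per-origin gene-origin probabilities ``q_k``.

    Returns ``(n_founders, base_population, actual_base, {origin_id: q_k})``.
    Gene origins are the base-population animals: every unknown-parent slot
    is a point of gene origin credited to the animal carrying it, so an
    animal with one unknown parent contributes at half weight (the
    half-founder convention) and the ``q_k`` always sum to 1.
    """
    ref_idx = _reference_indices(ped, reference)
    unknown = 2 - ped.n_known_parents
    w = _raw_contributions(ped, ref_idx)
    q_arr = w * unknown / 2.0
    q = {ped.ids[i]: float(q_arr[i]) for i in np.flatnonzero(q_arr > 0)}
    return (
        int(ped.is_founder.sum()),
        int((unknown >= 1).sum()),
        float((unknown / 2.0).sum()),
        q,
    )


def effective_founders(founder_probabilities) -> float:
    """fe = 1 / sum q_k^2."""
    q = np.asarray(
        list(founder_probabilities.values())
        if isinstance(founder_probabilities, dict)
        else founder_probabilities,
        dtype=float,
    )
    if np.any(q < 0):
        raise ValueError("gene-origin probabilities must be non-negative")
    ssq = float((q**2).sum())
    if ssq == 0.0:
        raise ValueError("all founder probabilities are zero")
    return 1.0 / ssq


def effective_ancestors(
    ped: Pedigree, reference=None, max_ancestors: int | None = None
) -> tuple[float, list[tuple[str, float]]]:
    """Greedy marginal-contribution ancestor selection; fa = 1 / sum p_k^2.

    At each round each candidate's marginal contribution is its expected
    contribution to the reference through paths not intercepted by
    previously selected ancestors, times the fraction of its own genome not
    originating from them (ties broken by id).  Selection stops when the
    largest marginal contribution falls below ``MARGINAL_TOL`` or all
    contributing ancestors are taken.
    """
    ref_idx = _reference_indices(ped, reference)
    n = len(ped)
    selected: list[tuple[str, float]] = []
    blocked: set[int] = set()
    limit = max_ancestors or len(ped)
    # candidates: strict ancestors of the reference, plus founders (a
    # reference founder can only be explained by itself; a non-founder
    # reference member is explained through its parents)
    parents = np.concatenate(
        [ped.sire[ref_idx][ped.sire[ref_idx] >= 0], ped.dam[ref_idx][ped.dam[ref_idx] >= 0]]
    )
    eligible = ped.is_founder.copy()
    if len(parents):
        eligible |= ped.ancestors_of(parents)
    while len(selected) < limit:
        w = _raw_contributions(ped, ref_idx, blocked=blocked)
        # fraction of each animal's genome already explained by selected
        # ancestors (downward sweep; selected animals count as source 1)
        g = np.zeros(n)
        for i in range(n):
            if i in blocked:
                g[i] = 1.0
            else:
                acc = 0.0
                if ped.sire[i] >= 0:
                    acc += 0.5 * g[ped.sire[i]]
                if ped.dam[i] >= 0:
                    acc += 0.5 * g[ped.dam[i]]
                g[i] = acc
        w = w * (1.0 - g)
        w[~eligible] = 0.0
        cand = np.flatnonzero(w > MARGINAL_TOL)
        if len(cand) == 0:
            break
        best = min(cand, key=lambda i: (-w[i], ped.ids[i]))  # ties: lexicographic id
        selected.append((ped.ids[best], float(w[best])))
        blocked.add(best)
        if sum(p for _, p in selected) >= 1.0 - MARGINAL_TOL:
            break
    p = np.array([c for _, c in selected])
    fa = 1.0 / float((p**2).sum()) if len(p) else float("nan")
    return fa, selected


def founder_genome_equivalents(
    ped: Pedigree,
    reference=None,
    method: str = "analytic",
    n_reps: int = 10_000,
    seed: int = 0,
) -> float | tuple[float, float]:
    """fg as the inverse of twice the mean reference coancestry.

    ``method="analytic"`` uses the exact indirect-matrix mean;
    ``method="gene_drop"`` Monte-Carlo drops labeled founder alleles down the
    pedigree and returns ``(fg_hat, standard_error)``.
    """
    ref_idx = _reference_indices(ped, reference)
    if method == "analytic":
        C = relatedness.mean_coancestry(ped, ref_idx)
        return 1.0 / (2.0 * C)
    if method != "gene_drop":
        raise ValueError(f"unknown method {method!r}")
    if n_reps < 100:
        raise ValueError("gene_drop needs at least 100 replicates for stability")
    rng = np.random.default_rng(seed)
    n = len(ped)
    pat = np.empty((n, n_reps), dtype=np.int32)
    mat = np.empty((n, n_reps), dtype=np.int32)
    next_allele = 0
    for i in range(n):
        for arr, parent in ((pat, ped.sire[i]), (mat, ped.dam[i])):
            if parent >= 0:
                pick = rng.random(n_reps) < 0.5
                arr[i] = np.where(pick, pat[parent], mat[parent])
            else:
                # unknown slot: a fresh phantom founder with two labeled alleles
                arr[i] = next_allele + (rng.random(n_reps) < 0.5)
                next_allele += 2
    genes = np.concatenate([pat[ref_idx], mat[ref_idx]], axis=0)  # 2|R| x reps
    m = genes.shape[0]
    sim_C = np.empty(n_reps)
    for r in range(n_reps):
        _, counts = np.unique(genes[:, r], return_counts=True)
        sim_C[r] = float(((counts / m) ** 2).sum())
    C_hat = float(sim_C.mean())
    se_C = float(sim_C.std(ddof=1) / np.sqrt(n_reps))
    fg_hat = 1.0 / (2.0 * C_hat)
    se_fg = se_C / (2.0 * C_hat**2)  # delta method
    return fg_hat, se_fg


@dataclass
class DiversityLosses:
    gd: float
    gd_star: float
    total_loss: float        # 1 - GD
    founder_loss: float      # 1 - GD*
    drift_loss: float        # GD* - GD
    nef: float


def diversity_losses(fe: float, fg: float) -> DiversityLosses:
    """GD / GD* decomposition and the effective number of non-founders."""
    if not fg > 0:
        raise ValueError("fg must be positive")
    if fe < fg:
        raise ValueError(f"fe ({fe}) < fg ({fg}) violates fg <= fe; check upstream")
    gd = 1.0 - 1.0 / (2.0 * fg)
    gd_star = 1.0 - 1.0 / (2.0 * fe)
    nef = float("inf") if fe == fg else 1.0 / (1.0 / fg - 1.0 / fe)
    return DiversityLosses(
        gd=gd,
        gd_star=gd_star,
        total_loss=1.0 - gd,
        founder_loss=1.0 - gd_star,
        drift_loss=gd_star - gd,
        nef=nef,
    )


def partition_inbreeding(ped: Pedigree, reference=None, tol: float = 1e-12) -> dict[str, float]:
    """Mean reference inbreeding split into common-ancestor contributions.

    Uses the ``A = T D T'`` decomposition: ``F_i = 0.5 sum_j T_{s_i j}
    T_{d_i j} D_j``, so ancestor ``j``'s share of the mean F is obtained from
    one gene-flow (``T e_j``) sweep per contributing ancestor.  The shares
    sum to the mean inbreeding of the reference.
    """
    ref_idx = _reference_indices(ped, reference)
    n = len(ped)
    F = relatedness.inbreeding(ped)
    D = relatedness._mendelian_variances(ped, F)
    with_parents = [i for i in ref_idx if ped.sire[i] >= 0 and ped.dam[i] >= 0]
    if not with_parents:
        return {}
    sires = np.array([ped.sire[i] for i in with_parents])
    dams = np.array([ped.dam[i] for i in with_parents])
    # candidates: animals that are ancestors of (or equal to) both a sire and a dam
    anc_s = ped.ancestors_of(sires)
    anc_d = ped.ancestors_of(dams)
    out: dict[str, float] = {}
    scale = 0.5 / len(ref_idx)
    for j in np.flatnonzero(anc_s & anc_d):
        u = np.zeros(n)
        u[j] = 1.0
        for i in range(j + 1, n):
            t = 0.0
            if ped.sire[i] >= 0:
                t += 0.5 * u[ped.sire[i]]
            if ped.dam[i] >= 0:
                t += 0.5 * u[ped.dam[i]]
            if t:
                u[i] = t
        contrib = scale * D[j] * float((u[sires] * u[dams]).sum())
        if contrib > tol:
            out[ped.ids[j]] = contrib
    return out


def gene_origin_report(ped: Pedigree, reference=None) -> GeneOriginReport:
    """Full gene-origin accounting for a reference population."""
    n_f, base, actual, q = founder_accounting(ped, reference)
    fe = effective_founders(q)
    fa, marg = effective_ancestors(ped, reference)
    fg = founder_genome_equivalents(ped, reference, method="analytic")
    losses = diversity_losses(fe, fg)
    return GeneOriginReport(
        n_founders=n_f,
        base_population=base,
        actual_base=actual,
        n_ancestors_selected=len(marg),
        fe=fe,
        fa=fa,
        fg=fg,
        nef=losses.nef,
        gd=losses.gd,
        gd_star=losses.gd_star,
        founder_probabilities=q,
        marginal_contributions=marg,
    )
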