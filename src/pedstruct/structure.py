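"""Effective sizes, Wright's fixation indices, Nei distances and UPGMA.

Realized effective population sizes follow from the mean per-generation
rates: ``NeF = 1/(2 dF)`` via inbreeding and ``NeC = 1/(2 dC)`` via pairwise
coancestry.  Their ratio ``S = NeC / NeF`` is the number of equivalent
subpopulations: S > 1 flags substructure, S < 1 flags mixing.

Fixation indices use the coancestry-based definitions: with mean
self-inbreeding ``F``, mean within-subpopulation coancestry ``fw`` and
metapopulation mean coancestry ``fT`` (both including self-pairs, weighting
subpopulations by census size),

    FIS = (F - fw)/(1 - fw),  FST = (fw - fT)/(1 - fT),  FIT = (F - fT)/(1 - fT),

so that (1 - FIT) = (1 - FIS)(1 - FST) holds identically.

Nei's minimum distance between subpopulations is the coancestry analogue
``D_ij = (f_ii + f_jj)/2 - f_ij``; the dendrogram over breeds is built by
UPGMA (arithmetic-average agglomeration) and serialized as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as _upgma_linkage
from scipy.spatial.distance import squareform

from . import relatedness
from .pedigree import Pedigree


def effective_size(mean_rate: float) -> float:
    """Realized Ne = 1/(2 * mean rate of inbreeding or coancestry)."""
    if mean_rate <= 0:
        raise ValueError(
            "non-positive rate: population not losing diversity, Ne undefined"
        )
    return 1.0 / (2.0 * mean_rate)


def equivalent_subpopulations(ne_c: float, ne_f: float) -> float:
    """S = NeC / NeF."""
    if ne_c <= 0 or ne_f <= 0:
        raise ValueError("effective sizes must be positive")
    return ne_c / ne_f


@dataclass
class FStatistics:
    fis: float
    fst: float
    fit: float
    mean_self_inbreeding: float
    mean_within_coancestry: float
    mean_total_coancestry: float


def _subpop_masks(ped: Pedigree, labels, reference) -> dict[str, np.ndarray]:
    lab = np.asarray(labels if labels is not None else ped.breed, dtype=object)
    ref = ped.focal if reference is None else np.asarray(reference, dtype=bool)
    out = {}
    for g in sorted({str(x) for x in lab[ref]}):
        out[g] = ref & (lab == g)
    return {g: m for g, m in out.items() if m.any()}


def _coancestry_means(ped: Pedigree, masks: dict[str, np.ndarray], F: np.ndarray):
    """Within/between mean coancestries via one indirect product per group."""
    groups = list(masks)
    vs = {}
    us = {}
    for g in groups:
        v = np.zeros(len(ped))
        idx = np.flatnonzero(masks[g])
        v[idx] = 1.0 / len(idx)
        vs[g] = v
        us[g] = relatedness.relationship_times(ped, v, F=F)
    fmat = pd.DataFrame(index=groups, columns=groups, dtype=float)
    for i, g in enumerate(groups):
        for h in groups[i:]:
            f = 0.5 * float(vs[g] @ us[h])
            fmat.loc[g, h] = f
            fmat.loc[h, g] = f
    return fmat


def wright_f_statistics(
    ped: Pedigree, labels=None, reference=None
) -> FStatistics:
    """FIS/FST/FIT for a subpopulation assignment (default: breed labels)."""
    masks = _subpop_masks(ped, labels, reference)
    if len(masks) < 2:
        raise ValueError("need at least 2 non-empty subpopulations")
    F = relatedness.inbreeding(ped)
    fmat = _coancestry_means(ped, masks, F)
    sizes = np.array([masks[g].sum() for g in masks], dtype=float)
    wts = sizes / sizes.sum()
    f_within = float(np.sum(wts * np.diag(fmat.to_numpy())))
    f_total = float(wts @ fmat.to_numpy() @ wts)
    all_mask = np.zeros(len(ped), dtype=bool)
    for m in masks.values():
        all_mask |= m
    f_self = float(F[all_mask].mean())
    return FStatistics(
        fis=(f_self - f_within) / (1.0 - f_within),
        fst=(f_within - f_total) / (1.0 - f_total),
        fit=(f_self - f_total) / (1.0 - f_total),
        mean_self_inbreeding=f_self,
        mean_within_coancestry=f_within,
        mean_total_coancestry=f_total,
    )


def nei_minimum_distance(ped: Pedigree, labels=None, reference=None) -> pd.DataFrame:
    """Pairwise Nei minimum distances over subpopulation coancestries."""
    masks = _subpop_masks(ped, labels, reference)
    if len(masks) < 2:
        raise ValueError("need at least 2 non-empty subpopulations")
    F = relatedness.inbreeding(ped)
    fmat = _coancestry_means(ped, masks, F)
    groups = list(fmat.index)
    D = pd.DataFrame(0.0, index=groups, columns=groups)
    for g in groups:
        for h in groups:
            D.loc[g, h] = (fmat.loc[g, g] + fmat.loc[h, h]) / 2.0 - fmat.loc[g, h]
    np.fill_diagonal(D.values, 0.0)
    return D


def upgma_tree(distance_matrix: pd.DataFrame | np.ndarray, labels=None) -> str:
    """UPGMA dendrogram of a distance matrix, as a Newick string.

    The output is ultrametric: every leaf sits at half the joining distance
    of the root.  Branch lengths are differences of merge heights.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        D = distance_matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(distance_matrix, dtype=float)
        if labels is None:
            labels = [f"T{i}" for i in range(D.shape[0])]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    m = D.shape[0]
    if m == 1:
        return f"{labels[0]}:0.0;"
    Z = _upgma_linkage(squareform(D, checks=False))
    heights = {i: 0.0 for i in range(m)}
    newick = {i: str(labels[i]) for i in range(m)}
    for k, (a, b, dist, _) in enumerate(Z):
        a, b = int(a), int(b)
        h = dist / 2.0
        node = m + k
        newick[node] = (
            f"({newick[a]}:{h - heights[a]:.10g},{newick[b]}:{h - heights[b]:.10g})"
        )
        heights[node] = h
    return newick[m + len(Z) - 1] + ";"


@dataclass
class StructureReport:
    ne_f: float
    ne_c: float
    s: float
    f_statistics: FStatistics
    nei_matrix: pd.DataFrame
    newick: str


def structure_report(
    ped: Pedigree, labels=None, reference=None, seed: int = 0
) -> StructureReport:
    """Effective sizes, fixation indices, Nei matrix and UPGMA tree."""
    summary = relatedness.diversity_summary(ped, reference=reference, seed=seed)
    ne_f = effective_size(summary.mean_dF)
    ne_c = effective_size(summary.mean_dC)
    fstats = wright_f_statistics(ped, labels=labels, reference=reference)
    nei = nei_minimum_distance(ped, labels=labels, reference=reference)
    return StructureReport(
        ne_f=ne_f,
        ne_c=ne_c,
        s=equivalent_subpopulations(ne_c, ne_f),
        f_statistics=fstats,
        nei_matrix=nei,
        newick=upgma_tree(nei),
    )
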