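"""Canonical discriminant analysis of per-individual diversity parameters.

The grouping factor is the breed label; the predictors are pedigree-derived
diversity parameters per animal (average relatedness, genetic conservation
index, individual non-random-mating contribution, maximum and complete
generation numbers, offspring count, with inbreeding and equivalent
generations available before the multicollinearity screen).

Pipeline: variance-inflation-factor screen -> optional PCA screen (report
only by default) -> forward stepwise selection on overall Wilks' Lambda ->
canonical functions from the generalized eigenproblem ``B v = lambda W v``
(axes scaled to unit pooled within-group variance), with Bartlett chi-square
tests of Wilks' Lambda, Pillai's trace with its F approximation,
standardized coefficients, discriminant loadings, centroids, Mahalanobis
distances between centroids, linear classification with group-size priors,
exact leave-one-out cross-validation and Press' Q.

Identities maintained throughout: ``Rc_m^2 = lambda_m / (1 + lambda_m)`` and
``Lambda = prod_m 1/(1 + lambda_m)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from . import demography, relatedness
from .pedigree import Pedigree

MEANINGFUL_RC = 0.30        # canonical correlation below which a function is noise
CHI2_CRIT_1DF_01 = stats.chi2.ppf(0.99, 1)   # Press' Q reference value (6.63)
DEFAULT_VIF_THRESHOLD = 4.0
DEFAULT_F_TO_ENTER = 3.84


# ---------------------------------------------------------------------------
# feature assembly


def assemble_features(ped: Pedigree, reference=None) -> tuple[pd.DataFrame, pd.Series]:
    """Per-individual diversity parameters and breed labels for the CDA.

    Columns: F_pct, AR_pct, alpha, GCI, max_generations, complete_generations,
    equivalent_generations, n_offspring.  The individual non-random-mating
    contribution is ``1 - (1 - F_i)/(1 - C_breed)`` with ``C_breed`` the mean
    coancestry of the animal's own breed reference.
    """
    ref = ped.focal if reference is None else np.asarray(reference, dtype=bool)
    idx = np.flatnonzero(ref)
    if len(idx) == 0:
        raise ValueError("empty reference population")
    F = relatedness.inbreeding(ped)
    AR = relatedness.average_relatedness(ped, F=F)
    GCI = relatedness.genetic_conservation_index(ped)
    gens = demography.generation_numbers(ped)
    n_off = demography.offspring_counts(ped)
    breeds = np.asarray(ped.breed, dtype=object)
    c_by_breed = {}
    for b in sorted({str(breeds[i]) for i in idx}):
        mask = ref & (breeds == b)
        c_by_breed[b] = relatedness.mean_coancestry(ped, np.flatnonzero(mask), F=F)
    alpha = np.array(
        [1.0 - (1.0 - F[i]) / (1.0 - c_by_breed[str(breeds[i])]) for i in idx]
    )
    X = pd.DataFrame(
        {
            "F_pct": 100.0 * F[idx],
            "AR_pct": 100.0 * AR[idx],
            "alpha": alpha,
            "GCI": GCI[idx],
            "max_generations": gens["max_generations"].to_numpy()[idx].astype(float),
            "complete_generations": gens["complete_generations"].to_numpy()[idx].astype(float),
            "equivalent_generations": gens["equivalent_generations"].to_numpy()[idx],
            "n_offspring": n_off[idx].astype(float),
        },
        index=[ped.ids[i] for i in idx],
    )
    groups = pd.Series([str(breeds[i]) for i in idx], index=X.index, name="breed")
    return X, groups


# ---------------------------------------------------------------------------
# screens


def vif_screen(X: pd.DataFrame, threshold: float = DEFAULT_VIF_THRESHOLD):
    """Iterative variance-inflation-factor screen.

    Recomputes VIF = 1/(1 - R^2) after each removal; drops the largest
    offender (perfectly collinear columns, VIF = inf, go first) until every
    remaining column passes.  Returns ``(retained, vif_table, removed)``.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF screen needs at least 2 columns")
    cols = list(X.columns)
    removed: list[str] = []

    def vifs(cols: list[str]) -> pd.Series:
        out = {}
        M = X[cols].to_numpy(dtype=float)
        M = M - M.mean(axis=0)
        for j, c in enumerate(cols):
            y = M[:, j]
            Z = np.delete(M, j, axis=1)
            denom = float(y @ y)
            if denom == 0.0:
                out[c] = float("inf")  # constant column
                continue
            coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
            resid = y - Z @ coef
            r2 = 1.0 - float(resid @ resid) / denom
            out[c] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return pd.Series(out)

    table = vifs(cols)
    while len(cols) > 1 and table.max() > threshold:
        worst = table.idxmax()
        cols.remove(worst)
        removed.append(worst)
        table = vifs(cols)
    return cols, table, removed


def pca_screen(X: pd.DataFrame, loading_threshold: float = 0.5):
    """Principal-component loading screen on standardized columns.

    Loadings are eigenvector * sqrt(eigenvalue) of the correlation matrix,
    over components with eigenvalue >= 1 (Kaiser).  Columns whose maximum
    absolute loading falls below the threshold are *flagged*; removal is the
    caller's decision (report-only default).  Returns
    ``(retained, flagged, loadings)``.
    """
    Z = (X - X.mean()) / X.std(ddof=1)
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals >= 1.0
    if not keep.any():
        keep[0] = True
    loadings = pd.DataFrame(
        vecs[:, keep] * np.sqrt(vals[keep]),
        index=X.columns,
        columns=[f"PC{i + 1}" for i in range(int(keep.sum()))],
    )
    max_abs = loadings.abs().max(axis=1)
    flagged = list(max_abs.index[max_abs < loading_threshold])
    retained = [c for c in X.columns if c not in flagged]
    return retained, flagged, loadings


# ---------------------------------------------------------------------------
# scatter matrices and Wilks machinery


def _scatter(X: np.ndarray, groups: np.ndarray):
    """Within-group (W), between-group (B) scatter and group means."""
    labels = np.unique(groups)
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    means = {}
    for g in labels:
        Xg = X[groups == g]
        mg = Xg.mean(axis=0)
        means[g] = mg
        dev = Xg - mg
        W += dev.T @ dev
        dm = (mg - grand)[:, None]
        B += len(Xg) * (dm @ dm.T)
    return W, B, means, grand


def _wilks(X: np.ndarray, groups: np.ndarray) -> float:
    W, B, _, _ = _scatter(X, groups)
    T = W + B
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def stepwise_select(
    X: pd.DataFrame, groups: pd.Series, f_to_enter: float = DEFAULT_F_TO_ENTER
) -> pd.DataFrame:
    """Forward stepwise variable selection minimizing overall Wilks' Lambda.

    At each step the candidate giving the smallest Lambda enters if its
    partial F meets ``f_to_enter``.  Returns the per-step table (variable,
    Lambda, partial F) in entry order; raises if nothing enters at step 1.
    """
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    n = len(X)
    n_groups = len(labels)
    selected: list[str] = []
    rows = []
    lambda_prev = 1.0
    remaining = list(X.columns)
    while remaining:
        best = None
        for c in remaining:
            lam = _wilks(X[selected + [c]].to_numpy(dtype=float), g)
            if best is None or lam < best[1]:
                best = (c, lam)
        c, lam = best
        q = len(selected)
        if lam <= 0:
            partial_f = float("inf")
        else:
            partial_f = ((n - n_groups - q) / (n_groups - 1)) * (lambda_prev / lam - 1.0)
        if partial_f < f_to_enter:
            break
        selected.append(c)
        remaining.remove(c)
        rows.append({"variable": c, "wilks_lambda": lam, "partial_F": partial_f})
        lambda_prev = lam
    if not rows:
        raise ValueError("no variable meets the F-to-enter criterion")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the model


@dataclass
class CdaModel:
    variables: list[str]
    groups: list[str]
    priors: dict[str, float]
    n: int
    eigenvalues: np.ndarray
    canonical_correlations: np.ndarray
    variance_explained: np.ndarray          # eigenvalue shares, sum to 1
    meaningful: np.ndarray                  # Rc >= MEANINGFUL_RC
    wilks: pd.DataFrame                     # per function set: lambda, chi2, df, p
    pillai: dict
    raw_coefficients: pd.DataFrame          # variables x functions
    standardized_coefficients: pd.DataFrame
    loadings: pd.DataFrame                  # pooled within-group correlations
    centroids: pd.DataFrame                 # groups x functions
    group_means: pd.DataFrame
    pooled_cov: np.ndarray
    grand_mean: np.ndarray

    @property
    def wilks_lambda(self) -> float:
        return float(self.wilks["wilks_lambda"].iloc[0])


def fit_cda(
    X: pd.DataFrame, groups: pd.Series, priors: str = "from_group_sizes"
) -> CdaModel:
    """Fit canonical discriminant functions.

    Solves ``B v = lambda W v`` (between/within scatter); axes are scaled so
    the pooled within-group variance of each canonical score is 1.
    """
    g = np.asarray(groups).astype(str)
    labels = [str(x) for x in np.unique(g)]
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    n_groups = len(labels)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    W, B, means, grand = _scatter(Xv, g)
    # singularity check with a helpful message
    diag = np.diag(W)
    if np.any(diag <= 0):
        bad = X.columns[np.argmin(diag)]
        raise ValueError(f"within-group scatter singular: column {bad!r} has no within-group variance")
    try:
        np.linalg.cholesky(W / n)
    except np.linalg.LinAlgError:
        corr = W / np.sqrt(np.outer(diag, diag))
        off = np.abs(corr - np.eye(p))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            f"within-group scatter singular: columns {X.columns[i]!r} and "
            f"{X.columns[j]!r} are collinear"
        ) from None

    m = min(p, n_groups - 1)
    vals, vecs = scipy.linalg.eigh(B, W)     # eigh normalizes v' W v = 1
    order = np.argsort(vals)[::-1][:m]
    lam = np.clip(vals[order], 0.0, None)
    V = vecs[:, order] * np.sqrt(n - n_groups)   # pooled within-variance of scores = 1
    # sign convention: largest-|loading| variable positive per function
    Sw = W / (n - n_groups)
    load = (Sw @ V) / np.sqrt(np.diag(Sw))[:, None]
    for k in range(m):
        if load[np.argmax(np.abs(load[:, k])), k] < 0:
            V[:, k] *= -1
            load[:, k] *= -1

    rc = np.sqrt(lam / (1.0 + lam))
    shares = lam / lam.sum() if lam.sum() > 0 else np.full(m, np.nan)

    # Wilks tests for function sets r..m (Bartlett chi-square)
    rows = []
    for r in range(m):
        lam_set = lam[r:]
        wl = float(np.prod(1.0 / (1.0 + lam_set)))
        chi2 = -(n - 1 - (p + n_groups) / 2.0) * np.log(wl) if wl > 0 else float("inf")
        df = (p - r) * (n_groups - r - 1)
        rows.append(
            {
                "functions": f"{r + 1} through {m}" if r + 1 < m else f"{m}",
                "wilks_lambda": wl,
                "chi_square": chi2,
                "df": df,
                "p_value": float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan"),
            }
        )
    wilks = pd.DataFrame(rows)

    # Pillai trace and its F approximation
    V_trace = float(np.sum(lam / (1.0 + lam)))
    s = min(p, n_groups - 1)
    m_p = (abs(p - (n_groups - 1)) - 1) / 2.0
    n_p = (n - n_groups - p - 1) / 2.0
    df1 = s * (2 * m_p + s + 1)
    df2 = s * (2 * n_p + s + 1)
    f_stat = ((2 * n_p + s + 1) / (2 * m_p + s + 1)) * (V_trace / (s - V_trace)) if s > V_trace else float("inf")
    pillai = {
        "trace": V_trace,
        "F": f_stat,
        "df1": df1,
        "df2": df2,
        "p_value": float(stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0,
    }

    std_coef = V * np.sqrt(np.diag(Sw))[:, None]
    fn = [f"F{k + 1}" for k in range(m)]
    centroids = pd.DataFrame(
        {lab: (means[lab] - grand) @ V for lab in labels}, index=fn
    ).T
    sizes = {lab: int((g == lab).sum()) for lab in labels}
    if priors == "equal":
        pri = {lab: 1.0 / n_groups for lab in labels}
    elif priors == "from_group_sizes":
        pri = {lab: sizes[lab] / n for lab in labels}
    else:
        raise ValueError(f"unknown priors option {priors!r}")
    return CdaModel(
        variables=list(X.columns),
        groups=labels,
        priors=pri,
        n=n,
        eigenvalues=lam,
        canonical_correlations=rc,
        variance_explained=shares,
        meaningful=rc >= MEANINGFUL_RC,
        wilks=wilks,
        pillai=pillai,
        raw_coefficients=pd.DataFrame(V, index=X.columns, columns=fn),
        standardized_coefficients=pd.DataFrame(std_coef, index=X.columns, columns=fn),
        loadings=pd.DataFrame(load, index=X.columns, columns=fn),
        centroids=centroids,
        group_means=pd.DataFrame({lab: means[lab] for lab in labels}, index=X.columns).T,
        pooled_cov=Sw,
        grand_mean=grand,
    )


def mahalanobis_between(model: CdaModel) -> pd.DataFrame:
    """Squared Mahalanobis distances between group centroids.

    Computed in the original variable space with the pooled within-group
    covariance; equals the squared Euclidean distance between centroids in
    the full canonical score space.
    """
    labels = model.groups
    Minv = np.linalg.inv(model.pooled_cov)
    D2 = pd.DataFrame(0.0, index=labels, columns=labels)
    gm = model.group_means
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d = gm.loc[a].to_numpy() - gm.loc[b].to_numpy()
            v = float(d @ Minv @ d)
            D2.loc[a, b] = v
            D2.loc[b, a] = v
    return D2


# ---------------------------------------------------------------------------
# classification


def _discriminant_scores(Xv, means, Sw_inv, priors, labels):
    """Linear (pooled-covariance) classification scores, one column per group."""
    out = np.empty((Xv.shape[0], len(labels)))
    for k, g in enumerate(labels):
        mg = means[g]
        w = Sw_inv @ mg
        out[:, k] = Xv @ w - 0.5 * float(mg @ w) + np.log(priors[g])
    return out


def classify(model: CdaModel, X: pd.DataFrame) -> np.ndarray:
    """Assign each row to the group with the highest linear score."""
    Sw_inv = np.linalg.inv(model.pooled_cov)
    means = {g: model.group_means.loc[g].to_numpy() for g in model.groups}
    sc = _discriminant_scores(X.to_numpy(dtype=float), means, Sw_inv, model.priors, model.groups)
    return np.asarray(model.groups, dtype=object)[np.argmax(sc, axis=1)]


def press_q(n_total: int, n_correct: int, n_groups: int) -> float:
    """Press' Q = (N - nK)^2 / (N (K - 1)): classification vs. chance."""
    if n_groups < 2:
        raise ValueError("Press' Q needs at least 2 groups")
    return (n_total - n_correct * n_groups) ** 2 / (n_total * (n_groups - 1))


@dataclass
class ClassificationReport:
    confusion: pd.DataFrame
    loocv_confusion: pd.DataFrame
    hit_ratio: float
    loocv_hit_ratio: float
    press_q: float                  # on the LOOCV assignments
    press_q_significant: bool       # vs chi2(1df) at 0.01


def _confusion(truth: np.ndarray, pred: np.ndarray, labels: list[str]) -> pd.DataFrame:
    cm = pd.DataFrame(0, index=labels, columns=labels)
    for t, p in zip(truth, pred):
        cm.loc[t, p] += 1
    cm.index.name = "true"
    cm.columns.name = "predicted"
    return cm


def classify_loocv(
    X: pd.DataFrame, groups: pd.Series, priors: str = "from_group_sizes",
    method: str = "auto",
) -> ClassificationReport:
    """Resubstitution and leave-one-out classification with Press' Q.

    ``method="downdate"`` removes each case from the pooled scatter and group
    mean by exact rank-one updates (identical to a full refit up to numerical
    precision); ``"refit"`` refits from scratch per case and is practical for
    small n; ``"auto"`` picks the downdate.
    """
    g = np.asarray(groups).astype(str)
    labels = [str(x) for x in np.unique(g)]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    Xv = X.to_numpy(dtype=float)
    n = len(Xv)
    model = fit_cda(X, groups, priors=priors)
    pred = classify(model, X)
    hit = float((pred == g).mean())

    sizes = {lab: int((g == lab).sum()) for lab in labels}
    if min(sizes.values()) < 2:
        raise ValueError("leave-one-out would empty a group: every group needs >= 2 cases")
    loo_pred = np.empty(n, dtype=object)
    if method == "refit":
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            m_i = fit_cda(X.iloc[keep], groups.iloc[keep], priors=priors)
            loo_pred[i] = classify(m_i, X.iloc[[i]])[0]
    else:
        W, _, means, _ = _scatter(Xv, g)
        for i in range(n):
            gi = g[i]
            ng = sizes[gi]
            x = Xv[i]
            mg = means[gi]
            d = x - mg
            W_i = W - (ng / (ng - 1)) * np.outer(d, d)
            means_i = dict(means)
            means_i[gi] = (ng * mg - x) / (ng - 1)
            Sw_i = W_i / (n - 1 - len(labels))
            if priors == "equal":
                pri = {lab: 1.0 / len(labels) for lab in labels}
            else:
                pri = {lab: (sizes[lab] - (lab == gi)) / (n - 1) for lab in labels}
            sc = _discriminant_scores(
                x[None, :], means_i, np.linalg.inv(Sw_i), pri, labels
            )
            loo_pred[i] = labels[int(np.argmax(sc))]
    loo_hit = float((loo_pred == g).mean())
    q = press_q(n, int((loo_pred == g).sum()), len(labels))
    return ClassificationReport(
        confusion=_confusion(g, pred, labels),
        loocv_confusion=_confusion(g, loo_pred, labels),
        hit_ratio=hit,
        loocv_hit_ratio=loo_hit,
        press_q=q,
        press_q_significant=bool(q > CHI2_CRIT_1DF_01),
    )


def territorial_coordinates(model: CdaModel, X: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Canonical scores per individual plus centroid rows, for plotting.

    Scores are grand-mean centered; the pooled within-group variance of each
    axis is 1 by the fitting convention.
    """
    Xv = X.to_numpy(dtype=float) - model.grand_mean
    scores = Xv @ model.raw_coefficients.to_numpy()
    fn = list(model.raw_coefficients.columns)
    df = pd.DataFrame(scores, columns=fn, index=X.index)
    df["group"] = np.asarray(groups).astype(str)
    df["is_centroid"] = False
    cent = model.centroids.copy()
    cent["group"] = cent.index
    cent["is_centroid"] = True
    cent.index = [f"centroid_{g}" for g in cent["group"]]
    return pd.concat([df, cent], axis=0)
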