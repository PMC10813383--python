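"""Robust PCA, k-means clustering and cluster phenotyping on ilr
coordinates.

Clustering runs on the full 45-dimensional ilr coordinates (Euclidean
distance there is the Aitchison metric on the simplex); PCA is used for
the low-dimensional variance summary and visualisation, not for
pre-reduction.  Cluster labels are oriented so that label 1 is always
the cluster with the higher mean total abundance of the simple glycan
peaks GP1-GP11, which makes labels reproducible across seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.cluster import KMeans
from sklearn.covariance import MinCovDet

import statsmodels.api as sm

from .coda import GP_COLUMNS, clr, ilr, ilr_inverse, pivot_basis
from .inference import bh_adjust, chi_square, mann_whitney
from .traits import TRAIT_NAMES, trait_table

__all__ = [
    "RobustPcaResult",
    "ClusterResult",
    "robust_pca",
    "kmeans_ilr",
    "choose_k_elbow",
    "characterize_clusters",
    "adjusted_outcome_models",
]

SIMPLE_PEAKS = GP_COLUMNS[:11]   # GP1..GP11, the simple-glycan end


@dataclass
class RobustPcaResult:
    eigenvalues: np.ndarray            # all 45, descending
    loadings: np.ndarray               # 45 x k, orthonormal columns
    clr_loadings: np.ndarray           # 46 x k, Psi^T @ loadings
    scores: np.ndarray                 # n x k
    location: np.ndarray               # robust centre, 45-vector
    explained_fraction: np.ndarray     # per retained component
    method: str = "mcd"


@dataclass
class ClusterResult:
    labels: np.ndarray                 # per-subject, in {1..k}
    centroids: np.ndarray              # k x 45 ilr vectors (label order)
    wss: float
    k: int
    seed: int
    wss_curve: dict[int, float] | None = None
    chosen_k: int | None = None
    no_clear_elbow: bool = False
    extra: dict = field(default_factory=dict)


def robust_pca(ilr_matrix, h_fraction: float = 0.75,
               k_components: int = 2, seed: int = 0) -> RobustPcaResult:
    """PCA of a robust (MCD) scatter estimate of the ilr coordinates.

    h_fraction is the MCD subset fraction; h_fraction = 1 gives the
    classical covariance.  Cohorts below 100 subjects fall back to
    classical PCA with a warning.  Explained fractions are eigenvalue
    shares of the (robust) scatter.
    """
    x = np.asarray(ilr_matrix, float)
    n, p = x.shape
    if not (0.5 < h_fraction <= 1.0):
        raise ValueError("h_fraction must lie in (0.5, 1]")
    method = "mcd"
    if n < 100:
        warnings.warn("fewer than 100 subjects: falling back to classical PCA",
                      stacklevel=2)
        method = "classical"
    if method == "classical" or h_fraction == 1.0:
        location = x.mean(axis=0)
        scatter = np.cov(x, rowvar=False)
        method = "classical"
    else:
        mcd = MinCovDet(support_fraction=h_fraction, random_state=seed).fit(x)
        location = mcd.location_
        scatter = mcd.covariance_
    if np.linalg.matrix_rank(scatter) < p:
        raise np.linalg.LinAlgError("singular scatter matrix")
    w, v = np.linalg.eigh(scatter)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    k = min(k_components, p)
    loadings = v[:, :k]
    return RobustPcaResult(
        eigenvalues=w,
        loadings=loadings,
        clr_loadings=pivot_basis(p + 1).T @ loadings,
        scores=(x - location) @ loadings,
        location=location,
        explained_fraction=w[:k] / w.sum(),
        method=method,
    )


def _orient_labels(raw_labels: np.ndarray,
                   centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters so label 1 has the highest mean GP1-11 abundance."""
    comp = ilr_inverse(centers)
    simple_mass = comp[:, :11].sum(axis=1)
    order = np.argsort(simple_mass)[::-1]      # descending simple-glycan mass
    relabel = np.empty_like(order)
    relabel[order] = np.arange(1, len(order) + 1)
    return relabel[raw_labels], centers[order]


def kmeans_ilr(ilr_matrix, k: int, n_init: int = 25, seed: int = 0) -> ClusterResult:
    """K-means (k-means++, Lloyd) on ilr coordinates; best of n_init by WSS.

    Labels are in {1..k}, ordered by decreasing simple-glycan (GP1-11)
    abundance of the back-transformed centroid.
    """
    x = np.asarray(ilr_matrix, float)
    if k < 1 or x.shape[0] <= k:
        raise ValueError("need k >= 1 and more subjects than clusters")
    if k == 1:
        center = x.mean(axis=0, keepdims=True)
        wss = float(np.sum((x - center) ** 2))
        return ClusterResult(np.ones(x.shape[0], dtype=int), center, wss, 1, seed)
    km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                algorithm="lloyd", random_state=seed).fit(x)
    labels, centers = _orient_labels(km.labels_, km.cluster_centers_)
    return ClusterResult(labels, centers, float(km.inertia_), k, seed)


def choose_k_elbow(ilr_matrix, k_max: int = 8, n_init: int = 25,
                   seed: int = 0, flat_threshold: float = 0.01) -> ClusterResult:
    """WSS curve for k = 1..k_max and the elbow choice of k.

    The elbow is the k in {2..k_max-1} maximising the normalised second
    difference (WSS_{k-1} - 2 WSS_k + WSS_{k+1}) / WSS_1.  A maximum
    below ``flat_threshold`` flags a near-linear decline (no clear
    elbow).  The returned ClusterResult holds the fit at the chosen k.
    """
    if k_max < 3:
        raise ValueError("k_max must be at least 3")
    x = np.asarray(ilr_matrix, float)
    fits = {k: kmeans_ilr(x, k, n_init=n_init, seed=seed)
            for k in range(1, k_max + 1)}
    wss = {k: fits[k].wss for k in fits}
    second_diff = {
        k: (wss[k - 1] - 2 * wss[k] + wss[k + 1]) / wss[1]
        for k in range(2, k_max)
    }
    chosen = max(second_diff, key=second_diff.get)
    no_elbow = second_diff[chosen] < flat_threshold
    if no_elbow:
        warnings.warn("near-linear WSS decline: no clear elbow", stacklevel=2)
    res = fits[chosen]
    res.wss_curve = wss
    res.chosen_k = chosen
    res.no_clear_elbow = no_elbow
    res.extra["second_differences"] = second_diff
    return res


def _median_iqr(v: np.ndarray) -> str:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}, {q3:.2f})"


# traits tested on a log-ratio scale within their family; bounded
# fucosylation/oligomannose traits tested on the logit scale
_TRAIT_FAMILY = {
    **{t: "G" for t in ("G0", "G1", "G2", "G3", "G4")},
    **{t: "S" for t in ("S0", "S1", "S2", "S3", "S4")},
    **{t: "A" for t in ("A1", "A2", "A3", "A4")},
    "CF": "bounded", "OF": "bounded", "OM": "bounded",
}


def _trait_transform(traits: pd.DataFrame, name: str) -> np.ndarray:
    """Comparison scale for one trait: clr within its compositional
    family (galactosylation / sialylation / branching [+OM]), logit for
    the bounded fucosylation and oligomannose traits."""
    fam = _TRAIT_FAMILY[name]
    eps = 1e-6
    if fam == "bounded":
        frac = np.clip(traits[name].to_numpy(float) / 100.0, eps, 1 - eps)
        return logit(frac)
    members = {
        "G": ["G0", "G1", "G2", "G3", "G4", "OM"],
        "S": ["S0", "S1", "S2", "S3", "S4"],
        "A": ["A1", "A2", "A3", "A4", "OM"],
    }[fam]
    sub = np.clip(traits[members].to_numpy(float), eps, None)
    return clr(sub)[:, members.index(name)]


def characterize_clusters(cohort: pd.DataFrame, labels,
                          covariates: list[str] | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype clusters: trait medians/IQRs with tests, and covariate
    comparisons, each BH-corrected.

    Returns (trait_table, covariate_table).  Continuous covariates get
    median (IQR) and a Mann-Whitney (2 clusters) / Kruskal-Wallis test;
    categorical covariates get counts (%) and a chi-square test.
    """
    labels = np.asarray(labels)
    ks = np.unique(labels)
    if ks.size < 2:
        raise ValueError("need at least two clusters")
    traits = trait_table(cohort)

    rows, pvals = [], []
    for t in TRAIT_NAMES:
        row = {"trait": t}
        for k in ks:
            row[f"cluster{k}"] = _median_iqr(traits.loc[labels == k, t].to_numpy())
        tv = _trait_transform(traits, t)
        if ks.size == 2:
            p = mann_whitney(tv[labels == ks[0]], tv[labels == ks[1]]).p_value
        else:
            from .inference import kruskal_wallis
            p = kruskal_wallis(*[tv[labels == k] for k in ks]).p_value
        pvals.append(p)
        rows.append(row)
    trait_out = pd.DataFrame(rows)
    trait_out["p"] = pvals
    trait_out["p_adj"] = bh_adjust(pvals)

    if covariates is None:
        reserved = {"subject_id", "age", *GP_COLUMNS}
        covariates = [c for c in cohort.columns if c not in reserved]
        covariates = ["age"] + covariates if "age" in cohort.columns else covariates
    rows, pvals, kept = [], [], []
    for cov in covariates:
        col = cohort[cov]
        if col.nunique(dropna=True) < 2:
            warnings.warn(f"covariate {cov!r} has a single value: skipped",
                          stacklevel=2)
            continue
        row = {"covariate": cov}
        if pd.api.types.is_numeric_dtype(col):
            v = col.to_numpy(float)
            ok = np.isfinite(v)
            for k in ks:
                row[f"cluster{k}"] = _median_iqr(v[ok & (labels == k)])
            if ks.size == 2:
                p = mann_whitney(v[ok & (labels == ks[0])],
                                 v[ok & (labels == ks[1])]).p_value
            else:
                from .inference import kruskal_wallis
                p = kruskal_wallis(*[v[ok & (labels == k)] for k in ks]).p_value
            row["test"] = "Mann-Whitney" if ks.size == 2 else "Kruskal-Wallis"
        else:
            tab = pd.crosstab(col, labels)
            for k in ks:
                counts = tab[k]
                row[f"cluster{k}"] = "; ".join(
                    f"{lvl}: {c} ({100 * c / counts.sum():.1f}%)"
                    for lvl, c in counts.items())
            p = chi_square(tab.to_numpy()).p_value
            row["test"] = "chi-square"
        pvals.append(p)
        rows.append(row)
        kept.append(cov)
    cov_out = pd.DataFrame(rows)
    cov_out["p"] = pvals
    cov_out["p_adj"] = bh_adjust(pvals)
    return trait_out, cov_out


def adjusted_outcome_models(cohort: pd.DataFrame, labels,
                            outcomes: dict[str, str] | None = None
                            ) -> pd.DataFrame:
    """Cluster effects on outcomes, adjusted for age and sex.

    outcomes maps column -> "continuous" or "binary".  Continuous
    outcomes: OLS outcome ~ cluster1 + age + sex, cluster coefficient
    with 95% Wald CI.  Binary outcomes: logistic regression, odds ratio
    with 95% Wald CI.  |coefficient| > 15 is flagged as separation and
    the CI suppressed.
    """
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {1, 2}:
        raise ValueError("adjusted models require binary cluster labels {1,2}")
    if outcomes is None:
        outcomes = {
            "fructosamine": "continuous", "glycated_albumin": "continuous",
            "glucose": "continuous", "AST": "continuous", "GGT": "continuous",
            "T3": "continuous", "gfr": "continuous", "tnf_alpha": "continuous",
        }
        if "comorbidity_count" in cohort.columns:
            outcomes["comorbidity_ge2"] = "binary"
    design = pd.DataFrame({
        "cluster1": (labels == 1).astype(float),
        "age": cohort["age"].to_numpy(float),
        "sex_F": (cohort["sex"] == "F").astype(float).to_numpy(),
    }, index=cohort.index)
    X = sm.add_constant(design)

    rows = []
    for name, kind in outcomes.items():
        if name == "comorbidity_ge2" and name not in cohort.columns:
            y = (cohort["comorbidity_count"].to_numpy(float) >= 2).astype(float)
        else:
            y = cohort[name].to_numpy(float)
            if kind == "binary":
                y = (y != 0).astype(float)
        ok = np.isfinite(y)
        row = {"outcome": name, "kind": kind}
        if kind == "continuous":
            fit = sm.OLS(y[ok], X[ok]).fit()
            coef = fit.params["cluster1"]
            lo, hi = fit.conf_int().loc["cluster1"]
            row.update(estimate=coef, ci_low=lo, ci_high=hi,
                       p=fit.pvalues["cluster1"])
        else:
            fit = sm.Logit(y[ok], X[ok]).fit(disp=0)
            coef = fit.params["cluster1"]
            if abs(coef) > 15:
                row.update(estimate=np.exp(coef), ci_low=np.nan, ci_high=np.nan,
                           p=np.nan, separation=True)
                rows.append(row)
                continue
            lo, hi = fit.conf_int().loc["cluster1"]
            row.update(estimate=np.exp(coef), ci_low=np.exp(lo),
                       ci_high=np.exp(hi), p=fit.pvalues["cluster1"])
        rows.append(row)
    return pd.DataFrame(rows)
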