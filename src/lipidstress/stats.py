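"""Statistical layer: ordination, discriminant VIP scores, and contrasts.

* :func:`pca` — descriptive principal component analysis of log2
  intensity profiles (feature-centred, SVD-based, deterministic sign
  convention).
* :func:`plsda_vip` — PLS-DA (PLS2 on one-hot class membership, with
  autoscaled features) and the cumulative variable-importance-in-
  projection score

      VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

  where p is the number of species, w_a the a-th weight vector and SSY_a
  the Y-variance explained by component a.  The mean of VIP^2 over
  species is exactly 1; species with VIP above a threshold (default 2.0)
  are the discriminant selection.
* :func:`per_species_rm_anova` — one-way repeated-measures ANOVA per
  species (replicates paired across conditions within a cell line), with
  an unpaired one-way fallback for unbalanced designs.  For two
  conditions the F statistic equals the squared paired t statistic.
* :func:`contrast_si` — two-sided t-test (paired, or unpaired Welch) on
  per-sample saturation indices, with star coding at 0.05/0.01/0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io import PeakTable

__all__ = [
    "OrdinationResult",
    "VipResult",
    "ContrastResult",
    "pca",
    "plsda_vip",
    "per_species_rm_anova",
    "contrast_si",
    "significance_stars",
]


@dataclass
class OrdinationResult:
    """PCA scores, per-component explained-variance fractions, loadings."""

    scores: pd.DataFrame  # samples x components
    explained_variance_fraction: np.ndarray
    loadings: pd.DataFrame  # species x components


@dataclass
class VipResult:
    """Per-species VIP scores and the thresholded, ranked selection."""

    vip: pd.Series  # indexed by species, original order
    selected: pd.DataFrame  # species over threshold, sorted descending
    threshold: float
    n_components: int
    ssy: np.ndarray  # Y-variance explained per component
    weights: pd.DataFrame  # species x components


@dataclass
class ContrastResult:
    """A single two-group comparison with its significance coding."""

    cell_line: str
    lipid_class: str
    condition_a: str
    condition_b: str
    test_name: str
    statistic: float
    p_value: float
    alpha: float = 0.05
    degenerate: bool = False
    n_a: int = 0
    n_b: int = 0
    stars: str = field(init=False)
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.stars = significance_stars(self.p_value)
        self.significant = bool(self.p_value <= self.alpha)


def significance_stars(p: float) -> str:
    """Conventional star coding: *** <=0.001, ** <=0.01, * <=0.05."""
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def pca(matrix: pd.DataFrame, n_components: int = 2) -> OrdinationResult:
    """PCA of a species x samples matrix (samples are observations).

    Features are centred (not scaled).  Deterministic up to the fixed
    sign convention: in every component the largest-magnitude loading is
    made positive.
    """
    X = matrix.T.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_components > min(n, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_species)={min(n, p)}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # p x k
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comps = [f"PC{j + 1}" for j in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comps),
        explained_variance_fraction=model.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(loadings, index=matrix.index, columns=comps),
    )


def plsda_vip(
    matrix: pd.DataFrame,
    class_labels: list[str] | pd.Series | np.ndarray,
    n_components: int = 2,
    vip_threshold: float = 2.0,
) -> VipResult:
    """PLS-DA of a species x samples matrix and cumulative VIP scores.

    Class membership is one-hot encoded; features are autoscaled (unit
    variance).  Species with VIP above ``vip_threshold`` are returned
    ranked by descending VIP.
    """
    labels = np.asarray(class_labels)
    X = matrix.T.to_numpy(dtype=float)
    n, p = X.shape
    if labels.shape[0] != n:
        raise ValueError("one label per sample required")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("PLS-DA requires at least 2 classes")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds the rank bound min(n-1, p)={min(n - 1, p)}"
        )

    sd = X.std(axis=0, ddof=1)
    zero_var = matrix.index[sd == 0].tolist()
    if zero_var:
        raise ValueError(f"zero-variance species cannot be autoscaled: {zero_var[:5]}")
    Xs = (X - X.mean(axis=0)) / sd
    Y = (labels[:, None] == groups[None, :]).astype(float)

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, Y)
    W = pls.x_weights_  # p x A, unit-norm columns
    T = pls.x_scores_  # n x A
    Q = pls.y_loadings_  # m x A
    ssy = (T**2).sum(axis=0) * (Q**2).sum(axis=0)  # Y-variance explained per comp
    Wn = W / np.linalg.norm(W, axis=0)
    vip = np.sqrt(p * (Wn**2 @ ssy) / ssy.sum())

    vip_s = pd.Series(vip, index=matrix.index, name="vip")
    selected = (
        vip_s[vip_s > vip_threshold]
        .sort_values(ascending=False)
        .rename_axis("species")
        .reset_index()
    )
    return VipResult(
        vip=vip_s,
        selected=selected,
        threshold=vip_threshold,
        n_components=n_components,
        ssy=ssy,
        weights=pd.DataFrame(W, index=matrix.index, columns=[f"comp{a + 1}" for a in range(n_components)]),
    )


def _rm_anova_balanced(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way repeated-measures ANOVA.

    ``vals`` has shape (species, subjects, conditions); returns (F, p).
    """
    S, n, k = vals.shape
    gm = vals.mean(axis=(1, 2), keepdims=True)
    m_c = vals.mean(axis=1, keepdims=True)
    m_s = vals.mean(axis=2, keepdims=True)
    ss_cond = n * ((m_c - gm) ** 2).sum(axis=(1, 2))
    ss_subj = k * ((m_s - gm) ** 2).sum(axis=(1, 2))
    ss_tot = ((vals - gm) ** 2).sum(axis=(1, 2))
    ss_err = np.maximum(ss_tot - ss_cond - ss_subj, 0.0)
    df_c, df_e = k - 1, (n - 1) * (k - 1)
    tol = 1e-12 * np.maximum(ss_tot, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / df_c) / (ss_err / df_e)
    F = np.where(ss_err <= tol, np.where(ss_cond <= tol, 0.0, np.inf), F)
    p = sps.f.sf(F, df_c, df_e)
    return F, p


def per_species_rm_anova(
    table: PeakTable,
    alpha: float = 0.001,
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Repeated-measures ANOVA across conditions for every species.

    Runs within each cell line, pairing replicates across conditions.
    Values are expected on the log2 scale.  If the pairing is unbalanced
    (not every replicate measured under every condition) the analysis
    falls back to an unpaired one-way ANOVA with a warning recorded in
    ``test_name``.  Raw p-values are flagged at ``alpha`` and accompanied
    by Benjamini-Hochberg q-values per cell line.
    """
    meta = table.sample_meta_frame()
    results = []
    for cell_line, m in meta.groupby("cell_line", sort=True):
        conditions = sorted(m[condition_col].unique())
        if len(conditions) < 2:
            raise ValueError(f"cell line {cell_line}: need >=2 conditions")
        pivot = m.pivot_table(
            index="replicate", columns=condition_col, values="sample_id", aggfunc="count"
        ).fillna(0)
        balanced = (
            pivot.shape[0] >= 2 and (pivot.to_numpy() == 1).all() and pivot.shape[1] == len(conditions)
        )
        vals = table.intensities[m["sample_id"]]
        if balanced:
            reps = sorted(m["replicate"].unique())
            order = [
                m.set_index(["replicate", condition_col])["sample_id"].loc[(r, c)]
                for r in reps
                for c in conditions
            ]
            arr = vals[order].to_numpy(dtype=float).reshape(len(vals), len(reps), len(conditions))
            complete = ~np.isnan(arr).any(axis=(1, 2))
            F = np.full(len(vals), np.nan)
            p = np.full(len(vals), np.nan)
            F[complete], p[complete] = _rm_anova_balanced(arr[complete])
            test_name = "rm_anova"
        else:
            warnings.warn(
                f"cell line {cell_line}: unbalanced replicate/condition pairing; "
                "falling back to unpaired one-way ANOVA",
                stacklevel=2,
            )
            group_cols = [
                m.loc[m[condition_col] == c, "sample_id"].tolist() for c in conditions
            ]
            F = np.full(len(vals), np.nan)
            p = np.full(len(vals), np.nan)
            for i in range(len(vals)):
                samples = [vals.iloc[i][cols].dropna().to_numpy() for cols in group_cols]
                if any(len(s) < 2 for s in samples):
                    continue
                if all(np.ptp(s) == 0 for s in samples):
                    means = [s[0] for s in samples]
                    F[i], p[i] = (0.0, 1.0) if np.ptp(means) == 0 else (np.inf, 0.0)
                else:
                    F[i], p[i] = sps.f_oneway(*samples)
            test_name = "oneway_anova_unpaired_fallback"

        ok = ~np.isnan(p)
        q = np.full(len(vals), np.nan)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        results.append(
            pd.DataFrame(
                {
                    "cell_line": cell_line,
                    "species": vals.index,
                    "statistic": F,
                    "p_value": p,
                    "q_value": q,
                    "significant": p < alpha,
                    "test_name": test_name,
                }
            )
        )
    return pd.concat(results, ignore_index=True)


def contrast_si(
    si_table: pd.DataFrame,
    cell_line: str,
    lipid_class: str,
    condition_pair: tuple[str, str],
    paired: bool = False,
    alpha: float = 0.05,
) -> ContrastResult:
    """Two-sided t-test on per-sample SI values for one class and cell line.

    Unpaired comparisons use Welch's t-test.  Degenerate zero-variance
    groups are resolved exactly: identical constants give p = 1, distinct
    constants p = 0 with the ``degenerate`` flag set, rather than NaN.
    Undefined (NaN) SI values are excluded.
    """
    cond_a, cond_b = condition_pair
    sub = si_table[
        (si_table["cell_line"] == cell_line) & (si_table["lipid_class"] == lipid_class)
    ]
    if sub.empty:
        raise ValueError(f"no SI rows for ({cell_line}, {lipid_class})")
    a_rows = sub[sub["condition"] == cond_a].dropna(subset=["si"])
    b_rows = sub[sub["condition"] == cond_b].dropna(subset=["si"])
    if paired:
        merged = a_rows.merge(b_rows, on="replicate", suffixes=("_a", "_b"))
        if len(merged) < 2:
            raise ValueError(
                f"paired contrast needs >=2 matched replicates, got {len(merged)}"
            )
        a, b = merged["si_a"].to_numpy(), merged["si_b"].to_numpy()
    else:
        a, b = a_rows["si"].to_numpy(), b_rows["si"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"contrast needs >=2 replicates per condition, got {len(a)} and {len(b)}"
            )

    degenerate = False
    if paired:
        d = a - b
        if np.ptp(d) == 0:
            degenerate = d[0] != 0
            stat, p = (0.0, 1.0) if d[0] == 0 else (np.inf * np.sign(d[0]), 0.0)
            test = "paired_t"
        else:
            stat, p = sps.ttest_rel(a, b)
            test = "paired_t"
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            degenerate = a[0] != b[0]
            stat, p = (0.0, 1.0) if a[0] == b[0] else (np.inf * np.sign(a[0] - b[0]), 0.0)
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=False)
        test = "welch_t"
    return ContrastResult(
        cell_line=cell_line,
        lipid_class=lipid_class,
        condition_a=cond_a,
        condition_b=cond_b,
        test_name=test,
        statistic=float(stat),
        p_value=float(p),
        alpha=alpha,
        degenerate=degenerate,
        n_a=len(a),
        n_b=len(b),
    )
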