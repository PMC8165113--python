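"""Variance filtering, projection-score optimisation, PCA, differential
expression and hierarchical clustering.

Differential expression comes in two flavours: a paired (repeated-measures)
t-test of calcified vs nondiseased tissue within patients, and a
tissue-adjusted male-vs-female test on within-grade-centred residuals.
Both report the mean log2 difference, the linear fold change 2^delta, and
Benjamini-Hochberg q-values computed over exactly the genes tested. The
two-stage selection keeps genes that clear the paired test (q < 0.05 and
fold change outside (0.8, 1.2)) and then clear the sex test (q < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, TISSUE_LEVELS

DE_COLUMNS = ("delta_log2", "fc", "t", "p", "q")


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------
# variance filtering and projection score
# ----------------------------------------------------------------------


def variance_rank_filter(
    expr: ExpressionMatrix, keep: int | None = None, threshold: float | None = None
) -> ExpressionMatrix:
    """Retain the genes with the highest across-sample variance.

    Exactly one of ``keep`` (gene count) or ``threshold`` (minimum variance,
    inclusive) must be given. Ties at the boundary are broken by gene id.
    """
    if (keep is None) == (threshold is None):
        raise ValueError("give exactly one of keep= or threshold=")
    if expr.n_genes == 0:
        raise ValueError("empty expression matrix")
    variances = expr.values.var(axis=1, ddof=1)
    if keep is not None:
        if keep > expr.n_genes:
            raise ValueError(f"keep={keep} exceeds n_genes={expr.n_genes}")
        order = sorted(expr.gene_ids, key=lambda g: (-variances[g], g))
        retained = expr.gene_ids[expr.gene_ids.isin(order[:keep])]  # keep matrix order
    else:
        retained = expr.gene_ids[variances >= threshold]
    return expr.subset_genes(retained)


@dataclass
class ProjectionScoreResult:
    """Projection scores over a variance-threshold grid."""

    table: pd.DataFrame  # threshold, n_retained, alpha_obs, alpha_perm, score
    best_threshold: float
    k_components: int
    n_perm: int

    def best_row(self) -> pd.Series:
        return self.table.loc[self.table["score"].idxmax()]


def _variance_fraction_topk(x: np.ndarray, k: int) -> float:
    """Fraction of total variance captured by the first k PCs of the
    row-centred matrix."""
    xc = x - x.mean(axis=1, keepdims=True)
    s = np.linalg.svd(xc, compute_uv=False)
    ev = s**2
    total = ev.sum()
    if total == 0:
        return 0.0
    return float(ev[:k].sum() / total)


def projection_score_optimize(
    expr: ExpressionMatrix,
    k_components: int = 2,
    threshold_grid=None,
    n_perm: int = 20,
    seed: int = 0,
) -> ProjectionScoreResult:
    """Choose a variance-filter threshold by maximising the projection score.

    For each candidate threshold the score is sqrt(alpha_observed) minus the
    permutation mean of sqrt(alpha), where alpha is the fraction of variance
    captured by the first ``k_components`` PCs of the retained, gene-centred
    submatrix, and each permutation shuffles every retained gene's values
    independently across samples. Structure inflates alpha relative to its
    permutation null; pure noise scores near zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    variances = expr.values.var(axis=1, ddof=1)
    if threshold_grid is None:
        qs = np.linspace(0.0, 0.95, 12)
        threshold_grid = np.unique(np.quantile(variances.to_numpy(), qs))
    threshold_grid = np.asarray(list(threshold_grid), dtype=float)
    if threshold_grid.size == 0:
        raise ValueError("threshold grid is empty")

    rng = np.random.default_rng(seed)
    rows = []
    for thr in threshold_grid:
        mask = variances.to_numpy() >= thr
        x = expr.values.to_numpy()[mask]
        if x.shape[0] < 1 or x.shape[1] < 2:
            warnings.warn(f"threshold {thr:g}: retained submatrix too small; skipped")
            continue
        alpha_obs = _variance_fraction_topk(x, k_components)
        perm_vals = np.empty(n_perm)
        for i in range(n_perm):
            perm_vals[i] = np.sqrt(_variance_fraction_topk(rng.permuted(x, axis=1), k_components))
        rows.append(
            {
                "threshold": thr,
                "n_retained": int(mask.sum()),
                "alpha_obs": alpha_obs,
                "sqrt_alpha_perm_mean": perm_vals.mean(),
                "score": np.sqrt(alpha_obs) - perm_vals.mean(),
            }
        )
    if not rows:
        raise ValueError("no usable threshold in grid")
    table = pd.DataFrame(rows)
    best = float(table.loc[table["score"].idxmax(), "threshold"])
    return ProjectionScoreResult(
        table=table, best_threshold=best, k_components=k_components, n_perm=n_perm
    )


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray


def pca_embed(expr: ExpressionMatrix, k: int = 2) -> PCAResult:
    """Gene-centred PCA of the samples; reproducible up to component sign."""
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if k > min(expr.n_genes, expr.n_samples):
        raise ValueError(f"k={k} exceeds matrix rank bound")
    x = expr.values.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    ev = s**2
    total = ev.sum()
    frac = ev / total if total > 0 else np.zeros_like(ev)
    coords = (vt[:k].T * s[:k])[:, :k]
    return PCAResult(
        coordinates=pd.DataFrame(
            coords, index=expr.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        variance_fraction=frac[:k],
    )


# ----------------------------------------------------------------------
# differential expression
# ----------------------------------------------------------------------


@dataclass
class DEResult:
    """Per-gene effect sizes and (adjusted) significance for one contrast."""

    table: pd.DataFrame  # columns DE_COLUMNS, indexed by gene id
    contrast: str
    n_units: int  # patients (paired) or samples (two-group)

    def significant(self, q_threshold: float = 0.05) -> pd.Index:
        return self.table.index[self.table["q"] < q_threshold]


def _finalize_de(gene_ids, delta, t, p, contrast, n_units) -> DEResult:
    table = pd.DataFrame(
        {
            "delta_log2": delta,
            "fc": np.exp2(delta),
            "t": t,
            "p": p,
            "q": bh_qvalues(p),
        },
        index=gene_ids,
    )
    return DEResult(table=table, contrast=contrast, n_units=n_units)


def paired_de(
    expr: ExpressionMatrix, contrast: tuple[str, str] = ("calcified", "nondiseased")
) -> DEResult:
    """Paired t-test of ``contrast[0]`` minus ``contrast[1]`` within patients.

    Patients lacking either tissue sample are dropped with a warning. Genes
    with zero difference variance get t = 0, p = 1 when the mean difference
    is also zero (t = +/-inf, p = 0 otherwise).
    """
    hi, lo = contrast
    lookup = expr.sample_lookup()
    hi_cols, lo_cols = [], []
    for patient in dict.fromkeys(expr.samples["patient_id"]):
        sh, sl = lookup.get((patient, hi)), lookup.get((patient, lo))
        if sh is None or sl is None:
            warnings.warn(f"patient {patient} lacks a {hi} or {lo} sample; dropped")
            continue
        hi_cols.append(sh)
        lo_cols.append(sl)
    n = len(hi_cols)
    if n < 2:
        raise ValueError("need >= 2 patients with both tissue samples")

    d = expr.values[hi_cols].to_numpy() - expr.values[lo_cols].to_numpy()
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    t[zero_sd & (mean == 0)] = 0.0
    t[zero_sd & (mean > 0)] = np.inf
    t[zero_sd & (mean < 0)] = -np.inf
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return _finalize_de(expr.gene_ids, mean, t, p, f"{hi} vs {lo} (paired)", n)


def sex_de_adjusted(expr: ExpressionMatrix, equal_var: bool = True) -> DEResult:
    """Male-vs-female t-test after removing per-tissue-grade means.

    Each gene is centred within every tissue grade (the adjustment), then a
    two-sample t-test (pooled variance by default, Welch with
    ``equal_var=False``) compares male vs female residuals. Delta is the
    male minus female mean residual.
    """
    tissue = expr.samples["tissue"]
    sex = expr.samples["sex"]
    for grade in sorted(tissue.unique()):
        present = set(sex[tissue == grade].unique())
        if present != {"M", "F"}:
            raise ValueError(f"tissue grade {grade!r} lacks one sex entirely")

    x = expr.values.to_numpy().astype(float)
    resid = np.empty_like(x)
    for grade in tissue.unique():
        cols = (tissue == grade).to_numpy()
        resid[:, cols] = x[:, cols] - x[:, cols].mean(axis=1, keepdims=True)

    male = (sex == "M").to_numpy()
    xm, xf = resid[:, male], resid[:, ~male]
    n1, n2 = xm.shape[1], xf.shape[1]
    delta = xm.mean(axis=1) - xf.mean(axis=1)
    if equal_var:
        v1 = xm.var(axis=1, ddof=1)
        v2 = xf.var(axis=1, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
        zero = sp2 == 0
        t[zero & (delta == 0)] = 0.0
        t[zero & (delta > 0)] = np.inf
        t[zero & (delta < 0)] = -np.inf
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
    else:
        res = stats.ttest_ind(xm, xf, axis=1, equal_var=False)
        t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
        bad = ~np.isfinite(t)
        t[bad & (delta == 0)] = 0.0
        p[np.isnan(p)] = 1.0
    return _finalize_de(expr.gene_ids, delta, t, p, "male vs female (tissue-adjusted)", n1 + n2)


def fc_filter(de: DEResult, low: float = 0.8, high: float = 1.2) -> pd.Index:
    """Genes whose linear fold change falls outside the open interval
    (low, high); 2^delta values equal to a bound are retained."""
    if low >= high:
        raise ValueError("low must be < high")
    fc = de.table["fc"]
    return de.table.index[(fc <= low) | (fc >= high)]


@dataclass
class SexDESelection:
    genes: pd.Index
    stage1: DEResult
    stage1_survivors: pd.Index
    stage2: DEResult | None


def select_sex_de_genes(
    expr: ExpressionMatrix,
    q_threshold: float = 0.05,
    fc_bounds: tuple[float, float] = (0.8, 1.2),
    use_q: bool = True,
    use_fc: bool = True,
    equal_var: bool = True,
) -> SexDESelection:
    """Two-stage selection of sex-differential genes.

    Stage 1 keeps genes differential between calcified and nondiseased
    tissue (paired test, q below threshold, fold change outside the bounds).
    Stage 2 re-tests the survivors for a male-female difference adjusted for
    tissue grade and keeps those with q below threshold.
    """
    stage1 = paired_de(expr)
    survivors = stage1.table.index
    if use_q:
        survivors = survivors.intersection(stage1.significant(q_threshold))
    if use_fc:
        survivors = survivors.intersection(fc_filter(stage1, *fc_bounds))
    survivors = stage1.table.index[stage1.table.index.isin(survivors)]
    if len(survivors) == 0:
        return SexDESelection(
            genes=pd.Index([]), stage1=stage1, stage1_survivors=survivors, stage2=None
        )
    stage2 = sex_de_adjusted(expr.subset_genes(survivors), equal_var=equal_var)
    selected = stage2.significant(q_threshold)
    return SexDESelection(genes=selected, stage1=stage1, stage1_survivors=survivors, stage2=stage2)


# ----------------------------------------------------------------------
# hierarchical clustering
# ----------------------------------------------------------------------


def correlation_distance_matrix(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; constant rows are maximally
    distant (distance 2) from everything, with a warning."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant item(s): correlation undefined, set maximally distant")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    d = 1.0 - c
    d[np.isnan(d)] = 2.0
    d = np.clip(d, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def hclust_order(expr: ExpressionMatrix, method: str = "average") -> dict:
    """Average-linkage clustering on 1 - Pearson distance.

    Returns leaf orders for both genes and samples as
    ``{"genes": [...], "samples": [...]}``.
    """
    out = {}
    for axis, ids, mat in (
        ("genes", expr.gene_ids, expr.values.to_numpy()),
        ("samples", expr.sample_ids, expr.values.to_numpy().T),
    ):
        if len(ids) < 2:
            raise ValueError(f"need >= 2 {axis} to cluster")
        d = correlation_distance_matrix(mat)
        z = linkage(squareform(d, checks=False), method=method)
        out[axis] = [ids[i] for i in leaves_list(z)]
    return out
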