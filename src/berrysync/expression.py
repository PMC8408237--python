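"""Count normalisation and the time-course / pairwise expression stack.

The stack mirrors a standard bulk RNA-seq stage analysis: CPM/RPKM with an
RPKM > 1 expression filter (per genotype x stage condition mean), TMM
between-sample normalisation, a quadratic time-course gate (stages G, P, S
coded 0, 1, 2; genotype main effects and interactions against a control
genotype; global F-test with BH-FDR and an R^2 >= 0.7 goodness gate),
24 unit-step model profiles merged into four shape clusters (A up, B down,
C up-peak at P, D down-peak at P), and a simplified negative-binomial Wald
test for the S-versus-G pairwise contrast.

The time-course and pairwise engines are deliberately simplified
re-implementations of the corresponding third-party tools: they reproduce
the decision rules (thresholds, profile merging, FDR) rather than any
specific package's internals, and their reports say so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compute_cpm",
    "compute_rpkm",
    "condition_means",
    "rpkm_filter",
    "tmm_factors",
    "effective_library_sizes",
    "timecourse_test",
    "MODEL_PROFILES",
    "profile_cluster",
    "pairwise_de",
    "concordance_sets",
    "sample_overview",
]

ENGINE_NOTE = "simplified re-implementation"

_STAGE_CODE = {"G": 0.0, "P": 1.0, "S": 2.0}


# ---------------------------------------------------------------------------
# normalisation


def compute_cpm(counts: pd.DataFrame, library_sizes=None, tmm=None) -> pd.DataFrame:
    """Counts per million.  Without TMM factors every column sums to 1e6."""
    libs = counts.sum(axis=0) if library_sizes is None else pd.Series(library_sizes, index=counts.columns)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    if tmm is not None:
        libs = libs * pd.Series(tmm, index=counts.columns)
    return counts.div(libs, axis=1) * 1e6


def compute_rpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
                 library_sizes=None, tmm=None) -> pd.DataFrame:
    """Reads per kilobase per million: RPKM = CPM x 1e3 / length_bp."""
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    return compute_cpm(counts, library_sizes, tmm).div(lengths, axis=0) * 1e3


def condition_means(values: pd.DataFrame, sample_info: pd.DataFrame,
                    by=("genotype", "stage")) -> pd.DataFrame:
    """Per-gene means over experimental conditions (genotype x stage)."""
    info = sample_info.set_index("sample_id").loc[values.columns]
    key = info[list(by)].astype(str).agg("|".join, axis=1)
    return values.T.groupby(key.to_numpy()).mean().T


def rpkm_filter(counts: pd.DataFrame, gene_lengths: pd.Series,
                sample_info: pd.DataFrame, min_rpkm: float = 1.0) -> pd.Index:
    """Expressed genes: RPKM > min_rpkm in at least one condition mean."""
    rpkm = compute_rpkm(counts, gene_lengths)
    means = condition_means(rpkm, sample_info)
    return counts.index[(means > min_rpkm).any(axis=1)]


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3,
                sum_trim: float = 0.05) -> pd.Series:
    """Trimmed mean of M-values normalisation factors.

    30% two-sided trim on M (log ratios), 5% on A (average log
    abundance); precision weights from the delta method; the reference is
    the sample whose upper-quartile (of counts/library) is closest to the
    mean upper-quartile.  Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >=2 samples")
    libs = counts.sum(axis=0).to_numpy(dtype=float)
    if (libs <= 0).any():
        raise ValueError("all-zero sample")
    mat = counts.to_numpy(dtype=float)
    props = mat / libs
    uq = np.array([np.quantile(props[:, j][mat[:, j] > 0], 0.75) if (mat[:, j] > 0).any() else 0.0
                   for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(mat.shape[1])
    yr, nr = props[:, ref], mat[:, ref]
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        ys, ns = props[:, j], mat[:, j]
        keep = (ys > 0) & (yr > 0)
        if keep.sum() == 0:
            continue
        m = np.log2(ys[keep] / yr[keep])
        a = 0.5 * np.log2(ys[keep] * yr[keep])
        w = (libs[j] - ns[keep]) / (libs[j] * ns[keep]) + (libs[ref] - nr[keep]) / (libs[ref] * nr[keep])
        n = m.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        rank_m = stats.rankdata(m, method="ordinal")
        rank_a = stats.rankdata(a, method="ordinal")
        trimmed = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if trimmed.sum() == 0 or w[trimmed].sum() == 0:
            continue
        inv_w = 1.0 / w[trimmed]
        factors[j] = 2.0 ** (np.sum(inv_w * m[trimmed]) / np.sum(inv_w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def effective_library_sizes(counts: pd.DataFrame, tmm: pd.Series | None = None) -> pd.Series:
    libs = counts.sum(axis=0)
    if tmm is None:
        tmm = tmm_factors(counts)
    return libs * tmm


# ---------------------------------------------------------------------------
# time-course gate


def _design_matrix(sample_info: pd.DataFrame, control_genotype: str):
    info = sample_info.copy()
    missing = set(info["stage"]) - set(_STAGE_CODE)
    if missing:
        raise ValueError(f"unknown stages: {sorted(missing)}")
    t = info["stage"].map(_STAGE_CODE).to_numpy()
    genotypes = sorted(info["genotype"].unique())
    if control_genotype not in genotypes:
        raise ValueError(f"control genotype {control_genotype!r} not in sample sheet")
    others = [g for g in genotypes if g != control_genotype]
    cols = [np.ones_like(t), t, t**2]
    names = ["intercept", "t", "t2"]
    for g in others:
        dummy = (info["genotype"] == g).to_numpy(dtype=float)
        cols += [dummy, dummy * t, dummy * t**2]
        names += [f"g[{g}]", f"g[{g}]:t", f"g[{g}]:t2"]
    return np.column_stack(cols), names


def timecourse_test(
    log_expr: pd.DataFrame,
    sample_info: pd.DataFrame,
    control_genotype: str,
    alpha: float = 0.05,
    rsq_min: float = 0.7,
) -> pd.DataFrame:
    """Quadratic time-course gate over stages (coded 0/1/2).

    Per gene, OLS of log2(CPM+1) on time, time^2 and genotype main/interaction
    terms against the control genotype; a global F-test against the
    intercept-only model, BH-FDR across genes, and a model R^2 gate.  The
    significant set is {fdr < alpha and R^2 >= rsq_min}.
    """
    info = sample_info.set_index("sample_id").loc[log_expr.columns].reset_index()
    if info["stage"].nunique() < 3:
        raise ValueError("time-course test needs >=3 timepoints")
    x, names = _design_matrix(info, control_genotype)
    n, p = x.shape
    if n <= p:
        raise ValueError("design is rank deficient (too few samples)")
    y = log_expr.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sse = (resid**2).sum(axis=0)
    sst = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    ok = sst > 0
    r2 = np.full(y.shape[1], np.nan)
    r2[ok] = 1.0 - sse[ok] / sst[ok]
    df_model, df_resid = p - 1, n - p
    f = np.full(y.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        f[ok] = ((sst[ok] - sse[ok]) / df_model) / (sse[ok] / df_resid)
    pvals = np.full(y.shape[1], np.nan)
    pvals[ok] = stats.f.sf(f[ok], df_model, df_resid)
    if (~ok).any():
        warnings.warn(f"timecourse_test: {int((~ok).sum())} zero-variance genes skipped")
    fdr = np.full_like(pvals, np.nan)
    fdr[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "p_value": pvals,
            "fdr": fdr,
            "r_squared": np.clip(r2, 0.0, 1.0),
            "significant": (fdr < alpha) & (r2 >= rsq_min),
        },
        index=log_expr.index,
    )
    out.attrs["engine"] = ENGINE_NOTE
    out.attrs["design_columns"] = names
    out.attrs["scale"] = "log2(CPM+1), TMM-normalised"
    return out


# ---------------------------------------------------------------------------
# model profiles


def _make_profiles():
    profiles = {}
    pid = 0
    for d1 in range(-2, 3):
        for d2 in range(-2, 3):
            if d1 == 0 and d2 == 0:
                continue
            pid += 1
            vec = np.array([0.0, d1, d1 + d2])
            vec = vec - vec.mean()
            if d1 >= 0 and d2 >= 0:
                shape = "A"  # monotone increasing
            elif d1 <= 0 and d2 <= 0:
                shape = "B"  # monotone decreasing
            elif d1 > 0 and d2 < 0:
                shape = "C"  # up-peak at P
            else:
                shape = "D"  # down-peak at P
            profiles[pid] = (vec, shape)
    return profiles


#: The 24 unit-step model profiles: stage deltas (d1, d2) on {-2..2}^2
#: minus the flat (0, 0), mean-centred, with their merged shape cluster.
MODEL_PROFILES: dict[int, tuple[np.ndarray, str]] = _make_profiles()


def profile_cluster(log_expr: pd.DataFrame, sample_info: pd.DataFrame,
                    genes=None) -> pd.DataFrame:
    """Assign each gene to the best-correlated model profile.

    Stage means are computed per genotype on the log scale, mean-centred
    within genotype (so expression level cannot drive the clustering) and
    averaged across genotypes; the gene goes to the profile with maximal
    Pearson correlation, and profiles merge into shape clusters A-D.
    Zero-variance genes are left unassigned.
    """
    if genes is not None:
        log_expr = log_expr.loc[genes]
    info = sample_info.set_index("sample_id").loc[log_expr.columns]
    stages = ["G", "P", "S"]
    centred = []
    for _, sub in info.groupby("genotype"):
        cols = sub.index
        means = np.column_stack([
            log_expr[cols[sub.loc[cols, "stage"] == s]].mean(axis=1) for s in stages
        ])
        centred.append(means - means.mean(axis=1, keepdims=True))
    x = np.mean(centred, axis=0)  # genes x 3, mean-centred

    pids = sorted(MODEL_PROFILES)
    pmat = np.stack([MODEL_PROFILES[pid][0] for pid in pids])  # 24 x 3
    pnorm = pmat / np.linalg.norm(pmat, axis=1, keepdims=True)
    xnorm = np.linalg.norm(x, axis=1)
    rows = []
    for gi, gene in enumerate(log_expr.index):
        if xnorm[gi] <= 1e-12:
            rows.append({"gene_id": gene, "model_profile_id": -1,
                         "merged_cluster": "none", "correlation": np.nan})
            continue
        r = pnorm @ (x[gi] / xnorm[gi])
        best = int(np.argmax(r))
        pid = pids[best]
        rows.append({"gene_id": gene, "model_profile_id": pid,
                     "merged_cluster": MODEL_PROFILES[pid][1],
                     "correlation": float(r[best])})
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# pairwise differential expression (S vs G), simplified NB Wald test


def _dispersion_trend(mean_, disp):
    """Fit disp ~ a + b/mean and return the trend evaluated at each mean."""
    keep = mean_ > 0
    x = 1.0 / mean_[keep]
    y = disp[keep]
    if keep.sum() >= 10:
        b, a = np.polyfit(x, y, 1)
        trend = a + b / np.maximum(mean_, 1e-8)
    else:
        trend = np.full_like(mean_, float(np.median(disp[keep])) if keep.any() else 0.1)
    return np.clip(trend, 1e-4, 10.0)


def pairwise_de(
    counts: pd.DataFrame,
    sample_info: pd.DataFrame,
    genotype: str,
    stage_a: str = "G",
    stage_b: str = "S",
    gene_lengths: pd.Series | None = None,
    min_rpkm: float = 1.0,
    alpha: float = 0.05,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Simplified NB Wald test for the S-versus-G contrast in one genotype.

    Normalised counts (TMM effective library sizes), per-gene
    method-of-moments dispersion shrunk toward a mean-dispersion trend,
    Wald test on the log fold change, BH-FDR.  Genes are pre-filtered to
    RPKM > ``min_rpkm`` in at least one condition when lengths are given;
    all-zero genes are always dropped.
    """
    info = sample_info.set_index("sample_id")
    cols_a = [s for s in counts.columns if info.loc[s, "genotype"] == genotype
              and info.loc[s, "stage"] == stage_a]
    cols_b = [s for s in counts.columns if info.loc[s, "genotype"] == genotype
              and info.loc[s, "stage"] == stage_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("pairwise DE needs >=2 replicates per group")
    sub = counts[cols_a + cols_b]
    if gene_lengths is not None:
        keep = rpkm_filter(counts, gene_lengths, sample_info.reset_index()
                           if "sample_id" not in sample_info.columns else sample_info,
                           min_rpkm=min_rpkm)
        sub = sub.loc[sub.index.intersection(keep)]
    sub = sub.loc[sub.sum(axis=1) > 0]

    tmm = tmm_factors(counts)[cols_a + cols_b]
    eff = counts[cols_a + cols_b].sum(axis=0) * tmm
    size = (eff / np.exp(np.mean(np.log(eff)))).to_numpy()
    norm = sub.to_numpy(dtype=float) / size

    na, nb = len(cols_a), len(cols_b)
    ya, yb = norm[:, :na], norm[:, na:]
    ma, mb = ya.mean(axis=1), yb.mean(axis=1)
    va = ya.var(axis=1, ddof=1)
    vb = yb.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        da = (va - ma) / ma**2
        db = (vb - mb) / mb**2
    disp_mom = np.clip(np.nanmean(np.column_stack([da, db]), axis=1), 1e-4, 10.0)
    mean_all = norm.mean(axis=1)
    trend = _dispersion_trend(mean_all, disp_mom)
    n_resid = (na - 1) + (nb - 1)
    disp = (n_resid * disp_mom + prior_df * trend) / (n_resid + prior_df)

    pseudo = 0.5
    lfc_ln = np.log(mb + pseudo) - np.log(ma + pseudo)
    se = np.sqrt((1.0 / na) * (1.0 / (ma + pseudo) + disp)
                 + (1.0 / nb) * (1.0 / (mb + pseudo) + disp))
    z = lfc_ln / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2_fold_change": lfc_ln / np.log(2.0),
            "p_value": pvals,
            "fdr": fdr,
            "direction": np.where(lfc_ln > 0, "up", "down"),
            "mean_norm_a": ma,
            "mean_norm_b": mb,
            "significant": fdr < alpha,
        },
        index=sub.index,
    )
    out.attrs["engine"] = ENGINE_NOTE
    out.attrs["contrast"] = f"{stage_b} vs {stage_a} ({genotype})"
    return out


def concordance_sets(de_by_genotype: dict) -> dict:
    """Common up/down and discordant genes across genotype DE lists.

    Input: genotype -> DE frame with ``significant`` and ``direction``.
    A gene significant in every list with one direction everywhere is
    common; significant everywhere with mixed directions is discordant.
    """
    if len(de_by_genotype) < 2:
        raise ValueError("need >=2 genotype DE lists")
    sig_dirs = []
    for frame in de_by_genotype.values():
        sig = frame.loc[frame["significant"].astype(bool)]
        sig_dirs.append(sig["direction"])
    common = set(sig_dirs[0].index)
    for s in sig_dirs[1:]:
        common &= set(s.index)
    up, down, discordant = set(), set(), set()
    for gene in common:
        dirs = {s.loc[gene] for s in sig_dirs}
        if dirs == {"up"}:
            up.add(gene)
        elif dirs == {"down"}:
            down.add(gene)
        else:
            discordant.add(gene)
    return {
        "common_up": sorted(up),
        "common_down": sorted(down),
        "discordant": sorted(discordant),
        "counts": {"common_up": len(up), "common_down": len(down),
                   "discordant": len(discordant)},
    }


# ---------------------------------------------------------------------------
# sample overview


@dataclass
class SampleOverview:
    pca_coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray
    linkage: np.ndarray
    sample_order: list


def sample_overview(log_expr: pd.DataFrame, n_top: int = 500,
                    n_components: int = 2) -> SampleOverview:
    """PCA + correlation-distance average-linkage dendrogram of samples.

    Input is variance-stabilised expression (log2(CPM+1)); the PCA uses
    the ``n_top`` highest-variance genes, gene-centred.
    """
    if log_expr.shape[1] < 3:
        raise ValueError("need >=3 samples")
    var = log_expr.var(axis=1)
    top = var.sort_values(ascending=False).index[: min(n_top, len(var))]
    x = log_expr.loc[top].to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    from sklearn.decomposition import PCA

    n_comp = min(n_components, min(x.T.shape) - 1)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(x.T)
    pca_df = pd.DataFrame(coords, index=log_expr.columns,
                          columns=[f"PC{i + 1}" for i in range(n_comp)])
    dist = pdist(log_expr.to_numpy(dtype=float).T, metric="correlation")
    dist = np.clip(dist, 0.0, None)  # duplicated samples can give -0.0
    link = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(link)
    return SampleOverview(
        pca_coordinates=pca_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        linkage=link,
        sample_order=[log_expr.columns[i] for i in order],
    )
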