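"""Per-feature univariate statistics under a nested random-effects model.

Each feature Y_ijk (genotype i, biological sample j within genotype,
subsample k within sample) follows

    Y_ijk = mu + geno_i + sample(geno)_ij + e_ijk,

with the genotype effect fixed, the sample effect random (variance s2_s) and
residual variance s2_e.  Because subsamples enter only through their sample
mean, the genotype F-test is carried out on per-sample means against the
sample-within-genotype stratum (denominator df = total samples - genotypes);
with balanced subsample counts this coincides exactly with the REML mixed-
model test.  Multiple comparisons use Tukey-Kramer (valid for unequal group
sizes), summarized as compact letter groups; a one-degree contrast compares
the wild type with the pooled transgenic genotypes.  Outliers are screened
once, before fitting, on externally studentized within-sample residuals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spectra import ID_COLUMNS

__all__ = [
    "FeatureFit", "remove_outliers", "fit_feature", "analyze_features",
    "subset_rerun", "compact_letters",
]

DEFAULT_OUTLIER_THRESHOLD = 2.5
DEFAULT_ALPHA = 0.05


@dataclass
class FeatureFit:
    """Fit summary for one feature: the row format of a results table."""

    feature: str
    genotypes: list[str]
    means: dict[str, float]
    letters: dict[str, str]
    n_samples: dict[str, int]
    sem: float
    f_stat: float
    p_value: float
    df: tuple[int, int]
    pairwise_p: dict[tuple[str, str], float]
    contrast_p: float
    contrast_estimate: float
    shapiro_p: float
    sigma2_sample: float
    sigma2_resid: float
    removed: list[tuple] = field(default_factory=list)
    degenerate: bool = False


def _sample_means(df: pd.DataFrame, feature: str) -> pd.DataFrame:
    if feature not in df.columns:
        raise KeyError(f"no feature named {feature!r}")
    sub = df[ID_COLUMNS + [feature]].dropna(subset=[feature])
    g = sub.groupby(["genotype", "sample_id"], sort=True)[feature]
    out = g.agg(["mean", "count"]).reset_index()
    return out


def remove_outliers(df: pd.DataFrame, feature: str,
                    threshold: float = DEFAULT_OUTLIER_THRESHOLD
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass screen on externally studentized within-sample residuals.

    The residual of observation ijk is its deviation from its own sample
    mean; the scale estimate excludes the observation itself (leave-one-out).
    Observations with |t| > threshold are removed.  Returns (kept, removed),
    both with the original row order.
    """
    if feature not in df.columns:
        raise KeyError(f"no feature named {feature!r}")
    y = df[feature].to_numpy(dtype=float)
    sample = df["genotype"].astype(str) + "\x00" + df["sample_id"].astype(str)
    means = pd.Series(y).groupby(sample.values).transform("mean").to_numpy()
    counts = pd.Series(y).groupby(sample.values).transform("count").to_numpy()
    valid = np.isfinite(y) & (counts >= 2)
    r = np.where(valid, y - means, 0.0)
    h = np.where(counts >= 2, 1.0 / counts, 0.0)
    ss = float(np.sum(r[valid] ** 2))
    dof = int(np.sum(valid) - len(np.unique(sample.values[valid]))) if valid.any() else 0
    t = np.zeros_like(y)
    if dof > 1 and ss > 0:
        denom_var = np.maximum((ss - r ** 2 / (1.0 - h)) / (dof - 1), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(valid & (r != 0),
                         r / np.sqrt(np.maximum(denom_var * (1.0 - h), 1e-300)), 0.0)
    keep = np.abs(t) <= threshold
    return df.loc[keep].copy(), df.loc[~keep].copy()


def compact_letters(groups: list[str], means: dict[str, float],
                    pairwise_p: dict[tuple[str, str], float],
                    alpha: float = DEFAULT_ALPHA) -> dict[str, str]:
    """Compact letter display: two groups share a letter iff their adjusted
    p-value is >= alpha.

    Letters are assigned to the maximal cliques of the not-significantly-
    different graph, ordered by descending clique mean ('a' = highest).
    """
    def nsd(a: str, b: str) -> bool:
        p = pairwise_p.get((a, b), pairwise_p.get((b, a), 1.0))
        return not (p < alpha)

    cliques = []
    for size in range(len(groups), 0, -1):
        for combo in itertools.combinations(groups, size):
            if all(nsd(a, b) for a, b in itertools.combinations(combo, 2)):
                cs = set(combo)
                if not any(cs <= c for c in cliques):
                    cliques.append(cs)
    cliques.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in sorted(clique, key=lambda g: -means[g]):
            letters[g] += letter
    return letters


def fit_feature(df: pd.DataFrame, feature: str, wt_label: str = "WT",
                alpha: float = DEFAULT_ALPHA) -> FeatureFit:
    """Fit the nested model to one feature and summarize it table-style.

    Expects outliers to have been screened already (see remove_outliers /
    analyze_features).
    """
    sm = _sample_means(df, feature)
    genotypes = sorted(sm["genotype"].unique(), key=lambda g: (g != wt_label, g))
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    m = {g: sm.loc[sm.genotype == g, "mean"].to_numpy() for g in genotypes}
    n = {g: len(m[g]) for g in genotypes}
    means = {g: float(np.mean(m[g])) for g in genotypes}
    k = len(genotypes)
    N = sum(n.values())
    df_b, df_e = k - 1, N - k
    all_means = np.concatenate([m[g] for g in genotypes])
    grand = float(np.mean(all_means))
    ss_b = sum(n[g] * (means[g] - grand) ** 2 for g in genotypes)
    ss_w = sum(float(np.sum((m[g] - means[g]) ** 2)) for g in genotypes)

    # residual variance within samples (subsample stratum), for reporting
    sub = df[ID_COLUMNS + [feature]].dropna(subset=[feature])
    obs = sub[feature].to_numpy(dtype=float)
    key = sub["genotype"].astype(str) + "\x00" + sub["sample_id"].astype(str)
    smean = pd.Series(obs).groupby(key.values).transform("mean").to_numpy()
    counts = sub.groupby(key.values)[feature].transform("count").to_numpy()
    resid = obs - smean
    df_r = int(np.sum(counts >= 2) - len(np.unique(key.values[counts >= 2]))) \
        if (counts >= 2).any() else 0
    sigma2_e = float(np.sum(resid[counts >= 2] ** 2) / df_r) if df_r > 0 else float("nan")
    per_sample = sub.groupby(key.values)[feature].count().to_numpy()
    b_h = len(per_sample) / float(np.sum(1.0 / per_sample))  # harmonic mean subsamples

    degenerate = df_e <= 0 or (ss_w <= 1e-300 and ss_b <= 1e-300)
    if degenerate:
        mse = float("nan")
        f_stat = p_f = float("nan")
        pairwise = {pair: float("nan")
                    for pair in itertools.combinations(genotypes, 2)}
        letters = {g: "" for g in genotypes}
        contrast_p = contrast_est = float("nan")
        sem = float("nan")
    else:
        mse = ss_w / df_e
        if mse <= 1e-300:
            f_stat, p_f = float("inf"), 0.0
        else:
            f_stat = (ss_b / df_b) / mse
            p_f = float(sps.f.sf(f_stat, df_b, df_e))
        pairwise = {}
        for a, b in itertools.combinations(genotypes, 2):
            se = math.sqrt(mse / 2.0 * (1.0 / n[a] + 1.0 / n[b])) if mse > 0 else 0.0
            if se == 0:
                pairwise[(a, b)] = 1.0 if means[a] == means[b] else 0.0
            else:
                q = abs(means[a] - means[b]) / se
                pairwise[(a, b)] = float(sps.studentized_range.sf(q, k, df_e))
        letters = compact_letters(genotypes, means, pairwise, alpha)
        sem = math.sqrt(mse / min(n.values()))
        others = [g for g in genotypes if g != wt_label]
        if wt_label in genotypes and others:
            contrast_est = means[wt_label] - float(np.mean([means[g] for g in others]))
            var_c = mse * (1.0 / n[wt_label]
                           + sum(1.0 / n[g] for g in others) / len(others) ** 2)
            if var_c > 0:
                t = contrast_est / math.sqrt(var_c)
                contrast_p = float(2 * sps.t.sf(abs(t), df_e))
            else:
                contrast_p = float("nan")
        else:
            contrast_est = contrast_p = float("nan")

    sigma2_s = max(0.0, (ss_w / df_e if df_e > 0 else float("nan"))
                   - (sigma2_e / b_h if df_r > 0 else 0.0)) if df_e > 0 else float("nan")
    ok = resid[counts >= 2]
    if ok.size >= 3 and np.ptp(ok) > 0:
        shapiro_p = float(sps.shapiro(ok).pvalue)
    else:
        shapiro_p = float("nan")
    return FeatureFit(
        feature=feature, genotypes=genotypes, means=means, letters=letters,
        n_samples=n, sem=sem, f_stat=f_stat, p_value=p_f, df=(df_b, df_e),
        pairwise_p=pairwise, contrast_p=contrast_p, contrast_estimate=contrast_est,
        shapiro_p=shapiro_p, sigma2_sample=sigma2_s, sigma2_resid=sigma2_e,
        degenerate=degenerate,
    )


def _fit_to_row(fit: FeatureFit) -> dict:
    row: dict = {"feature": fit.feature}
    for g in fit.genotypes:
        row[g] = fit.means[g]
        row[f"{g}_letter"] = fit.letters[g]
    row.update(SEM=fit.sem, F=fit.f_stat, p=fit.p_value,
               contrast_p=fit.contrast_p, shapiro_p=fit.shapiro_p,
               n_removed=len(fit.removed), degenerate=fit.degenerate)
    return row


def analyze_features(ft: pd.DataFrame, features: list[str] | None = None,
                     wt_label: str = "WT", alpha: float = DEFAULT_ALPHA,
                     outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD
                     ) -> tuple[pd.DataFrame, dict[str, FeatureFit]]:
    """Outlier screen + nested-model fit for every feature column.

    Returns a results table mirroring the classical layout (genotype means
    with letters, SEM, F-test p, WT-vs-transgenic contrast p, residual
    normality p) and the per-feature fit objects.
    """
    if features is None:
        features = [c for c in ft.columns if c not in ID_COLUMNS]
    fits: dict[str, FeatureFit] = {}
    rows = []
    for feat in features:
        kept, removed = remove_outliers(ft, feat, outlier_threshold)
        fit = fit_feature(kept, feat, wt_label=wt_label, alpha=alpha)
        fit.removed = [tuple(r) for r in removed[ID_COLUMNS].itertuples(index=False)]
        fits[feat] = fit
        rows.append(_fit_to_row(fit))
    return pd.DataFrame(rows), fits


def subset_rerun(ft: pd.DataFrame, keep_samples: list[str], **kwargs
                 ) -> tuple[pd.DataFrame, dict[str, FeatureFit]]:
    """Re-run the whole univariate pipeline on a subset of biological samples.

    Used to emulate small-population re-analyses (e.g. keeping only two
    replicates per genotype to show how significance degrades).
    """
    keep = set(keep_samples)
    missing = keep - set(ft["sample_id"])
    if missing:
        raise ValueError(f"unknown sample ids {sorted(missing)}")
    sub = ft[ft["sample_id"].isin(keep)]
    if sub.empty:
        raise ValueError("empty subset")
    if sub["genotype"].nunique() < 2:
        raise ValueError("subset must retain at least two genotypes")
    return analyze_features(sub, **kwargs)
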