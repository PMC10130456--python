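"""PCA on the standardized mediator matrix and nonparametric group tests.

The multivariate view decomposes the sample x analyte Z-score matrix by
principal components and works on the 2nd/3rd component plane, where
case-control separation is typically visible once the dominant overall-
abundance axis (PC1) is set aside. Group differences per analyte are
assessed nonparametrically: Kruskal-Wallis across the six
(group x trimester) subgroups with Dunn's post-test for within-group
trimester contrasts, and Mann-Whitney for HC-vs-COVID at each trimester.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .cohort import Cohort, SubgroupKey, TRIMESTERS
from .signatures import ZMatrix


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance ratios.

    Components are numbered from 1. The sign of each component is fixed so
    that its largest-magnitude loading is positive, which makes the
    decomposition deterministic. ``mean_`` holds the column means removed
    before decomposition, so ``scores @ loadings.T + mean_`` restores the
    input matrix when all components are kept.
    """

    scores: pd.DataFrame      # samples x components
    loadings: pd.DataFrame    # analytes x components
    explained_variance_ratio: np.ndarray
    mean_: pd.Series
    meta: pd.DataFrame        # aligned to scores rows


def run_pca(z: ZMatrix, complete_case: bool = True) -> PCAResult:
    """Principal component analysis of the Z-score matrix.

    Rows with any missing value are dropped when ``complete_case`` (PCA has
    no native missing-value handling); zero-variance analytes are dropped
    with a warning. All components are retained.
    """
    values = z.values
    meta = z.meta
    if complete_case:
        keep = ~values.isna().any(axis=1)
        values = values[keep]
        meta = meta[keep.to_numpy()]
    elif values.isna().any().any():
        raise ValueError("matrix contains missing values; use complete_case=True")
    if len(values) < 3:
        raise ValueError(f"need >=3 complete samples for PCA, have {len(values)}")
    sd = values.std(ddof=1)
    if (sd == 0).any():
        dropped = list(sd.index[sd == 0])
        warnings.warn(f"dropping zero-variance analyte(s): {dropped}")
        values = values.drop(columns=dropped)
    pca = PCA(n_components=min(values.shape), svd_solver="full")
    raw_scores = pca.fit_transform(values.to_numpy())
    comps = pca.components_  # (k, p)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] *= -1
            raw_scores[:, k] *= -1
    names = [f"PC{i + 1}" for i in range(comps.shape[0])]
    scores = pd.DataFrame(raw_scores, index=values.index, columns=names)
    loadings = pd.DataFrame(comps.T, index=values.columns, columns=names)
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=pca.explained_variance_ratio_,
                     mean_=pd.Series(pca.mean_, index=values.columns),
                     meta=meta.copy())


@dataclass
class Projection:
    """PC2/PC3 coordinates, subgroup centroids and separation indices."""

    coordinates: pd.DataFrame  # per sample: PC2, PC3, group, trimester
    centroids: pd.DataFrame    # per subgroup label: PC2, PC3
    separation: pd.DataFrame   # per trimester pairing: index + spreads


def pc23_projection(result: PCAResult, components: tuple[int, int] = (2, 3),
                    ) -> Projection:
    """Project samples on two components and score HC/COVID separation.

    The separation index per trimester pairing is the distance between the
    HC and COVID centroids divided by the mean within-subgroup spread
    (mean distance of samples to their own centroid). Values well above 1
    indicate subgroups that cluster apart on this plane.
    """
    names = [f"PC{c}" for c in components]
    missing = [n for n in names if n not in result.scores.columns]
    if missing:
        raise ValueError(f"result lacks component(s) {missing}; "
                         f"only {result.scores.shape[1]} components available")
    coords = result.scores[names].copy()
    coords["group"] = result.meta["group"].to_numpy()
    coords["trimester"] = result.meta["trimester"].to_numpy()

    centroids = coords.groupby(["group", "trimester"])[names].mean()
    centroids.index = [f"{g}_t{t}" for g, t in centroids.index]

    rows = []
    for t in TRIMESTERS:
        sub = coords[coords["trimester"] == t]
        hc = sub[sub["group"] == "HC"][names].to_numpy()
        cv = sub[sub["group"] == "COVID"][names].to_numpy()
        if len(hc) == 0 or len(cv) == 0:
            continue
        c_hc, c_cv = hc.mean(axis=0), cv.mean(axis=0)
        spread_hc = np.linalg.norm(hc - c_hc, axis=1).mean() if len(hc) > 1 else np.nan
        spread_cv = np.linalg.norm(cv - c_cv, axis=1).mean() if len(cv) > 1 else np.nan
        spread = np.nanmean([spread_hc, spread_cv])
        dist = float(np.linalg.norm(c_hc - c_cv))
        rows.append({"trimester": t, "centroid_distance": dist,
                     "mean_within_spread": float(spread),
                     "separation_index": dist / spread if spread > 0 else np.inf})
    return Projection(coordinates=coords, centroids=centroids,
                      separation=pd.DataFrame(rows))


def loading_vectors(result: PCAResult, components: tuple[int, int] = (2, 3),
                    centroids: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-analyte loading vectors on two components, for biplot rendering.

    Reports each analyte's loading coordinates, vector magnitude and — when
    subgroup centroids are supplied — the centroid direction it best aligns
    with (cosine similarity). Zero loadings are flagged as unalignable.
    """
    names = [f"PC{c}" for c in components]
    vectors = result.loadings[names].copy()
    vectors["magnitude"] = np.linalg.norm(vectors[names].to_numpy(), axis=1)
    if centroids is not None:
        cent = centroids[names] if set(names) <= set(centroids.columns) else centroids
        cnorm = np.linalg.norm(cent.to_numpy(), axis=1)
        best, cosine = [], []
        for _, row in vectors.iterrows():
            v = row[names].to_numpy(dtype=float)
            if row["magnitude"] == 0 or not np.any(cnorm > 0):
                best.append(None)
                cosine.append(np.nan)
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                cos = (cent.to_numpy() @ v) / (cnorm * row["magnitude"])
            cos = np.where(cnorm > 0, cos, -np.inf)
            i = int(np.argmax(cos))
            best.append(cent.index[i])
            cosine.append(float(cos[i]))
        vectors["aligned_centroid"] = best
        vectors["cosine"] = cosine
    vectors.index.name = "analyte"
    return vectors


# --- univariate nonparametric comparisons --------------------------------

#: total-N limit under which Kruskal-Wallis p-values are computed by full
#: permutation enumeration rather than the chi-square approximation
EXACT_KW_MAX_N = 9


@dataclass
class GroupTestResult:
    analyte: str
    kruskal_statistic: float
    kruskal_p: float
    dunn: pd.DataFrame         # within-group trimester contrasts
    mannwhitney: pd.DataFrame  # HC-vs-COVID per trimester
    intragroup_letters: dict[tuple[str, int], str]
    asterisks: dict[int, bool]


def _kruskal_exact_p(groups: list[np.ndarray], observed_h: float) -> float:
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        arranged = pooled[list(perm)]
        parts, start = [], 0
        for s in sizes:
            parts.append(arranged[start:start + s])
            start += s
        h = stats.kruskal(*parts).statistic
        count += h >= observed_h - 1e-12
        total += 1
    return count / total


def _dunn_contrasts(samples: dict[tuple[str, int], np.ndarray],
                    contrasts: list[tuple[tuple[str, int], tuple[str, int]]],
                    adjust: str | None = "bonferroni",
                    n_family: int = 3) -> pd.DataFrame:
    """Dunn's post-test on the pooled ranking of all subgroups."""
    keys = list(samples)
    pooled = np.concatenate([samples[k] for k in keys])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    mean_rank: dict[tuple[str, int], float] = {}
    start = 0
    for k in keys:
        size = len(samples[k])
        mean_rank[k] = ranks[start:start + size].mean()
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n - 1)))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for k1, k2 in contrasts:
        se = np.sqrt(var_base * (1.0 / len(samples[k1]) + 1.0 / len(samples[k2])))
        z = (mean_rank[k1] - mean_rank[k2]) / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if not np.isnan(z) else np.nan
        if adjust == "bonferroni" and not np.isnan(p):
            p = min(1.0, p * n_family)
        rows.append({"group": k1[0], "trimester_a": k1[1], "trimester_b": k2[1],
                     "z": z, "p_adjusted": p})
    return pd.DataFrame(rows)


def group_comparisons(cohort: Cohort, analyte: str, alpha: float = 0.05,
                      dunn_adjust: str | None = "bonferroni",
                      min_n: int = 3) -> GroupTestResult:
    """Nonparametric comparisons for one analyte across the six subgroups.

    Kruskal-Wallis over every subgroup with >= ``min_n`` non-missing
    values; Dunn's post-test (pooled-rank z with tie correction, Bonferroni
    over the three within-group trimester contrasts by default) for
    intragroup trajectories; two-sided Mann-Whitney (exact for small
    tie-free samples) for HC vs COVID per trimester. Undersized subgroups
    are skipped with a warning. Figure-style markers are returned: letters
    a/b/c for significant intragroup contrasts against trimesters 1/2/3,
    an asterisk per trimester with a significant HC/COVID difference.
    """
    samples: dict[tuple[str, int], np.ndarray] = {}
    for group in ("HC", "COVID"):
        for t in TRIMESTERS:
            vals = np.array([
                s.concentrations.get(analyte, np.nan)
                for s in cohort.subgroup(SubgroupKey(group, t))], dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) >= min_n:
                samples[(group, t)] = vals
            else:
                warnings.warn(f"subgroup {group} t{t} has {len(vals)} values "
                              f"for {analyte}; skipped (min_n={min_n})")
    if len(samples) < 2:
        raise ValueError(f"fewer than two usable subgroups for {analyte}")

    groups = list(samples.values())
    kw = stats.kruskal(*groups)
    kw_p = float(kw.pvalue)
    if sum(map(len, groups)) <= EXACT_KW_MAX_N:
        kw_p = _kruskal_exact_p(groups, float(kw.statistic))

    contrasts = []
    for group in ("HC", "COVID"):
        for t1, t2 in itertools.combinations(TRIMESTERS, 2):
            if (group, t1) in samples and (group, t2) in samples:
                contrasts.append(((group, t1), (group, t2)))
    dunn = _dunn_contrasts(samples, contrasts, adjust=dunn_adjust)

    mw_rows = []
    asterisks: dict[int, bool] = {}
    for t in TRIMESTERS:
        if ("HC", t) not in samples or ("COVID", t) not in samples:
            continue
        hc, cv = samples[("HC", t)], samples[("COVID", t)]
        ties = len(np.unique(np.concatenate([hc, cv]))) < len(hc) + len(cv)
        method = "exact" if (max(len(hc), len(cv)) <= 8 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(hc, cv, alternative="two-sided", method=method)
        mw_rows.append({"trimester": t, "U": float(res.statistic),
                        "p": float(res.pvalue), "method": method})
        asterisks[t] = bool(res.pvalue < alpha)
    mannwhitney = pd.DataFrame(mw_rows)

    letters: dict[tuple[str, int], str] = {k: "" for k in samples}
    letter_of = {1: "a", 2: "b", 3: "c"}
    for _, row in dunn.iterrows():
        if row["p_adjusted"] < alpha:
            k1 = (row["group"], int(row["trimester_a"]))
            k2 = (row["group"], int(row["trimester_b"]))
            letters[k2] += letter_of[int(row["trimester_a"])]
            letters[k1] += letter_of[int(row["trimester_b"])]
    letters = {k: "".join(sorted(set(v))) for k, v in letters.items()}

    return GroupTestResult(analyte=analyte, kruskal_statistic=float(kw.statistic),
                           kruskal_p=kw_p, dunn=dunn, mannwhitney=mannwhitney,
                           intragroup_letters=letters, asterisks=asterisks)
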