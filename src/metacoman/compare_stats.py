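"""Two-condition comparative statistics on abundance profiles.

Differential expression is a per-feature two-sided Wilcoxon rank-sum test
(exact when both groups are small and tie-free, otherwise the normal
approximation with tie correction), Benjamini-Hochberg adjusted across
the features of one system, with a default FDR cutoff of 0.10. Fold
change is log2((mean_B + eps) / (mean_A + eps)) with a scale-adaptive
pseudocount. The "most varied" feature set is either every FDR-significant
feature or, when none passes, the 50 largest up- plus 50 largest
down-regulated features by fold change. Sample ordination uses classical
(metric) MDS on Bray-Curtis dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io_tab import SampleMetadata
from .profiling import AbundanceProfile

DEFAULT_FDR = 0.10
EXACT_GROUP_LIMIT = 10  # exact enumeration when both group sizes are at most this


@dataclass
class MostVariedSet:
    features: list[str]
    selection_mode: str  # "fdr_significant" | "top_fold_change"


def rank_sum_p(a: np.ndarray, b: np.ndarray, exact_limit: int = EXACT_GROUP_LIMIT) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact (full enumeration of rank assignments) when both group sizes are
    at most ``exact_limit`` and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction. Two
    identical constant groups give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and max(len(a), len(b)) <= exact_limit) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def default_pseudocount(profile: AbundanceProfile) -> float:
    """Half the smallest nonzero relative abundance in the profile."""
    values = profile.data.to_numpy()
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return 1e-12
    return float(nonzero.min() / 2.0)


def wilcoxon_de(
    profile: AbundanceProfile,
    meta: SampleMetadata,
    fdr_cutoff: float = DEFAULT_FDR,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-feature differential expression between the two conditions.

    Returns a frame indexed by feature with columns mean_a, mean_b,
    log2_fc, p_value, fdr, direction. Condition A is the reference
    (``meta.conditions[0]``); direction is "up" when condition B is higher.
    """
    if not 0 < fdr_cutoff < 1:
        raise ValueError("fdr_cutoff must be in (0, 1)")
    cond_a, cond_b = meta.conditions
    samples_a = [s for s in meta.samples_of(cond_a) if s in profile.samples]
    samples_b = [s for s in meta.samples_of(cond_b) if s in profile.samples]
    if not samples_a or not samples_b:
        raise ValueError("each condition needs at least one profiled sample")
    eps = default_pseudocount(profile) if pseudocount is None else pseudocount
    mat_a = profile.data[samples_a].to_numpy()
    mat_b = profile.data[samples_b].to_numpy()
    mean_a = mat_a.mean(axis=1)
    mean_b = mat_b.mean(axis=1)
    log2_fc = np.log2((mean_b + eps) / (mean_a + eps))
    pvals = np.array(
        [rank_sum_p(mat_a[i], mat_b[i]) for i in range(len(profile.features))]
    )
    fdr = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])
    direction = np.where(log2_fc > 0, "up", np.where(log2_fc < 0, "down", "none"))
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": log2_fc,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
        },
        index=profile.features.copy(),
    )
    out.index.name = "feature"
    return out


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def select_most_varied(
    de: pd.DataFrame,
    fdr_cutoff: float = DEFAULT_FDR,
    top_n: int = 50,
) -> MostVariedSet:
    """FDR-significant features, or the top fold-change features when none pass.

    In top-fold-change mode up to ``top_n`` features with the largest
    positive and up to ``top_n`` with the most negative log2 fold change
    are taken; ties on |log2_fc| are broken by smaller raw p, then feature
    id.
    """
    if de.empty:
        raise ValueError("empty differential-expression table")
    significant = de[de["fdr"] < fdr_cutoff]
    if len(significant):
        ordered = significant.assign(_id=significant.index.astype(str)).sort_values(
            ["fdr", "p_value", "_id"], kind="mergesort"
        )
        return MostVariedSet(list(ordered.index), "fdr_significant")
    ranked = de.assign(
        _abs_fc=de["log2_fc"].abs(), _id=de.index.astype(str)
    ).sort_values(
        ["_abs_fc", "p_value", "_id"], ascending=[False, True, True], kind="mergesort"
    )
    up = ranked[ranked["log2_fc"] > 0].head(top_n)
    down = ranked[ranked["log2_fc"] < 0].head(top_n)
    return MostVariedSet(list(up.index) + list(down.index), "top_fold_change")


def mds_ordination(
    profile: AbundanceProfile,
    dissimilarity: str = "braycurtis",
    k: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (metric) MDS of the samples.

    Builds the sample x sample dissimilarity matrix (Bray-Curtis by
    default, any scipy pdist metric accepted), double-centres the squared
    dissimilarities and eigendecomposes. Coordinates along axes with
    non-positive eigenvalues are zero. Axis signs are fixed by making the
    largest-magnitude loading on each axis positive, so the embedding is
    fully deterministic.

    Returns (coords: sample x k DataFrame, eigenvalues: length-k array).
    """
    samples = list(profile.samples)
    n = len(samples)
    if n < 3:
        raise ValueError("MDS needs at least 3 samples")
    X = profile.data.to_numpy().T  # samples x features
    D = squareform(pdist(X, metric=dissimilarity))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:k]
    vals = eigval[order]
    coords = np.zeros((n, k))
    for j, (lam, idx) in enumerate(zip(vals, order)):
        if lam > 1e-12:
            axis = eigvec[:, idx] * np.sqrt(lam)
            pivot = int(np.argmax(np.abs(axis)))
            if axis[pivot] < 0:
                axis = -axis
            coords[:, j] = axis
    frame = pd.DataFrame(
        coords, index=pd.Index(samples, name="sample"), columns=[f"MDS{j+1}" for j in range(k)]
    )
    return frame, vals
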