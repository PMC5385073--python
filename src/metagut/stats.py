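"""Diversity, ordination and group statistics for abundance profiles.

The conventions follow common practice in shotgun-metagenome studies:

* alpha diversity is the Shannon index in nats on the (renormalized) profile
  row; richness is the number of detected genes, optionally after seeded
  downsampling to a common depth;
* Chao1 and the incidence-based coverage estimator (ICE) extrapolate total
  richness from rare-feature frequencies;
* ordination is classical metric scaling (PCoA) of Bray-Curtis distances on
  square-root transformed abundances (Euclidean-after-sqrt available);
* two-group comparisons use the two-sided Wilcoxon rank-sum test (exact for
  small tie-free samples, mid-rank normal approximation otherwise) with
  Hommel or Benjamini-Hochberg correction across features, and the signed
  percentage effect size (mean_i - mean_j) / mean_j * 100;
* PERMANOVA partitions the squared distance matrix among/within groups and
  derives its p-value from seeded label permutations;
* the reporter z-score aggregates per-KO signed z-values over a functional
  module and standardizes against seeded same-size random KO sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

from .errors import (
    EmptySampleError,
    InvalidInputError,
    MissingFeatureError,
    UndefinedEffectError,
)
from .quantify import AbundanceProfile, CountTable


# ------------------------------------------------------------------ alpha
def shannon(profile: AbundanceProfile | pd.DataFrame) -> pd.Series:
    """Per-sample Shannon index H = -sum p ln p (nats), rows renormalized."""
    data = profile.data if isinstance(profile, AbundanceProfile) else profile
    values = data.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    if (totals == 0).any():
        bad = data.index[totals == 0].tolist()
        raise EmptySampleError(f"all-zero sample rows: {bad}")
    p = values / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return pd.Series(terms.sum(axis=1), index=data.index, name="shannon")


def gene_count(
    counts: CountTable,
    depth: int | None = None,
    seed: int | None = None,
) -> pd.Series:
    """Number of genes with at least one copy per sample.

    With ``depth`` set, reads are first downsampled without replacement to
    that common depth (samples below the depth keep all their reads).
    """
    frame = counts.counts
    if depth is None:
        return (frame >= 1).sum(axis=0).rename("gene_count")
    rng = np.random.default_rng(seed)
    out = {}
    for sample in frame.columns:
        x = frame[sample].to_numpy()
        total = int(x.sum())
        if total <= depth:
            out[sample] = int((x >= 1).sum())
            continue
        sub = rng.multivariate_hypergeometric(x, depth)
        out[sample] = int((sub >= 1).sum())
    return pd.Series(out, name="gene_count")


def chao1(s_obs: int, f1: int, f2: int) -> float:
    """Chao1 richness: S_obs + F1^2 / (2 F2); bias-corrected form when F2 = 0."""
    if min(s_obs, f1, f2) < 0:
        raise InvalidInputError("frequency counts must be non-negative")
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)


def chao1_from_counts(counts: Sequence[int]) -> float:
    x = np.asarray(counts)
    if (x < 0).any():
        raise InvalidInputError("counts must be non-negative")
    return chao1(int((x > 0).sum()), int((x == 1).sum()), int((x == 2).sum()))


def ice(incidence: np.ndarray | pd.DataFrame, rare_cutoff: int = 10) -> float:
    """Incidence-based coverage estimator of total richness.

    ``incidence`` is a features x samples presence/absence matrix.  Features
    found in <= ``rare_cutoff`` samples form the infrequent group; coverage is
    estimated from uniques and the estimator adds a coefficient-of-variation
    correction (the standard ICE of Lee & Chao as used by EstimateS).
    """
    inc = (np.asarray(incidence) > 0).astype(int)
    if inc.ndim != 2:
        raise InvalidInputError("incidence must be a 2-D matrix")
    freq = inc.sum(axis=1)
    s_obs = int((freq > 0).sum())
    infreq = (freq > 0) & (freq <= rare_cutoff)
    s_freq = int((freq > rare_cutoff).sum())
    s_infreq = int(infreq.sum())
    if s_infreq == 0:
        return float(s_obs)
    n_infreq = int(freq[infreq].sum())
    q1 = int((freq == 1).sum())
    if q1 == n_infreq:
        # all infrequent features are uniques; coverage undefined -> Chao2-style fallback
        return s_freq + s_infreq + q1 * (q1 - 1) / 2.0
    c_ice = 1.0 - q1 / n_infreq
    m_infreq = int((inc[infreq].sum(axis=0) > 0).sum())
    if m_infreq > 1:
        sum_jj = sum(j * (j - 1) * int((freq == j).sum()) for j in range(1, rare_cutoff + 1))
        gamma2 = max(
            (s_infreq / c_ice) * (m_infreq / (m_infreq - 1)) * sum_jj / (n_infreq * (n_infreq - 1))
            - 1.0,
            0.0,
        )
    else:
        gamma2 = 0.0
    return s_freq + s_infreq / c_ice + (q1 / c_ice) * gamma2


def rarefaction(
    counts: CountTable,
    depths: Sequence[int],
    reps: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean detected richness per sample over seeded subsamples at each depth."""
    rng = np.random.default_rng(seed)
    rows = {}
    for sample in counts.samples:
        x = counts.counts[sample].to_numpy()
        total = int(x.sum())
        means = []
        for depth in depths:
            if depth >= total:
                means.append(float((x >= 1).sum()))
                continue
            richness = [
                int((rng.multivariate_hypergeometric(x, depth) >= 1).sum()) for _ in range(reps)
            ]
            means.append(float(np.mean(richness)))
        rows[sample] = means
    return pd.DataFrame(rows, index=pd.Index(depths, name="depth")).T


def sorensen_dice(presence_a: Iterable, presence_b: Iterable) -> float:
    """Sorensen-Dice similarity 2|A&B| / (|A| + |B|); 0 when both sets empty."""
    a, b = set(presence_a), set(presence_b)
    if not a and not b:
        return 0.0
    return 2.0 * len(a & b) / (len(a) + len(b))


# --------------------------------------------------------------- ordination
@dataclass
class OrdinationResult:
    """PCoA sample coordinates plus the full eigenvalue spectrum."""

    coordinates: pd.DataFrame  # samples x retained axes (positive eigenvalues)
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    metric: str
    transform: str

    @property
    def proportion_explained(self) -> np.ndarray:
        positive = self.eigenvalues[self.eigenvalues > 0]
        return positive / positive.sum()

    def to_tsv(self, path) -> None:
        out = self.coordinates.copy()
        with open(path, "w") as fh:
            fh.write("# eigenvalues\t" + "\t".join(f"{e:.6g}" for e in self.eigenvalues) + "\n")
            out.to_csv(fh, sep="\t", index_label="sample")


def distance_matrix(
    profile: AbundanceProfile | pd.DataFrame,
    transform: str = "sqrt",
    metric: str = "braycurtis",
) -> pd.DataFrame:
    """Pairwise sample distances after an element-wise transform."""
    data = profile.data if isinstance(profile, AbundanceProfile) else profile
    values = data.to_numpy(dtype=float)
    if transform == "sqrt":
        values = np.sqrt(values)
    elif transform not in (None, "none"):
        raise InvalidInputError(f"unknown transform {transform!r}")
    dist = squareform(pdist(values, metric=metric))
    return pd.DataFrame(dist, index=data.index, columns=data.index)


def pcoa(
    profile: AbundanceProfile | pd.DataFrame,
    transform: str = "sqrt",
    metric: str = "braycurtis",
) -> OrdinationResult:
    """Classical metric scaling of transformed profile distances.

    Negative eigenvalues (possible for non-Euclidean metrics such as
    Bray-Curtis) are reported in the spectrum but their axes are dropped from
    the coordinates.
    """
    data = profile.data if isinstance(profile, AbundanceProfile) else profile
    if len(data) < 3:
        raise InvalidInputError("PCoA requires at least 3 samples")
    dist = distance_matrix(data, transform=transform, metric=metric)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dist.to_numpy(), method="eigh", warn_neg_eigval=False)
    eig = np.asarray(res.eigvals)
    keep = eig > 1e-12
    coords = pd.DataFrame(
        res.samples.to_numpy()[:, keep],
        index=data.index,
        columns=[f"PC{i + 1}" for i in range(int(keep.sum()))],
    )
    return OrdinationResult(coords, eig, metric=metric, transform=transform)


# ------------------------------------------------------------- group tests
@dataclass
class ComparisonResult:
    """Per-feature two-group comparison with correction and effect size."""

    feature: str
    mean_a: float
    mean_b: float
    p_value: float
    p_adjusted: float = math.nan
    effect_pct: float = math.nan
    direction: str = "none"  # higher-in-A | higher-in-B | none


def effect_size(abund_i: float, abund_j: float) -> float:
    """Signed percent effect (Abund_i - Abund_j) / Abund_j * 100."""
    if abund_j == 0:
        raise UndefinedEffectError("reference group mean abundance is zero")
    return (abund_i - abund_j) / abund_j * 100.0


def _rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # every observation tied: no evidence either way
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


def adjust_pvalues(p_values: Sequence[float], correction: str = "hommel") -> np.ndarray:
    method = {"hommel": "hommel", "bh": "fdr_bh", "fdr": "fdr_bh"}.get(correction.lower())
    if method is None:
        raise InvalidInputError(f"unknown correction {correction!r}")
    return multipletests(np.asarray(p_values, dtype=float), method=method)[1]


def wilcoxon_compare(
    profile: AbundanceProfile | pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    correction: str = "hommel",
    alpha: float = 0.05,
    direction_on: str = "adjusted",
) -> list[ComparisonResult]:
    """Two-sided Wilcoxon rank-sum test per feature between two groups.

    ``groups`` maps sample -> group label (exactly two labels, each with at
    least two samples; label order is alphabetical, the first label is "A").
    Direction is called at ``alpha`` on the adjusted p by default
    (``direction_on="raw"`` uses the unadjusted p, matching bookkeeping that
    counts raw-significant features).  The effect size is the signed
    percentage change of group A relative to group B (NaN when the reference
    mean is zero).
    """
    if direction_on not in ("adjusted", "raw"):
        raise InvalidInputError("direction_on must be 'adjusted' or 'raw'")
    data = profile.data if isinstance(profile, AbundanceProfile) else profile
    grouping = pd.Series(groups).reindex(data.index)
    if grouping.isna().any():
        raise InvalidInputError("every sample needs a group label")
    labels = sorted(grouping.unique())
    if len(labels) != 2:
        raise InvalidInputError(f"exactly two groups required, got {labels}")
    idx_a = grouping == labels[0]
    idx_b = grouping == labels[1]
    if idx_a.sum() < 2 or idx_b.sum() < 2:
        raise InvalidInputError("each group needs at least 2 samples")

    mat_a = data.loc[idx_a].to_numpy(dtype=float)
    mat_b = data.loc[idx_b].to_numpy(dtype=float)
    raw = [
        _rank_sum_test(mat_a[:, k], mat_b[:, k]) for k in range(data.shape[1])
    ]
    adjusted = adjust_pvalues(raw, correction) if raw else np.array([])
    results = []
    for k, feature in enumerate(data.columns):
        mean_a = float(mat_a[:, k].mean())
        mean_b = float(mat_b[:, k].mean())
        direction = "none"
        p_for_call = adjusted[k] if direction_on == "adjusted" else raw[k]
        if p_for_call < alpha and mean_a != mean_b:
            direction = "higher-in-A" if mean_a > mean_b else "higher-in-B"
        try:
            eff = effect_size(mean_a, mean_b)
        except UndefinedEffectError:
            eff = math.nan
        results.append(
            ComparisonResult(
                feature=str(feature),
                mean_a=mean_a,
                mean_b=mean_b,
                p_value=raw[k],
                p_adjusted=float(adjusted[k]),
                effect_pct=eff,
                direction=direction,
            )
        )
    return results


def comparison_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            [r.feature, r.mean_a, r.mean_b, r.p_value, r.p_adjusted, r.effect_pct, r.direction]
            for r in results
        ],
        columns=["feature", "mean_a", "mean_b", "p", "p_adjusted", "effect_pct", "direction"],
    )


# --------------------------------------------------------------- PERMANOVA
def permanova(
    distances: pd.DataFrame | np.ndarray,
    groups: Mapping[str, str] | pd.Series | Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-way PERMANOVA pseudo-F and permutation p-value.

    The total sum of squared distances is partitioned into among- and
    within-group components; p = (1 + #{permuted F >= observed}) / (1 + n_perm)
    with label permutations drawn from a seeded generator.
    """
    if isinstance(distances, pd.DataFrame):
        labels = pd.Series(groups).reindex(distances.index)
        if labels.isna().any():
            raise InvalidInputError("every sample needs a group label")
        d = distances.to_numpy(dtype=float)
        grouping = labels.to_numpy()
    else:
        d = np.asarray(distances, dtype=float)
        grouping = np.asarray(list(groups))
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-10):
        raise InvalidInputError("distance matrix must be square and symmetric")
    if grouping.shape[0] != n:
        raise InvalidInputError("grouping length must match the distance matrix")
    codes, uniques = pd.factorize(grouping)
    g = len(uniques)
    if g < 2:
        raise InvalidInputError("PERMANOVA requires at least 2 groups")

    d2 = d**2
    ss_total = d2.sum() / (2.0 * n)

    def ss_within(code_rows: np.ndarray) -> np.ndarray:
        # code_rows: (P, n) integer labels; returns within-group SS per row
        out = np.zeros(code_rows.shape[0])
        for gi in range(g):
            mask = (code_rows == gi).astype(float)
            sizes = mask.sum(axis=1)
            quad = np.einsum("pi,ij,pj->p", mask, d2, mask)
            out += np.where(sizes > 0, quad / (2.0 * np.maximum(sizes, 1)), 0.0)
        return out

    sw = ss_within(codes[None, :])[0]
    sa = ss_total - sw
    f_obs = (sa / (g - 1)) / (sw / (n - g))

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    sw_perm = ss_within(perms)
    sa_perm = ss_total - sw_perm
    f_perm = (sa_perm / (g - 1)) / (sw_perm / (n - g))
    p = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (1.0 + n_perm)
    return float(f_obs), float(p)


# --------------------------------------------------------- reporter z-score
def reporter_zscore(
    ko_results: Sequence[ComparisonResult],
    module_kos: Iterable[str],
    n_background: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Background-corrected reporter score for a KO module.

    Each KO's two-sided p is converted to a signed z (inverse normal of the
    one-sided p, sign from its direction of change); the module aggregate is
    Z = sum(z) / sqrt(k) and is standardized against ``n_background`` seeded
    random same-size KO sets drawn from the tested universe.  Returns
    (Z_adjusted, Z_raw).
    """
    by_feature = {r.feature: r for r in ko_results}
    kos = list(module_kos)
    missing = [k for k in kos if k not in by_feature]
    if missing:
        raise MissingFeatureError(f"module KOs absent from results: {missing[:5]}")

    def signed_z(res: ComparisonResult) -> float:
        sign = {"higher-in-A": 1.0, "higher-in-B": -1.0}.get(res.direction, 0.0)
        if sign == 0.0:
            sign = np.sign(res.mean_a - res.mean_b)
        p_one = np.clip(res.p_value / 2.0, 1e-15, 1 - 1e-15)
        return float(sign * sps.norm.ppf(1.0 - p_one))

    z_all = np.array([signed_z(r) for r in ko_results])
    z_idx = {r.feature: i for i, r in enumerate(ko_results)}
    k = len(kos)
    z_raw = float(z_all[[z_idx[ko] for ko in kos]].sum() / math.sqrt(k))

    rng = np.random.default_rng(seed)
    n_univ = len(ko_results)
    bg = np.empty(n_background)
    for b in range(n_background):
        pick = rng.choice(n_univ, size=k, replace=False)
        bg[b] = z_all[pick].sum() / math.sqrt(k)
    sd = bg.std(ddof=1)
    if sd == 0:
        raise InvalidInputError("degenerate background: zero variance")
    return float((z_raw - bg.mean()) / sd), z_raw
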