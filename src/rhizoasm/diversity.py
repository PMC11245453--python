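"""Alpha diversity, Bray-Curtis beta diversity, PCoA ordination, ANOSIM /
PERMANOVA permutation tests, and the factorial (regime x season) statistics
used to compare them across a fertilization study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
import skbio
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io import OtuTable

__all__ = [
    "alpha_diversity",
    "shannon",
    "chao1",
    "bray_curtis",
    "PcoaResult",
    "pcoa",
    "AnosimResult",
    "anosim",
    "permanova",
    "FactorialStats",
    "factorial_stats",
]


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy of one sample; natural log by default (nats)."""
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("sample has zero total count")
    p = x[x > 0] / total
    h = -np.sum(p * np.log(p))
    if base is not None:
        h /= np.log(base)
    return float(h)


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimator from singleton (F1) and doubleton (F2) counts.

    Bias-corrected form S + F1(F1-1)/(2(F2+1)) by default; the classic
    S + F1^2/(2 F2) is available but undefined at F2 = 0.
    """
    x = np.asarray(counts)
    s_obs = int(np.sum(x > 0))
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ValueError("classic Chao1 undefined when F2 = 0; use bias_corrected=True")
    return s_obs + f1 * f1 / (2.0 * f2)


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample richness, Shannon (nats) and bias-corrected Chao1."""
    rows = []
    for sid in table.sample_ids:
        col = table.data[sid].to_numpy()
        if col.sum() == 0:
            raise ValueError(f"zero-sum sample {sid!r}")
        rows.append(
            {
                "sample_id": sid,
                "richness": int(np.sum(col > 0)),
                "shannon": shannon(col),
                "chao1": chao1(col),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable) -> skbio.DistanceMatrix:
    """Bray-Curtis dissimilarity between samples, BC = sum|x-y| / sum(x+y)."""
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    sums = table.data.sum(axis=0)
    if (sums == 0).any():
        raise ValueError(f"zero-sum sample(s): {list(sums.index[sums == 0])}")
    mat = table.counts.T.astype(float)
    condensed = pdist(mat, metric="braycurtis")
    return skbio.DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    percent_variance: np.ndarray  # relative to the positive-eigenvalue total
    negative_eigenvalues: np.ndarray


def pcoa(dm: skbio.DistanceMatrix) -> PcoaResult:
    """Classical scaling (Gower double-centering of -D^2/2).

    Percent variance per axis is eigenvalue / sum(positive eigenvalues) * 100.
    Negative eigenvalues are reported as-is, never corrected away.
    """
    res = _skbio_pcoa(dm, method="eigh", dimensions=0)
    eig = res.eigvals.to_numpy()
    pos = eig[eig > 0]
    pct = np.where(eig > 0, eig / pos.sum() * 100.0, 0.0)
    coords = res.samples
    coords.index = list(dm.ids)
    return PcoaResult(
        coordinates=coords,
        eigenvalues=eig,
        percent_variance=pct,
        negative_eigenvalues=eig[eig < 0],
    )


# ---------------------------------------------------------------------------
# ANOSIM / PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    statistic: float
    p_value: float
    n_permutations: int
    factor: str


def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def anosim(
    dm: skbio.DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
    factor: str = "grouping",
) -> AnosimResult:
    """ANOSIM R with permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4) on
    the ranked dissimilarities; p = (#{permuted R >= observed} + 1) /
    (n_permutations + 1).
    """
    labels = np.asarray(list(grouping))
    n = len(dm.ids)
    if len(labels) != n:
        raise ValueError("grouping length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"group(s) with a single sample: {small}")

    condensed = dm.condensed_form()
    ranks = stats.rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)
    within = labels[iu] == labels[ju]
    r_obs = _anosim_r(ranks, within, n)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm[iu] == perm[ju], n) >= r_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return AnosimResult(statistic=r_obs, p_value=p, n_permutations=n_permutations, factor=factor)


def permanova(
    dm: skbio.DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
    factor: str = "grouping",
) -> AnosimResult:
    """PERMANOVA pseudo-F under the same label-permutation scheme (the
    'adonis' dialect); returned in the same result container."""
    rng = np.random.default_rng(seed)
    res = skbio.stats.distance.permanova(
        dm, np.asarray(list(grouping)), permutations=n_permutations, seed=rng
    )
    return AnosimResult(
        statistic=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        n_permutations=n_permutations,
        factor=factor,
    )


# ---------------------------------------------------------------------------
# factorial (two-way) statistics
# ---------------------------------------------------------------------------

@dataclass
class FactorialStats:
    anova: pd.DataFrame  # F and p for factor_a, factor_b, interaction
    tukey_letters_a: dict  # level -> letters, factor A averaged over B
    tukey_letters_b: dict
    ks_normality_p: float


def _compact_letter_display(levels, means, sig_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    Two levels share a letter iff they are not significantly different.
    """
    sets = [set(levels)]
    for a, b in sig_pairs:
        next_sets = []
        for s in sets:
            if a in s and b in s:
                next_sets.extend([s - {a}, s - {b}])
            else:
                next_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(next_sets, key=len, reverse=True):
            if not any(s <= t for t in sets):
                sets.append(s)
    order = sorted(levels, key=lambda l: -means[l])
    sets.sort(key=lambda s: min(order.index(l) for l in s) if s else 0)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {l: "" for l in levels}
    for i, s in enumerate(sets):
        for l in order:
            if l in s:
                letters[l] += alphabet[i % len(alphabet)]
    return letters


def _tukey_letters(values: np.ndarray, labels: np.ndarray, alpha: float = 0.05) -> dict:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    levels = list(pd.unique(labels))
    means = {l: float(values[labels == l].mean()) for l in levels}
    if len(levels) < 2 or np.allclose(values, values[0]):
        return {l: "a" for l in levels}
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(
        data=res.summary().data[1:], columns=res.summary().data[0]
    )
    sig_pairs = [
        (row["group1"], row["group2"])
        for _, row in frame.iterrows()
        if bool(row["reject"]) or str(row["reject"]) == "True"
    ]
    return _compact_letter_display(levels, means, sig_pairs)


def factorial_stats(
    values,
    metadata: pd.DataFrame,
    factor_a: str = "regime",
    factor_b: str = "season",
    alpha: float = 0.05,
) -> FactorialStats:
    """Two-way type-II ANOVA with interaction, Tukey HSD letter displays per
    factor, and a Kolmogorov-Smirnov normality screen.

    ``values`` is a per-sample response aligned to ``metadata.sample_id``
    (a pandas Series indexed by sample id, or an array in metadata order).
    The KS p-value is attached as a screen only; it never gates the ANOVA.
    Letters are computed per factor pooling over the other factor, the
    usual dual (uppercase/lowercase) presentation of factorial tables; here
    both are lowercase strings in separate mappings.
    """
    meta = metadata.reset_index(drop=True)
    if isinstance(values, pd.Series):
        y = values.loc[meta["sample_id"]].to_numpy(dtype=float)
    else:
        y = np.asarray(values, dtype=float)
        if len(y) != len(meta):
            raise ValueError("values length does not match metadata")

    cells = meta.groupby([factor_a, factor_b], observed=True).size()
    expected = meta[factor_a].nunique() * meta[factor_b].nunique()
    if len(cells) < expected:
        raise ValueError("empty regime x season cell(s) in the design")
    if (cells < 2).any():
        raise ValueError("need >= 2 replicates per cell")

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = meta[[factor_a, factor_b]].copy()
    df["y"] = y
    model = smf.ols(f"y ~ C({factor_a}) * C({factor_b})", data=df).fit()
    if np.allclose(y, y[0]):
        idx = [f"C({factor_a})", f"C({factor_b})", f"C({factor_a}):C({factor_b})"]
        anova = pd.DataFrame({"F": [0.0] * 3, "PR(>F)": [1.0] * 3}, index=idx)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova = sm.stats.anova_lm(model, typ=2)[["F", "PR(>F)"]].iloc[:3]

    sd = y.std(ddof=1)
    if sd == 0:
        ks_p = 1.0
    else:
        ks_p = float(stats.kstest((y - y.mean()) / sd, "norm").pvalue)

    return FactorialStats(
        anova=anova,
        tukey_letters_a=_tukey_letters(y, meta[factor_a].to_numpy(), alpha),
        tukey_letters_b=_tukey_letters(y, meta[factor_b].to_numpy(), alpha),
        ks_normality_p=ks_p,
    )
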