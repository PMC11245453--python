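"""Sloan neutral community model and Levins niche breadth.

The Sloan model treats each local community as a migration-drift sample of
the regional pool: a taxon with regional mean relative abundance p is
detected (above detection limit d) in a fraction of samples

    F(p) = 1 - BetaCDF(d; N*m*p, N*m*(1 - p))

where N is the community (read) size and m the migration rate.  Fitting the
single parameter Nm to the observed (p, occurrence frequency) cloud gives a
migration estimate and an R^2 describing how much of the frequency pattern
is explainable by neutral drift plus dispersal alone.  Taxa above the 95%
prediction band are detected more often than neutrality predicts; taxa
below, less often.

Levins niche breadth B = 1 / sum_i P_ij^2 (inverse Simpson concentration of
taxon j's abundance over resource states i) quantifies how evenly a taxon
spreads over habitats; permutation against fixed-margin null tables
classifies taxa into generalists, specialists, and neutral taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import OtuTable

__all__ = ["NcmFit", "ncm_fit", "ncm_curve", "levins_breadth", "spec_gen_classify"]


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------

@dataclass
class NcmFit:
    Nm: float
    m: float
    r_squared: float
    detection_limit: float
    n_samples: int
    community_size: float
    taxa: pd.DataFrame = field(repr=False)  # p, freq, freq_pred, lower, upper, band


def ncm_curve(p, Nm: float, d: float):
    """Predicted occurrence frequency for regional mean abundance ``p``."""
    p = np.asarray(p, dtype=float)
    a = np.clip(Nm * p, 1e-12, None)
    b = np.clip(Nm * (1.0 - p), 1e-12, None)
    return stats.beta.sf(d, a, b)


def _wilson_band(freq_pred: np.ndarray, n: int, z: float = 1.959963984540054):
    """Wilson score 95% interval around a predicted proportion at sample
    count n."""
    denom = 1.0 + z**2 / n
    center = (freq_pred + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(freq_pred * (1 - freq_pred) / n + z**2 / (4 * n**2))
    return np.clip(center - half, 0.0, 1.0), np.clip(center + half, 0.0, 1.0)


def ncm_fit(table: OtuTable, detection_limit: float | None = None) -> NcmFit:
    """Fit the one-parameter (Nm) Sloan model by nonlinear least squares.

    ``detection_limit`` defaults to 1/N with N the mean sample read total.
    Raises on degenerate inputs (too few taxa/samples, or every taxon
    present in every sample) and on optimizer failure.
    """
    counts = table.counts.astype(float)
    n_samples = counts.shape[1]
    if n_samples < 5:
        raise ValueError("need at least 5 samples to fit the neutral model")
    totals = counts.sum(axis=0)
    rel = counts / totals
    p = rel.mean(axis=1)
    keep = p > 0
    if keep.sum() < 10:
        raise ValueError("need at least 10 taxa with nonzero mean abundance")
    p = p[keep]
    freq = (counts[keep] > 0).mean(axis=1)
    taxa_ids = [t for t, k in zip(table.taxon_ids, keep) if k]

    n_mean = float(totals.mean())
    d = 1.0 / n_mean if detection_limit is None else float(detection_limit)
    if np.all(freq >= 1.0):
        raise ValueError("all taxa occur in every sample; occurrence curve is degenerate")

    def residuals(log_nm):
        return ncm_curve(p, np.exp(log_nm[0]), d) - freq

    best = None
    for start in (np.log(n_mean * 0.1), np.log(n_mean), 5.0, 10.0):
        try:
            sol = optimize.least_squares(residuals, x0=[start], method="lm", max_nfev=10_000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError("neutral model fit did not converge from any start point")

    nm = float(np.exp(best.x[0]))
    pred = ncm_curve(p, nm, d)
    sse = float(np.sum((freq - pred) ** 2))
    sst = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    lower, upper = _wilson_band(pred, n_samples)
    band = np.where(freq > upper, "above", np.where(freq < lower, "below", "within"))

    taxa = pd.DataFrame(
        {"p": p, "freq": freq, "freq_pred": pred, "lower": lower, "upper": upper,
         "band": band},
        index=pd.Index(taxa_ids, name="taxon_id"),
    )
    return NcmFit(
        Nm=nm, m=nm / n_mean, r_squared=r2, detection_limit=d,
        n_samples=n_samples, community_size=n_mean, taxa=taxa,
    )


# ---------------------------------------------------------------------------
# Levins niche breadth
# ---------------------------------------------------------------------------

def _resource_matrix(table: OtuTable, resource_states: pd.Series | None) -> pd.DataFrame:
    """Taxa-by-state count matrix; states default to individual samples, or
    pooled by a sample -> state mapping (e.g. regime x season cells)."""
    if resource_states is None:
        return table.data
    mapped = [resource_states.loc[s] for s in table.sample_ids]
    return table.data.T.groupby(pd.Index(mapped, name="state")).sum().T


def levins_breadth(
    table: OtuTable, resource_states: pd.Series | None = None
) -> pd.Series:
    """Levins B per taxon: 1 / sum of squared proportions over resource
    states.  B = 1 for a single-state specialist, B = number of states for a
    perfectly even generalist.  Taxa absent everywhere are excluded with a
    warning."""
    mat = _resource_matrix(table, resource_states)
    row_sums = mat.sum(axis=1)
    absent = row_sums == 0
    if absent.any():
        warnings.warn(f"excluding {int(absent.sum())} taxa absent from all states")
        mat = mat.loc[~absent]
        row_sums = row_sums[~absent]
    prop = mat.div(row_sums, axis=0)
    return 1.0 / (prop**2).sum(axis=1)


def spec_gen_classify(
    table: OtuTable,
    n_perm: int = 1000,
    seed: int | None = None,
    resource_states: pd.Series | None = None,
    ci: float = 95.0,
) -> pd.DataFrame:
    """Generalist / specialist / neutral classification of every taxon.

    The null distribution of B per taxon comes from ``n_perm`` random count
    tables with the observed row and column sums held fixed (Patefield
    sampling of the fixed-margin table space).  A taxon whose observed B
    exceeds the upper 97.5 percentile of its null is a generalist, below the
    2.5 percentile a specialist, within the interval a neutral taxon.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mat = _resource_matrix(table, resource_states)
    row_sums = mat.sum(axis=1)
    mat = mat.loc[row_sums > 0]
    obs = levins_breadth(table, resource_states)

    rng = np.random.default_rng(seed)
    r = mat.sum(axis=1).to_numpy(dtype=np.int64)
    c = mat.sum(axis=0).to_numpy(dtype=np.int64)
    sampler = stats.random_table(r, c, seed=rng)
    null_b = np.empty((n_perm, len(r)))
    for k in range(n_perm):
        nt = sampler.rvs(method="patefield").astype(float)
        prop = nt / r[:, None]
        null_b[k] = 1.0 / np.sum(prop**2, axis=1)

    lo = np.percentile(null_b, (100.0 - ci) / 2.0, axis=0)
    hi = np.percentile(null_b, 100.0 - (100.0 - ci) / 2.0, axis=0)
    b = obs.loc[mat.index].to_numpy()
    cls = np.where(b > hi, "generalist", np.where(b < lo, "specialist", "neutral"))
    return pd.DataFrame(
        {"breadth": b, "null_lower": lo, "null_upper": hi, "classification": cls},
        index=mat.index,
    )
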