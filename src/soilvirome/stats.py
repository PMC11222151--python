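"""Atlas-level diversity statistics.

Operates on attribute x sample occupancy (count) matrices — attributes
being vOTUs, genus/family clusters, functional-domain annotations or host
orders. Provides per-sample rarefaction (subsampling without replacement),
cumulative accumulation curves ordered by assembled base pairs, occupancy
summaries (fraction of attributes seen in more than one / more than five
samples), the empirical CDF of per-sample spacer-hit ratios, and Spearman
correlations between host-order hit counts and soil covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "RarefactionCurve",
    "rarefy",
    "filter_rarefaction_inputs",
    "accumulation_curve",
    "occupancy_stats",
    "host_ratio_cdf",
    "spearman_host_env",
]

#: minimum per-sample richness for rarefaction, by attribute kind
_RAREFACTION_FLOORS = {
    "vOTU": 5,
    "genus_cluster": 5,
    "family_cluster": 5,
    "domain_annotation": 5,
    "host_order": 100,
    "microbial_domain": 100,
    "microbial_taxon": 100,
}


@dataclass
class RarefactionCurve:
    depths: list[int]
    mean_richness: list[float]
    sd_richness: list[float]
    n_reps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.depths,
                "mean_richness": self.mean_richness,
                "sd_richness": self.sd_richness,
            }
        )


def rarefy(
    counts: dict[str, int],
    depths: list[int],
    n_reps: int = 100,
    seed: int = 0,
) -> RarefactionCurve:
    """Rarefaction of one sample by subsampling without replacement.

    At each depth, that many observations are drawn without replacement
    from the sample's count vector ``n_reps`` times; the mean and sd of the
    number of distinct attributes are reported. Depths beyond the total
    count raise ``ValueError``.
    """
    items = [a for a, c in counts.items() for _ in range(c)]
    total = len(items)
    labels, _ = pd.factorize(np.array(items)) if items else (np.array([], dtype=int), None)
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds total count {total}")
        if depth == 0:
            means.append(0.0)
            sds.append(0.0)
            continue
        rich = np.empty(n_reps)
        for r in range(n_reps):
            pick = rng.choice(labels, size=depth, replace=False)
            rich[r] = np.unique(pick).size
        means.append(float(rich.mean()))
        sds.append(float(rich.std(ddof=0)))
    return RarefactionCurve(list(depths), means, sds, n_reps, seed)


def filter_rarefaction_inputs(
    matrix: pd.DataFrame, kind: str
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples whose richness is under the kind-specific floor.

    Viral attribute kinds require at least 5 distinct attributes per
    sample; host/microbial kinds at least 100 ("fewer than" is strict, so
    a sample exactly at the floor is kept). Returns (kept matrix, dropped
    sample ids).
    """
    if kind not in _RAREFACTION_FLOORS:
        raise ValueError(f"unknown attribute kind {kind!r}")
    floor = _RAREFACTION_FLOORS[kind]
    richness = (matrix > 0).sum(axis=0)
    keep = richness >= floor
    dropped = [s for s in matrix.columns if not keep[s]]
    return matrix.loc[:, keep], dropped


def accumulation_curve(
    matrix: pd.DataFrame, assembled_bp: dict[str, int]
) -> pd.DataFrame:
    """Cumulative distinct attributes, adding samples by assembled bp.

    Samples are ordered ascending by assembled base pairs (ties by sample
    id); each step reports the cumulative bp and the number of distinct
    attributes seen in the prefix.
    """
    missing = [s for s in matrix.columns if s not in assembled_bp]
    if missing:
        raise ValueError(f"samples without assembled_bp: {missing}")
    order = sorted(matrix.columns, key=lambda s: (assembled_bp[s], s))
    seen: set[str] = set()
    rows = []
    cum_bp = 0
    for s in order:
        cum_bp += assembled_bp[s]
        seen.update(matrix.index[matrix[s] > 0])
        rows.append(
            {"sample_id": s, "cumulative_bp": cum_bp, "cumulative_richness": len(seen)}
        )
    return pd.DataFrame(rows)


def occupancy_stats(matrix: pd.DataFrame) -> dict:
    """Occupancy summary of an attribute x sample count matrix."""
    present = matrix > 0
    n_samples_per_attr = present.sum(axis=1)
    observed = n_samples_per_attr > 0
    n_attr = int(observed.sum())
    richness = present.sum(axis=0)
    return {
        "n_attributes": n_attr,
        "n_samples": matrix.shape[1],
        "fraction_gt1_sample": float((n_samples_per_attr > 1).sum() / n_attr) if n_attr else 0.0,
        "fraction_gt5_samples": float((n_samples_per_attr > 5).sum() / n_attr) if n_attr else 0.0,
        "mean_richness_per_sample": float(richness.mean()),
        "min_richness_per_sample": int(richness.min()),
        "max_richness_per_sample": int(richness.max()),
    }


def host_ratio_cdf(ratios: list[float]) -> pd.DataFrame:
    """Right-continuous empirical CDF of per-sample spacer-hit ratios,
    as (ratio, fraction of samples <= ratio) at each distinct ratio."""
    if any(r < 0 for r in ratios):
        raise ValueError("ratios must be non-negative")
    x = np.sort(np.asarray(ratios, dtype=float))
    n = len(x)
    values = np.unique(x)
    cdf = np.searchsorted(x, values, side="right") / n
    return pd.DataFrame({"ratio": values, "cdf": cdf})


def spearman_host_env(
    host_counts: pd.DataFrame,
    env: pd.DataFrame,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Spearman rho between host-order hit counts and soil covariates.

    ``host_counts`` is order x sample, ``env`` is sample x covariate. Only
    orders present (count > 0) in strictly more than ``min_samples``
    samples are correlated. Per (order, covariate) pair, rho is computed
    with average ranks over the samples where both values are defined;
    pairs with fewer than 3 paired observations or a constant vector yield
    NaN.
    """
    shared = [s for s in host_counts.columns if s in env.index]
    hc = host_counts[shared]
    prevalent = hc.index[(hc > 0).sum(axis=1) > min_samples]
    out = pd.DataFrame(index=prevalent, columns=env.columns, dtype=float)
    for order in prevalent:
        for cov in env.columns:
            x = hc.loc[order].astype(float)
            y = env.loc[shared, cov].astype(float)
            mask = x.notna().values & y.notna().values
            if mask.sum() < 3:
                out.loc[order, cov] = np.nan
                continue
            xv, yv = x.values[mask], y.values[mask]
            if np.all(xv == xv[0]) or np.all(yv == yv[0]):
                out.loc[order, cov] = np.nan
                continue
            rho, _ = sstats.spearmanr(xv, yv)
            out.loc[order, cov] = rho
    return out
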