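"""Gene-set enrichment per contrast with separate up/down calls.

Per-gene statistics are log2 ratios of moderated normalized abundances for
every (treatment sample, control sample) pair; each set is compared to the
genome-wide background with a t-like statistic per pair column, one-sided
per direction, and the per-column p-values are combined with Stouffer's
method. Core ("influential") genes are the members driving the signal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de_core import NormFactors, bh_adjust, tmm_factors
from .io_formats import CountMatrix, GeneSetDB

logger = logging.getLogger("smoketc")

DEFAULT_MIN_SET_SIZE = 5
CORE_SD_THRESHOLD = 1.0


def gene_level_stats(
    cm: CountMatrix,
    labels,
    pair: tuple[str, str],
    nf: NormFactors | None = None,
    moderation: float | None = None,
) -> np.ndarray:
    """Per-gene log2 ratios over all (treatment, control) sample pairs.

    ``stat[g, k]`` for pair ``k = (i, j)`` is
    ``log2((y_gi/N_i + c) / (y_gj/N_j + c))`` on effective library sizes,
    with moderation constant ``c = 8 / mean(N)`` unless overridden.
    """
    labels = np.asarray(labels)
    treat, control = pair
    i1 = np.flatnonzero(labels == treat)
    i2 = np.flatnonzero(labels == control)
    if len(i1) == 0 or len(i2) == 0:
        raise ValueError(f"empty group in contrast {treat} vs {control}")
    if nf is None:
        nf = tmm_factors(cm)
    eff = nf.effective_lib_sizes
    if moderation is None:
        moderation = 8.0 / float(eff.mean())
    prop = cm.counts / eff[None, :] + moderation
    logp = np.log2(prop)
    cols = [(i, j) for i in i1 for j in i2]
    out = np.empty((cm.counts.shape[0], len(cols)))
    for k, (i, j) in enumerate(cols):
        out[:, k] = logp[:, i] - logp[:, j]
    return out


def set_test(
    stats_matrix: np.ndarray,
    member_idx: np.ndarray,
    direction: str,
    n_treat: int | None = None,
    n_control: int | None = None,
) -> tuple[float, float]:
    """Test one gene set against the background, one-sided.

    Per pair column a two-sample t-like statistic compares set genes to all
    genes (t reference, df = set size - 1); column p-values are combined by
    Stouffer's method. Pair columns sharing a sample are correlated (0.5
    under the exchangeable null), so when the pair layout (``n_treat``,
    ``n_control``) is known the combined z is scaled by the exact null
    variance ``n_treat * n_control * (n_treat + n_control) / 2`` instead of
    the independence value; without it the naive (anti-conservative)
    combination is used. Returns (mean per-column t, combined p).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    member_idx = np.asarray(member_idx)
    m = member_idx.size
    if m < 2:
        raise ValueError("set too small to test")
    big_n = stats_matrix.shape[0]
    set_vals = stats_matrix[member_idx, :]
    mean_set = set_vals.mean(axis=0)
    var_set = set_vals.var(axis=0, ddof=1)
    mean_all = stats_matrix.mean(axis=0)
    var_all = stats_matrix.var(axis=0, ddof=1)
    se = np.sqrt(var_set / m + var_all / big_n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean_set - mean_all) / se, 0.0)
    df = m - 1
    if direction == "up":
        p_cols = stats.t.sf(t, df)
    else:
        p_cols = stats.t.cdf(t, df)
    if n_treat is not None and n_control is not None:
        if n_treat * n_control != t.size:
            raise ValueError("pair layout inconsistent with statistic matrix")
        null_var = n_treat * n_control * (n_treat + n_control) / 2.0
    else:
        null_var = float(t.size)
    p = _stouffer(p_cols, null_var)
    return float(t.mean()), float(p)


def _stouffer(p_cols: np.ndarray, null_var: float | None = None) -> float:
    p_cols = np.clip(np.asarray(p_cols, dtype=float), 1e-300, 1.0 - 1e-16)
    z = stats.norm.isf(p_cols)
    if null_var is None:
        null_var = float(z.size)
    combined = z.sum() / np.sqrt(null_var)
    return float(stats.norm.sf(combined))


def core_genes(
    stats_matrix: np.ndarray,
    gene_ids: list[str],
    member_idx: np.ndarray,
    direction: str,
    sd_threshold: float = CORE_SD_THRESHOLD,
) -> list[str]:
    """Members contributing substantially to the set's signal.

    A member is core when its mean pair statistic carries the enrichment
    sign and its magnitude is at least ``sd_threshold`` standard deviations
    of the all-gene mean-statistic distribution.
    """
    member_idx = np.asarray(member_idx)
    gene_means = stats_matrix.mean(axis=1)
    sd_all = float(gene_means.std(ddof=1))
    sign = 1.0 if direction == "up" else -1.0
    vals = gene_means[member_idx] * sign
    keep = vals >= sd_threshold * sd_all
    return [gene_ids[i] for i, k in zip(member_idx, keep) if k]


def enrich_contrast(
    cm: CountMatrix,
    sets: GeneSetDB,
    treat: str,
    control: str,
    treat_time: str | None = None,
    control_time: str | None = None,
    nf: NormFactors | None = None,
    fdr: float = 0.10,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> pd.DataFrame:
    """Up/down enrichment table for one pairwise contrast.

    q-values are BH-adjusted within each direction; ``significant`` means
    q <= fdr.
    """
    mask = np.array(
        [
            (s.group == treat and (treat_time is None or s.time_label == treat_time))
            or (
                s.group == control
                and (control_time is None or s.time_label == control_time)
            )
            for s in cm.samples
        ]
    )
    sub = cm.select_samples(mask)
    labels = np.array([s.group for s in sub.samples])
    if nf is not None:
        nf = nf.subset(np.flatnonzero(mask))
    else:
        nf = tmm_factors(sub)
    stats_matrix = gene_level_stats(sub, labels, (treat, control), nf)
    n_treat = int((labels == treat).sum())
    n_control = int((labels == control).sum())
    gene_pos = {g: i for i, g in enumerate(sub.gene_ids)}

    rows = []
    for name, members in sets:
        idx = np.array([gene_pos[g] for g in members if g in gene_pos])
        if idx.size < min_set_size:
            logger.info(
                "set %r skipped: %d tested members < min_set_size=%d",
                name,
                idx.size,
                min_set_size,
            )
            continue
        for direction in ("up", "down"):
            stat, p = set_test(stats_matrix, idx, direction, n_treat, n_control)
            core = core_genes(stats_matrix, sub.gene_ids, idx, direction)
            rows.append(
                {
                    "set": name,
                    "direction": direction,
                    "set_stat": stat,
                    "p_value": p,
                    "n_tested": int(idx.size),
                    "core_genes": core,
                }
            )
    res = pd.DataFrame(
        rows,
        columns=["set", "direction", "set_stat", "p_value", "n_tested", "core_genes"],
    )
    if len(res):
        res["q_value"] = np.nan
        for direction in ("up", "down"):
            sel = res["direction"] == direction
            res.loc[sel, "q_value"] = bh_adjust(res.loc[sel, "p_value"].to_numpy())
        res["significant"] = res["q_value"] <= fdr
    else:
        res["q_value"] = pd.Series(dtype=float)
        res["significant"] = pd.Series(dtype=bool)
    res.attrs["contrast"] = f"{treat}_vs_{control}"
    res.attrs["fdr"] = fdr
    return res


def enrich_timepoints(
    cm: CountMatrix,
    sets: GeneSetDB,
    time_labels,
    pair: tuple[str, str] = ("CS", "AC"),
    nf: NormFactors | None = None,
    fdr: float = 0.10,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> dict[str, pd.DataFrame]:
    """Enrichment tables for one contrast at each time point."""
    return {
        t: enrich_contrast(
            cm,
            sets,
            pair[0],
            pair[1],
            treat_time=t,
            control_time=t,
            nf=nf,
            fdr=fdr,
            min_set_size=min_set_size,
        )
        for t in time_labels
    }


def significance_grid(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Set x time-point grid of significant enrichment direction.

    Cell values: +1 (up), -1 (down), 0 (not significant). If a set is
    somehow significant in both directions the smaller q wins.
    """
    all_sets: list[str] = []
    for tab in tables.values():
        for s in tab["set"].unique():
            if s not in all_sets:
                all_sets.append(s)
    grid = pd.DataFrame(0, index=all_sets, columns=list(tables), dtype=int)
    for t, tab in tables.items():
        sig = tab[tab["significant"]]
        for name, group in sig.groupby("set", sort=False):
            best = group.loc[group["q_value"].idxmin()]
            grid.loc[name, t] = 1 if best["direction"] == "up" else -1
    return grid


__all__ = [
    "gene_level_stats",
    "set_test",
    "core_genes",
    "enrich_contrast",
    "enrich_timepoints",
    "significance_grid",
]
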