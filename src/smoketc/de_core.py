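"""Pairwise differential expression for NB-distributed counts.

Implements trimmed-mean-of-M normalization, quantile-adjusted conditional
maximum-likelihood dispersion estimation (common + shrunken tagwise), the
conditional NB exact test, Benjamini-Hochberg adjustment, and independent
filtering on the overall mean normalized count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .io_formats import CountMatrix

logger = logging.getLogger("smoketc")

PHI_MIN = 1e-6
PHI_MAX = 10.0
#: proportional prior count added to per-sample group means before log2
LOGFC_PRIOR = 0.125
#: relative tolerance for probability ties in the two-sided exact test
_TIE_LOGTOL = 1e-8


@dataclass
class NormFactors:
    """Per-sample TMM scale factors (geometric mean 1)."""

    sample_ids: list[str]
    factors: np.ndarray
    lib_sizes: np.ndarray

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.factors

    def subset(self, idx) -> "NormFactors":
        idx = np.asarray(idx)
        return NormFactors(
            sample_ids=[self.sample_ids[i] for i in idx],
            factors=self.factors[idx],
            lib_sizes=self.lib_sizes[idx],
        )


@dataclass
class DispersionEstimates:
    """Common and tagwise NB dispersions (phi; variance = mu + phi*mu^2)."""

    common_phi: float
    tagwise_phi: np.ndarray
    prior_df: float = 10.0


# ---------------------------------------------------------------------------
# TMM normalization


def tmm_factors(
    cm: CountMatrix,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
    ref_index: int | None = None,
) -> NormFactors:
    """Trimmed-mean-of-M-values scale factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile. M values are doubly trimmed
    (``m_trim`` each M tail, ``a_trim`` each A tail) and combined with
    inverse asymptotic-variance weights.
    """
    counts = cm.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample column")
    if ref_index is None:
        f75 = np.percentile(counts / lib, 75, axis=0)
        ref_index = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = counts[:, ref_index]
    nref = lib[ref_index]

    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_index:
            continue
        obs = counts[:, j]
        nobs = lib[j]
        both = (obs > 0) & (ref > 0)
        if not both.any():
            raise ValueError(
                f"sample {cm.samples[j].sample_id!r} shares no expressed "
                f"gene with the reference"
            )
        po = obs[both] / nobs
        pr = ref[both] / nref
        m = np.log2(po / pr)
        a = 0.5 * np.log2(po * pr)
        # asymptotic variance of M (delta method, binomial sampling)
        var = (
            (nobs - obs[both]) / (nobs * obs[both])
            + (nref - ref[both]) / (nref * ref[both])
        )
        n = m.size
        mrank = np.argsort(np.argsort(m, kind="stable"), kind="stable")
        arank = np.argsort(np.argsort(a, kind="stable"), kind="stable")
        lo_m, hi_m = np.floor(n * m_trim), np.ceil(n * (1 - m_trim))
        lo_a, hi_a = np.floor(n * a_trim), np.ceil(n * (1 - a_trim))
        keep = (
            (mrank >= lo_m)
            & (mrank < hi_m)
            & (arank >= lo_a)
            & (arank < hi_a)
        )
        if not keep.any():
            logger.warning(
                "TMM: trimming removed all genes for sample %r; factor set "
                "to 1",
                cm.samples[j].sample_id,
            )
            continue
        w = 1.0 / var[keep]
        lf = float(np.sum(w * m[keep]) / np.sum(w))
        if not np.isfinite(lf):
            lf = 0.0
        log_factors[j] = lf

    factors = 2.0 ** (log_factors - log_factors.mean())
    return NormFactors(sample_ids=cm.sample_ids, factors=factors, lib_sizes=lib)


def equalize_counts(cm: CountMatrix, nf: NormFactors) -> tuple[np.ndarray, float]:
    """Scale counts to the geometric-mean effective library size, re-rounded.

    Returns the integer pseudo-count matrix and the common library size.
    """
    eff = nf.effective_lib_sizes
    common = float(np.exp(np.mean(np.log(eff))))
    pseudo = np.rint(cm.counts * (common / eff)[None, :]).astype(np.int64)
    return pseudo, common


def cpm(cm: CountMatrix, nf: NormFactors | None = None) -> np.ndarray:
    """Counts per million on effective (TMM-adjusted) library sizes."""
    lib = cm.lib_sizes if nf is None else nf.effective_lib_sizes
    return cm.counts / lib[None, :] * 1e6


# ---------------------------------------------------------------------------
# qCML dispersion


def _group_indices(labels) -> list[np.ndarray]:
    labels = np.asarray(labels)
    return [np.flatnonzero(labels == g) for g in pd.unique(labels)]


def _cond_loglik(pseudo: np.ndarray, group_idx: list[np.ndarray], phi: float) -> np.ndarray:
    """Per-gene NB conditional log-likelihood given per-group totals."""
    r = 1.0 / phi
    out = np.zeros(pseudo.shape[0])
    for idx in group_idx:
        y = pseudo[:, idx]
        n = len(idx)
        z = y.sum(axis=1)
        out += (
            gammaln(y + r).sum(axis=1)
            + gammaln(n * r)
            - gammaln(z + n * r)
            - n * gammaln(r)
        )
    return out


def estimate_dispersion(
    cm: CountMatrix,
    labels,
    nf: NormFactors,
    prior_df: float = 10.0,
    grid_size: int = 81,
) -> DispersionEstimates:
    """Common + tagwise qCML dispersion on quantile-equalized counts.

    The common value maximizes the conditional log-likelihood summed over
    genes; tagwise values maximize the per-gene likelihood plus
    ``prior_df / residual_df`` copies of the genome-average likelihood
    (shrinkage toward common; ``prior_df = inf`` gives tagwise == common).
    """
    labels = np.asarray(labels)
    group_idx = _group_indices(labels)
    for idx in group_idx:
        if len(idx) < 2:
            raise ValueError("each group needs >=2 samples for qCML")
    pseudo, _ = equalize_counts(cm, nf)

    def neg_total(log_phi: float) -> float:
        return -float(_cond_loglik(pseudo, group_idx, np.exp(log_phi)).sum())

    res = minimize_scalar(
        neg_total,
        bounds=(np.log(PHI_MIN), np.log(PHI_MAX)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    common = float(np.exp(res.x))
    if common <= PHI_MIN * 1.01 or common >= PHI_MAX * 0.99:
        logger.warning("common dispersion at optimizer boundary: %.3g", common)

    if np.isinf(prior_df):
        tagwise = np.full(pseudo.shape[0], common)
        return DispersionEstimates(common, tagwise, prior_df)

    df_resid = len(labels) - len(group_idx)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    prior_n = prior_df / df_resid

    grid = np.exp(np.linspace(np.log(PHI_MIN), np.log(PHI_MAX), grid_size))
    # widen resolution near the common value
    grid = np.unique(np.concatenate([grid, common * np.exp(np.linspace(-1, 1, 21))]))
    ll = np.empty((grid.size, pseudo.shape[0]))
    for k, phi in enumerate(grid):
        ll[k] = _cond_loglik(pseudo, group_idx, phi)
    shared = ll.mean(axis=1)  # genome-average likelihood per grid point
    weighted = ll + prior_n * shared[:, None]
    best = np.argmax(weighted, axis=0)
    tagwise = grid[best]
    return DispersionEstimates(common, tagwise, prior_df)


# ---------------------------------------------------------------------------
# exact test


def _exact_nb_pvalues(
    s1: np.ndarray,
    total: np.ndarray,
    r1: np.ndarray,
    r2: np.ndarray,
    chunk_cells: int = 20_000_000,
) -> np.ndarray:
    """Two-sided conditional exact p-values, vectorized over genes.

    Conditioning on each gene's total pseudo-count, the first-group sum is
    distributed as the convolution split of two NB sums with sizes ``r1``
    and ``r2``; the two-sided p-value sums the probabilities of every split
    no more probable than the observed one.
    """
    s1 = np.asarray(s1, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    p = np.ones(total.size)

    # process in chunks bounded by total support size (memory control)
    lengths = total + 1
    csum = np.concatenate([[0], np.cumsum(lengths)])
    start = 0
    while start < total.size:
        stop = int(np.searchsorted(csum, csum[start] + chunk_cells, side="right")) - 1
        stop = min(max(stop, start + 1), total.size)
        sl = slice(start, stop)
        p[sl] = _exact_chunk(s1[sl], total[sl], r1[sl], r2[sl])
        start = stop
    return p


def _exact_chunk(s1, total, r1, r2) -> np.ndarray:
    lengths = total + 1
    offsets = np.zeros(lengths.size + 1, dtype=np.int64)
    np.cumsum(lengths, out=offsets[1:])
    gene = np.repeat(np.arange(lengths.size), lengths)
    x = np.arange(offsets[-1], dtype=np.int64) - offsets[:-1][gene]
    tg = total[gene]
    logc = (
        gammaln(x + r1[gene])
        - gammaln(x + 1.0)
        + gammaln(tg - x + r2[gene])
        - gammaln(tg - x + 1.0)
    )
    starts = offsets[:-1]
    mx = np.maximum.reduceat(logc, starts)
    w = np.exp(logc - mx[gene])
    z = np.add.reduceat(w, starts)
    obs_log = logc[starts + s1]
    include = logc <= obs_log[gene] + _TIE_LOGTOL
    num = np.add.reduceat(np.where(include, w, 0.0), starts)
    return np.minimum(num / z, 1.0)


def exact_test(
    cm: CountMatrix,
    labels,
    pair: tuple[str, str],
    nf: NormFactors,
    disp: DispersionEstimates,
    fdr: float = 0.10,
    min_fc: float = 1.5,
) -> pd.DataFrame:
    """Conditional NB exact test between ``pair = (treatment, control)``.

    Returns a frame with log2 fold change (treatment over control), p- and
    BH q-values, and the joint ``significant`` call
    (q <= fdr and \\|FC\\| >= min_fc).
    """
    labels = np.asarray(labels)
    treat, control = pair
    i1 = np.flatnonzero(labels == treat)
    i2 = np.flatnonzero(labels == control)
    if len(i1) == 0 or len(i2) == 0:
        raise ValueError(f"empty group in contrast {treat} vs {control}")
    extra = set(labels) - {treat, control}
    if extra:
        raise ValueError(f"exact test expects exactly two groups, extra: {sorted(extra)}")

    pseudo, _ = equalize_counts(cm, nf)
    s1 = pseudo[:, i1].sum(axis=1)
    s2 = pseudo[:, i2].sum(axis=1)
    total = s1 + s2
    n1, n2 = len(i1), len(i2)
    phi = np.maximum(np.asarray(disp.tagwise_phi, dtype=float), PHI_MIN)

    p = np.ones(total.size)
    nz = total > 0
    p[nz] = _exact_nb_pvalues(
        s1[nz], total[nz], n1 / phi[nz], n2 / phi[nz]
    )

    m1 = s1 / n1 + LOGFC_PRIOR
    m2 = s2 / n2 + LOGFC_PRIOR
    log2_fc = np.where(nz & (s1 * n2 != s2 * n1), np.log2(m1 / m2), 0.0)

    q = bh_adjust(p)
    res = pd.DataFrame(
        {
            "gene": cm.gene_ids,
            "log2_fc": log2_fc,
            "p_value": p,
            "q_value": q,
        }
    )
    res["significant"] = (res["q_value"] <= fdr) & (
        res["log2_fc"].abs() >= np.log2(min_fc)
    )
    res.attrs["contrast"] = f"{treat}_vs_{control}"
    res.attrs["fdr"] = fdr
    res.attrs["min_fc"] = min_fc
    return res


# ---------------------------------------------------------------------------
# multiplicity


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def independent_filter(
    results: pd.DataFrame,
    filter_stat: np.ndarray,
    fdr: float = 0.10,
    min_fc: float = 1.5,
    thetas: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Scan filter fractions, keep the one maximizing q<=fdr discoveries.

    ``filter_stat`` must be computed independently of the contrast under
    the null (overall mean normalized count across all samples). Returns
    the surviving genes with recomputed q-values and the chosen fraction.
    """
    filter_stat = np.asarray(filter_stat, dtype=float)
    if filter_stat.size != len(results):
        raise ValueError("filter_stat length does not match results")
    if thetas is None:
        thetas = np.round(np.arange(0.0, 0.5001, 0.01), 4)
    p = results["p_value"].to_numpy()
    m = p.size
    rank = np.argsort(np.argsort(filter_stat, kind="stable"), kind="stable")

    best_theta, best_hits, best_mask = 0.0, -1, None
    for theta in thetas:
        n_drop = int(np.floor(theta * m))
        keep = rank >= n_drop
        if not keep.any():
            continue
        q = bh_adjust(p[keep])
        hits = int((q <= fdr).sum())
        if hits > best_hits:
            best_theta, best_hits, best_mask = float(theta), hits, keep

    out = results.loc[best_mask].copy()
    out["q_value"] = bh_adjust(p[best_mask])
    out["significant"] = (out["q_value"] <= fdr) & (
        out["log2_fc"].abs() >= np.log2(min_fc)
    )
    out.attrs.update(results.attrs)
    out.attrs["filter_theta"] = best_theta
    return out, best_theta


def mean_normalized_count(cm: CountMatrix, nf: NormFactors) -> np.ndarray:
    """Overall mean normalized count per gene (the filter statistic)."""
    eff = nf.effective_lib_sizes
    common = float(np.exp(np.mean(np.log(eff))))
    return (cm.counts / eff[None, :] * common).mean(axis=1)


# ---------------------------------------------------------------------------
# convenience driver


def run_contrast(
    cm: CountMatrix,
    treat: str,
    control: str,
    time_label: str | None = None,
    treat_time: str | None = None,
    control_time: str | None = None,
    fdr: float = 0.10,
    min_fc: float = 1.5,
    prior_df: float = 10.0,
    filter_stat: np.ndarray | None = None,
    nf_full: NormFactors | None = None,
    apply_filter: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full DE pass for one pairwise contrast at one time point.

    Normalization factors and the independent-filter statistic may be
    supplied from the full matrix (recommended); otherwise they are
    computed on the contrast subset.
    """
    treat_time = treat_time or time_label
    control_time = control_time or time_label
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
    if nf_full is not None:
        nf = nf_full.subset(np.flatnonzero(mask))
    else:
        nf = tmm_factors(sub)
    disp = estimate_dispersion(sub, labels, nf, prior_df=prior_df)
    res = exact_test(sub, labels, (treat, control), nf, disp, fdr=fdr, min_fc=min_fc)
    theta = 0.0
    if apply_filter:
        if filter_stat is None:
            filter_stat = mean_normalized_count(cm, nf_full) if nf_full is not None \
                else mean_normalized_count(sub, nf)
        res, theta = independent_filter(res, filter_stat, fdr=fdr, min_fc=min_fc)
    info = {
        "contrast": f"{treat}_vs_{control}",
        "time": time_label or f"{treat_time}/{control_time}",
        "common_phi": disp.common_phi,
        "filter_theta": theta,
        "factors": dict(zip(nf.sample_ids, nf.factors.round(6))),
        "n_significant": int(res["significant"].sum()),
    }
    return res, info


__all__ = [
    "NormFactors",
    "DispersionEstimates",
    "tmm_factors",
    "equalize_counts",
    "cpm",
    "estimate_dispersion",
    "exact_test",
    "bh_adjust",
    "independent_filter",
    "mean_normalized_count",
    "run_contrast",
]
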