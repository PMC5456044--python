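"""Metabolite-level tests and pathway transcriptome-metabolome concordance.

Per-metabolite Welch t-tests on log2 abundances (raw p < 0.05, no
multiplicity correction — deliberate and recorded in output metadata),
pathway-level aggregation by Fisher's combined probability (min-p
alternative reported alongside), and the pathway x time-point concordance
grid restricted to transcriptome-recurrent pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MetaboliteMatrix

DEFAULT_MIN_N = 3
METABOLITE_ALPHA = 0.05


def test_metabolites(
    mm: MetaboliteMatrix,
    treat: str = "CS",
    control: str = "AC",
    treat_time: str | None = None,
    control_time: str | None = None,
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """Welch two-sample t-tests on log2 abundances for one contrast.

    Metabolites with fewer than ``min_n`` non-missing values in either
    group get status "untested" (p is NaN there, never an error).
    """
    sel1 = np.array(
        [
            s.group == treat and (treat_time is None or s.time_label == treat_time)
            for s in mm.samples
        ]
    )
    sel2 = np.array(
        [
            s.group == control
            and (control_time is None or s.time_label == control_time)
            for s in mm.samples
        ]
    )
    if not sel1.any() or not sel2.any():
        raise ValueError(f"empty group in contrast {treat} vs {control}")
    with np.errstate(divide="ignore"):
        log_ab = np.log2(mm.abundances)

    rows = []
    for i, mid in enumerate(mm.metabolite_ids):
        x = log_ab[i, sel1]
        y = log_ab[i, sel2]
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        n1, n2 = x.size, y.size
        if n1 < min_n or n2 < min_n:
            rows.append(
                dict(metabolite=mid, p_value=np.nan, direction=0, n_treat=n1,
                     n_control=n2, status="untested")
            )
            continue
        diff = float(x.mean() - y.mean())
        if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
            p = 1.0 if diff == 0.0 else 0.0
        else:
            p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
        rows.append(
            dict(
                metabolite=mid,
                p_value=p,
                direction=int(np.sign(diff)),
                n_treat=n1,
                n_control=n2,
                status="tested",
            )
        )
    out = pd.DataFrame(rows)
    out.attrs["contrast"] = f"{treat}_vs_{control}"
    out.attrs["multiplicity"] = "none (raw per-metabolite p-values)"
    return out


def fisher_combine(pvals) -> float:
    """Fisher's combined probability: chi^2(2k) tail of -2 * sum(ln p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    statistic = -2.0 * np.sum(np.log(np.clip(p, 1e-300, 1.0)))
    return float(stats.chi2.sf(statistic, 2 * p.size))


def pathway_metabolome_call(
    tests: pd.DataFrame,
    pathway: str,
    members: list[str],
    alpha: float = METABOLITE_ALPHA,
    method: str = "fisher",
) -> dict:
    """Aggregate member metabolite p-values into one pathway call.

    Both aggregations are always reported: Fisher's combined probability
    (default decision rule) and the minimum member p-value; ``method``
    selects which one drives ``significant``.
    """
    if method not in ("fisher", "minp"):
        raise ValueError("method must be 'fisher' or 'minp'")
    sub = tests[tests["metabolite"].isin(members) & (tests["status"] == "tested")]
    if sub.empty:
        return {
            "pathway": pathway,
            "status": "not_evaluable",
            "significant": False,
            "combined_p": np.nan,
            "min_p": np.nan,
            "n_tested": 0,
            "members_significant": [],
        }
    pvals = sub["p_value"].to_numpy()
    combined = fisher_combine(pvals)
    min_p = float(pvals.min())
    significant = (combined < alpha) if method == "fisher" else (min_p < alpha)
    return {
        "pathway": pathway,
        "status": "tested",
        "significant": bool(significant),
        "combined_p": combined,
        "min_p": min_p,
        "n_tested": int(len(sub)),
        "members_significant": list(sub.loc[sub["p_value"] < alpha, "metabolite"]),
    }


def recurring_pathways(grid: pd.DataFrame) -> list[str]:
    """Pathways significant (either direction) at two or more time points."""
    hits = (grid != 0).sum(axis=1)
    return [name for name, n in hits.items() if n >= 2]


@dataclass
class ConcordanceMatrix:
    """Pathway x time grid joining transcriptome direction and metabolome calls."""

    pathways: list[str]
    time_labels: list[str]  # exposure time points; cessation held separately
    transcriptome: pd.DataFrame  # codes "up"/"down"/"ns"; includes "cessation"
    metabolome: pd.DataFrame  # bool; includes "cessation"
    concordant: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        code = {"up": "U", "down": "D", "ns": "ns"}
        out = pd.DataFrame(index=self.pathways, columns=self.transcriptome.columns)
        for c in self.transcriptome.columns:
            t = self.transcriptome[c].map(code)
            m = self.metabolome[c].map({True: "M+", False: "M-"})
            out[c] = t + "/" + m
        out["concordant_multi"] = self.concordant
        out.index.name = "pathway"
        return out


def build_concordance(
    grid: pd.DataFrame,
    metabolite_tests_by_time: dict[str, pd.DataFrame],
    cessation_tests: pd.DataFrame,
    pathway_members: dict[str, list[str]],
    cessation_grid: pd.DataFrame | None = None,
    alpha: float = METABOLITE_ALPHA,
    method: str = "fisher",
) -> ConcordanceMatrix:
    """Concordance over pathways transcriptome-recurrent at >1 time point.

    ``grid`` is the CS-vs-AC enrichment direction grid (sets x time
    points, values +1/0/-1); the cessation column uses SS-vs-AC inputs.
    A pathway is flagged concordant at multiple time points when its
    metabolome call is significant at >=2 of the time points where it has
    a transcriptome signal.
    """
    rows = recurring_pathways(grid)
    times = list(grid.columns)
    cols = times + ["cessation"]
    tdir = pd.DataFrame("ns", index=rows, columns=cols)
    msig = pd.DataFrame(False, index=rows, columns=cols)

    for p in rows:
        for t in times:
            v = int(grid.loc[p, t])
            tdir.loc[p, t] = "up" if v > 0 else ("down" if v < 0 else "ns")
            tests = metabolite_tests_by_time.get(t)
            if tests is not None and p in pathway_members:
                call = pathway_metabolome_call(
                    tests, p, pathway_members[p], alpha=alpha, method=method
                )
                msig.loc[p, t] = call["significant"]
        if cessation_grid is not None and p in cessation_grid.index:
            v = int(cessation_grid.loc[p].iloc[0])
            tdir.loc[p, "cessation"] = "up" if v > 0 else ("down" if v < 0 else "ns")
        if p in pathway_members:
            call = pathway_metabolome_call(
                cessation_tests, p, pathway_members[p], alpha=alpha, method=method
            )
            msig.loc[p, "cessation"] = call["significant"]

    concordant = pd.Series(False, index=rows, dtype=bool)
    for p in rows:
        signal_times = [t for t in times if tdir.loc[p, t] != "ns"]
        n_conc = sum(bool(msig.loc[p, t]) for t in signal_times)
        concordant.loc[p] = n_conc >= 2
    return ConcordanceMatrix(
        pathways=rows,
        time_labels=times,
        transcriptome=tdir,
        metabolome=msig,
        concordant=concordant,
    )


__all__ = [
    "DEFAULT_MIN_N",
    "METABOLITE_ALPHA",
    "test_metabolites",
    "fisher_combine",
    "pathway_metabolome_call",
    "recurring_pathways",
    "ConcordanceMatrix",
    "build_concordance",
]
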