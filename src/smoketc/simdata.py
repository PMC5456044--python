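"""Synthetic count/metabolite generator with planted, recoverable truth.

Emulates the exposure design (AC and CS groups at 1d/7d/3mo/6mo/9mo plus a
cessation SS group at 9mo, ~5 animals per group): NB counts with gene-wise
dispersion, planted cessation patterns and time trends, pathway-coherent
gene-set effects, and metabolite shifts mirroring pathway direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    TIME_DAYS,
    CountMatrix,
    GeneSetDB,
    MetaboliteMatrix,
    SampleRecord,
)

DEFAULT_TIMES = ("1d", "7d", "3mo", "6mo", "9mo")

PATTERN_LABELS = (
    "reversible",
    "semi_reversible",
    "persistent",
    "semi_persistent",
    "continuing",
    "recovery",
)

TREND_CATEGORIES = (
    "quad_interaction",
    "linear_interaction",
    "group_plus_quad",
    "group_plus_linear",
    "group_only",
    "time_only",
)

#: SS latent mean position along the AC->CS gap, per planted pattern.
#: 0 = back at AC, 1 = still at CS. Chosen so that both the distance rule
#: and the |FC|>=1.5 significance filter can separate the semi classes at
#: the default planted effect of 2 log2 units.
SS_GAP_FRACTION = {
    "reversible": 0.0,
    "semi_reversible": 0.35,
    "persistent": 1.0,
    "semi_persistent": 0.65,
    "continuing": 1.5,
}


@dataclass
class GeneSetSpec:
    n_sets: int = 20
    size_range: tuple[int, int] = (10, 30)
    n_enriched_per_time: int = 3
    effect: float = 1.0  # coherent per-gene log2 shift in CS
    #: number of leading sets forced to be enriched at >=2 time points
    n_recurrent: int = 2
    #: recurrent sets whose metabolite shift persists in the SS group
    n_cessation_persistent: int = 1


@dataclass
class MetaboliteSpec:
    n_per_pathway: int = 8
    n_unmapped: int = 20
    shift_sd: float = 1.5  # shift in units of the log-abundance SD
    log_sd: float = 0.5
    missing_rate: float = 0.1


@dataclass
class SimulationSpec:
    n_genes: int = 2000
    n_per_group: int = 5
    time_labels: tuple[str, ...] = DEFAULT_TIMES
    baseline_logmean: tuple[float, float] = (4.0, 1.0)  # ln-scale (mu, sigma)
    dispersion: tuple[float, float, float] = (0.05, 2.0, 1.0)  # phi0, m, s
    library_sigma: float = 0.2
    #: pattern label -> (n_genes, log2 effect, fraction upregulated)
    pattern_table: dict = field(default_factory=dict)
    #: trend category -> (n_genes, amplitude in log2 over the course)
    trend_table: dict = field(default_factory=dict)
    geneset: GeneSetSpec = field(default_factory=GeneSetSpec)
    metabolite: MetaboliteSpec = field(default_factory=MetaboliteSpec)
    #: SS latent position along the AC->CS gap per pattern (see module default)
    ss_gap_fraction: dict = field(default_factory=lambda: dict(SS_GAP_FRACTION))
    seed: int = 0

    def validate(self) -> None:
        for label in self.pattern_table:
            if label not in PATTERN_LABELS:
                raise ValueError(f"unknown pattern label {label!r}")
        for cat in self.trend_table:
            if cat not in TREND_CATEGORIES:
                raise ValueError(f"unknown trend category {cat!r}")
        n_planted = sum(n for n, *_ in self.pattern_table.values())
        n_planted += sum(n for n, *_ in self.trend_table.values())
        if n_planted > self.n_genes:
            raise ValueError(
                f"{n_planted} planted genes exceed n_genes={self.n_genes}"
            )
        if not 0 <= self.metabolite.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        for label, (_, eff, *_rest) in self.pattern_table.items():
            if not np.isfinite(eff):
                raise ValueError(f"non-finite effect for pattern {label!r}")
        if "9mo" not in self.time_labels:
            raise ValueError("design must include the 9mo time point")


def default_spec(**overrides) -> SimulationSpec:
    """Spec with a representative planted-truth mix."""
    spec = SimulationSpec(
        pattern_table={
            "reversible": (60, 2.0, 0.5),
            "semi_reversible": (30, 2.0, 0.5),
            "persistent": (40, 2.0, 0.5),
            "semi_persistent": (30, 2.0, 0.5),
            "continuing": (20, 2.0, 0.5),
            "recovery": (20, 2.0, 0.5),
        },
        trend_table={
            "group_plus_linear": (20, 2.0),
            "group_plus_quad": (20, 2.0),
            "linear_interaction": (20, 2.0),
            "quad_interaction": (20, 2.0),
            "group_only": (10, 2.0),
            "time_only": (10, 2.0),
        },
    )
    for key, value in overrides.items():
        setattr(spec, key, value)
    spec.validate()
    return spec


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage."""

    #: gene -> (pattern label, direction "up"/"down")
    gene_pattern: dict
    #: gene -> trend category
    gene_trend: dict
    #: latent per-gene log2 offsets relative to AC baseline,
    #: indexed gene x "GROUP@time"
    latent_log2: pd.DataFrame
    #: gene -> {"CS_vs_AC@<t>": lfc, "SS_vs_CS": lfc, "SS_vs_AC": lfc}
    true_lfc: dict
    #: set name -> {time_label: +1 (up) or -1 (down)}
    set_direction: dict
    #: metabolite -> {time_label or "cessation": signed log2 shift}
    met_shift: dict
    #: the simulated gene-set database (planted sets draw from background genes)
    gene_sets: GeneSetDB | None = None
    #: true per-gene NB dispersions
    dispersion: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "gene_pattern": self.gene_pattern,
            "gene_trend": self.gene_trend,
            "true_lfc": self.true_lfc,
            "set_direction": self.set_direction,
            "met_shift": self.met_shift,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------


def make_design(spec: SimulationSpec) -> list[SampleRecord]:
    samples = []
    for t in spec.time_labels:
        for group in ("AC", "CS"):
            for k in range(spec.n_per_group):
                samples.append(
                    SampleRecord(f"{group}_{t}_{k + 1}", group, t)
                )
    for k in range(spec.n_per_group):
        samples.append(SampleRecord(f"SS_9mo_{k + 1}", "SS", "9mo"))
    return samples


def _time_curve(times_days: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude linear and u-shaped curves over the observed days."""
    u = (times_days - times_days.min()) / (times_days.max() - times_days.min())
    lin = u
    quad = 4.0 * (u - 0.5) ** 2  # 1 at endpoints, 0 at midpoint
    return lin, quad


def simulate_counts(spec: SimulationSpec) -> tuple[CountMatrix, GroundTruth]:
    """Draw NB counts under the planted latent-mean model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    samples = make_design(spec)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]

    mu0, sd0 = spec.baseline_logmean
    baseline = np.exp(rng.normal(mu0, sd0, size=spec.n_genes))
    phi0, m, s = spec.dispersion
    phi = phi0 + 1.0 / np.exp(rng.normal(m, s, size=spec.n_genes))
    lib = np.exp(rng.normal(0.0, spec.library_sigma, size=len(samples)))

    cells = [f"{g}@{t}" for g in ("AC", "CS", "SS") for t in spec.time_labels]
    latent = pd.DataFrame(0.0, index=genes, columns=cells)

    gene_pattern: dict[str, tuple[str, str]] = {}
    gene_trend: dict[str, str] = {}
    true_lfc: dict[str, dict[str, float]] = {}

    cursor = 0
    # --- cessation patterns (effects at 9mo) ---
    for label in PATTERN_LABELS:
        if label not in spec.pattern_table:
            continue
        n, eff, frac_up = spec.pattern_table[label]
        for k in range(n):
            g = genes[cursor]
            cursor += 1
            sign = 1.0 if (k < round(frac_up * n)) else -1.0
            d = sign * eff
            if label == "recovery":
                cs, ss = 0.0, d
            else:
                cs = d
                ss = spec.ss_gap_fraction[label] * d
            latent.loc[g, "CS@9mo"] = cs
            latent.loc[g, "SS@9mo"] = ss
            gene_pattern[g] = (label, "up" if sign > 0 else "down")
            true_lfc[g] = {
                "CS_vs_AC@9mo": cs,
                "SS_vs_CS": ss - cs,
                "SS_vs_AC": ss,
            }

    # --- time trends (AC/CS across all time points) ---
    days = np.array([TIME_DAYS[t] for t in spec.time_labels], dtype=float)
    lin, quad = _time_curve(days)
    for cat in TREND_CATEGORIES:
        if cat not in spec.trend_table:
            continue
        n, amp = spec.trend_table[cat]
        for k in range(n):
            g = genes[cursor]
            cursor += 1
            sign = 1.0 if k % 2 == 0 else -1.0
            a = sign * amp
            offset = a / 2.0
            for j, t in enumerate(spec.time_labels):
                if cat == "group_plus_linear":
                    latent.loc[g, f"AC@{t}"] = a * lin[j]
                    latent.loc[g, f"CS@{t}"] = a * lin[j] + offset
                elif cat == "group_plus_quad":
                    latent.loc[g, f"AC@{t}"] = a * quad[j]
                    latent.loc[g, f"CS@{t}"] = a * quad[j] + offset
                elif cat == "linear_interaction":
                    latent.loc[g, f"CS@{t}"] = a * lin[j]
                elif cat == "quad_interaction":
                    latent.loc[g, f"CS@{t}"] = a * quad[j]
                elif cat == "group_only":
                    latent.loc[g, f"CS@{t}"] = offset
                elif cat == "time_only":
                    latent.loc[g, f"AC@{t}"] = a * lin[j]
                    latent.loc[g, f"CS@{t}"] = a * lin[j]
            gene_trend[g] = cat

    # --- pathway-coherent gene-set effects on background genes ---
    gs = spec.geneset
    background = genes[cursor:]
    set_names = [f"SET{k:03d}" for k in range(gs.n_sets)]
    sets: dict[str, list[str]] = {}
    set_direction: dict[str, dict[str, int]] = {}
    for name in set_names:
        size = int(rng.integers(gs.size_range[0], gs.size_range[1] + 1))
        size = min(size, len(background))
        if size < 1:
            continue  # no unplanted genes left to form sets from
        members = list(rng.choice(background, size=size, replace=False))
        sets[name] = members
    set_names = list(sets)

    n_times = len(spec.time_labels)
    for k, name in enumerate(set_names):
        plan: dict[str, int] = {}
        if k < gs.n_recurrent:
            t1, t2 = spec.time_labels[k % n_times], spec.time_labels[(k + 2) % n_times]
            direction = 1 if k % 2 == 0 else -1
            plan = {t1: direction, t2: direction}
        elif k < gs.n_recurrent + gs.n_enriched_per_time:
            t1 = spec.time_labels[k % n_times]
            plan = {t1: 1 if k % 2 == 0 else -1}
        if plan:
            set_direction[name] = plan
            for t, direction in plan.items():
                col = f"CS@{t}"
                latent.loc[sets[name], col] = (
                    latent.loc[sets[name], col] + direction * gs.effect
                )

    # --- draw counts ---
    mu = np.empty((spec.n_genes, len(samples)))
    latent_vals = latent.to_numpy()
    col_index = {c: j for j, c in enumerate(latent.columns)}
    for j, sam in enumerate(samples):
        delta = latent_vals[:, col_index[f"{sam.group}@{sam.time_label}"]]
        mu[:, j] = lib[j] * baseline * np.exp2(delta)
    counts = _rnbinom(rng, mu, phi)

    cm = CountMatrix(gene_ids=genes, samples=samples, counts=counts)
    truth = GroundTruth(
        gene_pattern=gene_pattern,
        gene_trend=gene_trend,
        latent_log2=latent,
        true_lfc=true_lfc,
        set_direction=set_direction,
        met_shift={},
        gene_sets=GeneSetDB(sets=dict(sets)) if sets else GeneSetDB(sets={}),
        dispersion=phi,
    )
    return cm, truth


def _rnbinom(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB draws with variance mu + phi*mu^2 (Poisson when phi ~ 0)."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float)[:, None], mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = phi < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_metabolites(
    spec: SimulationSpec, truth: GroundTruth
) -> MetaboliteMatrix:
    """Log-normal metabolite abundances mirroring the planted set effects.

    Metabolites of an enriched pathway are shifted (in CS at the enriched
    time points) by ``shift_sd`` log-SD units in the pathway's direction;
    for the leading ``n_cessation_persistent`` recurrent pathways the shift
    also persists in the SS group. Missing entries are inserted completely
    at random.
    """
    ms = spec.metabolite
    rng = np.random.default_rng(spec.seed + 104729)  # independent stream
    samples = make_design(spec)

    pathway_names = list(truth.set_direction)
    met_ids: list[str] = []
    pathway_map: dict[str, list[str]] = {}
    met_pathway: dict[str, str | None] = {}
    for p in pathway_names:
        for k in range(ms.n_per_pathway):
            mid = f"{p}_met{k:02d}"
            met_ids.append(mid)
            pathway_map[mid] = [p]
            met_pathway[mid] = p
    for k in range(ms.n_unmapped):
        mid = f"free_met{k:03d}"
        met_ids.append(mid)
        met_pathway[mid] = None

    persist = set(pathway_names[: spec.geneset.n_cessation_persistent])
    base = rng.normal(6.0, 1.0, size=len(met_ids))
    log_abund = (
        base[:, None] + rng.normal(0.0, ms.log_sd, size=(len(met_ids), len(samples)))
    )

    met_shift: dict[str, dict[str, float]] = {}
    for i, mid in enumerate(met_ids):
        p = met_pathway[mid]
        if p is None:
            continue
        plan = truth.set_direction[p]
        shifts: dict[str, float] = {}
        for t, direction in plan.items():
            shift = direction * ms.shift_sd * ms.log_sd
            shifts[t] = shift * np.log2(np.e)  # report on log2 scale
            for j, sam in enumerate(samples):
                if sam.group == "CS" and sam.time_label == t:
                    log_abund[i, j] += shift
        if p in persist:
            direction = next(iter(plan.values()))
            shift = direction * ms.shift_sd * ms.log_sd
            shifts["cessation"] = shift * np.log2(np.e)
            for j, sam in enumerate(samples):
                if sam.group == "SS":
                    log_abund[i, j] += shift
        if shifts:
            met_shift[mid] = shifts

    abund = np.exp(log_abund)
    if ms.missing_rate > 0:
        mask = rng.random(abund.shape) < ms.missing_rate
        abund[mask] = np.nan

    truth.met_shift = met_shift
    return MetaboliteMatrix(
        metabolite_ids=met_ids,
        samples=samples,
        abundances=abund,
        pathway_map=pathway_map,
    )


__all__ = [
    "DEFAULT_TIMES",
    "PATTERN_LABELS",
    "TREND_CATEGORIES",
    "SS_GAP_FRACTION",
    "GeneSetSpec",
    "MetaboliteSpec",
    "SimulationSpec",
    "GroundTruth",
    "default_spec",
    "make_design",
    "simulate_counts",
    "simulate_metabolites",
]
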