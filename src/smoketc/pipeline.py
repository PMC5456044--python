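"""End-to-end orchestration: simulate/load -> DE -> enrichment -> patterns
-> trends -> concordance, with summary tables and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import concord, de_core, enrich, patterns, simdata, trends
from .io_formats import (
    FormatError,
    load_config,
    read_counts,
    read_gmt,
    read_metabolites,
    write_counts,
    write_design,
    write_gmt,
    write_metabolites,
)

logger = logging.getLogger("smoketc")

PIPELINE_VERSION = "0.1.0"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def simulate_inputs(cfg: dict, outdir: Path):
    """Generate the synthetic inputs and persist them as text files."""
    sim_cfg = cfg.get("simulate", {}) or {}
    spec = simdata.default_spec(seed=int(cfg.get("seed", 0)))
    for key in ("n_genes", "n_per_group", "library_sigma"):
        if key in sim_cfg:
            setattr(spec, key, sim_cfg[key])
    if "pattern_table" in sim_cfg:
        spec.pattern_table = {
            k: tuple(v) for k, v in sim_cfg["pattern_table"].items()
        }
    if "trend_table" in sim_cfg:
        spec.trend_table = {k: tuple(v) for k, v in sim_cfg["trend_table"].items()}
    spec.validate()
    cm, truth = simdata.simulate_counts(spec)
    mm = simdata.simulate_metabolites(spec, truth)
    sets = truth.gene_sets
    write_counts(cm, outdir / "counts.tsv")
    write_design(cm.samples, outdir / "design.tsv")
    write_gmt(sets, outdir / "sets.gmt")
    write_metabolites(mm, outdir / "metabolites.tsv", outdir / "metabolite_map.tsv")
    truth.to_json(outdir / "truth.json")
    return cm, sets, mm, truth


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Run every stage and write stage outputs, summaries and the manifest."""
    if not isinstance(config, dict):
        cfg = load_config(config)
    else:
        cfg = load_config(None, **config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "pipeline_version": PIPELINE_VERSION,
        "config": {k: v for k, v in cfg.items() if k != "simulate" or v},
        "seed": int(cfg.get("seed", 0)),
        "thresholds": {
            "fdr": cfg["fdr"],
            "min_fc": cfg["min_fc"],
            "metabolite_alpha": cfg["metabolite_alpha"],
        },
        "decisions": {
            "pattern_tie_break": "semi split by |log2FC(SSvAC)| vs |log2FC(SSvCS)|",
            "metabolome_aggregation": cfg.get("aggregation", "fisher"),
            "trend_error_control": "BH within tier across genes still in play",
            "metabolite_multiplicity": "none (raw p < alpha)",
        },
        "stages": {},
        "skipped": [],
    }

    # --- inputs ---
    stage = "input"
    try:
        if "counts" in cfg and "design" in cfg:
            cm = read_counts(cfg["counts"], cfg["design"])
            sets = read_gmt(cfg["gene_sets"]) if "gene_sets" in cfg else None
            mm = None
            if "metabolites" in cfg and "metabolite_map" in cfg:
                mm = read_metabolites(
                    cfg["metabolites"],
                    cfg["metabolite_map"],
                    cfg["design"],
                    missing_token=cfg["missing_token"],
                )
        else:
            cm, sets, mm, _truth = simulate_inputs(cfg, outdir)
    except (FormatError, OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    cm = cm.drop_excluded(include_excluded=bool(cfg["include_excluded_times"]))
    time_labels = [
        t
        for t in ("1d", "7d", "1mo", "3mo", "6mo", "9mo")
        if any(s.time_label == t and s.group == "CS" for s in cm.samples)
    ]
    fdr, min_fc = float(cfg["fdr"]), float(cfg["min_fc"])

    # --- normalization shared across contrasts ---
    stage = "normalize"
    try:
        nf = de_core.tmm_factors(cm)
        filter_stat = de_core.mean_normalized_count(cm, nf)
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"]["normalize"] = {
        "factors": dict(zip(nf.sample_ids, np.round(nf.factors, 6).tolist()))
    }

    # --- differential expression ---
    stage = "de"
    de_tables: dict[str, pd.DataFrame] = {}
    de_info: dict[str, dict] = {}
    contrasts = [(f"CS_vs_AC@{t}", "CS", "AC", t, t) for t in time_labels]
    has_ss = any(s.group == "SS" for s in cm.samples)
    if has_ss:
        contrasts += [
            ("SS_vs_CS", "SS", "CS", "9mo", "9mo"),
            ("SS_vs_AC", "SS", "AC", "9mo", "9mo"),
        ]
    try:
        for key, treat, control, tt, ct in contrasts:
            res, info = de_core.run_contrast(
                cm,
                treat,
                control,
                treat_time=tt,
                control_time=ct,
                fdr=fdr,
                min_fc=min_fc,
                prior_df=float(cfg["prior_df"]),
                filter_stat=filter_stat,
                nf_full=nf,
            )
            de_tables[key] = res
            de_info[key] = info
            _write_tsv(res, outdir / f"de_{key.replace('@', '_')}.tsv")
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"]["de"] = de_info

    # --- enrichment ---
    stage = "enrich"
    enr_tables: dict[str, pd.DataFrame] = {}
    grid = cess_grid = None
    if sets is not None:
        try:
            by_time = enrich.enrich_timepoints(
                cm, sets, time_labels, pair=("CS", "AC"), nf=nf, fdr=fdr,
                min_set_size=int(cfg["min_set_size"]),
            )
            enr_tables.update({f"CS_vs_AC@{t}": tab for t, tab in by_time.items()})
            grid = enrich.significance_grid(by_time)
            if has_ss:
                for key, treat, control in (
                    ("SS_vs_CS", "SS", "CS"),
                    ("SS_vs_AC", "SS", "AC"),
                ):
                    enr_tables[key] = enrich.enrich_contrast(
                        cm, sets, treat, control, treat_time="9mo",
                        control_time="9mo", nf=nf, fdr=fdr,
                        min_set_size=int(cfg["min_set_size"]),
                    )
                cess_grid = enrich.significance_grid(
                    {"cessation": enr_tables["SS_vs_AC"]}
                )
            for key, tab in enr_tables.items():
                out = tab.copy()
                out["core_genes"] = out["core_genes"].map(";".join)
                out["n_core"] = tab["core_genes"].map(len)
                _write_tsv(out, outdir / f"enrich_{key.replace('@', '_')}.tsv")
            _write_tsv(grid, outdir / "enrich_grid.tsv", index=True)
        except ValueError as exc:
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"]["enrich"] = {
            k: int(tab["significant"].sum()) for k, tab in enr_tables.items()
        }
    else:
        manifest["skipped"].append("enrich (no gene sets provided)")

    # --- cessation patterns ---
    stage = "patterns"
    gene_summary = path_summary = None
    if has_ss:
        calls = patterns.classify_genes(
            de_tables["CS_vs_AC@9mo"], de_tables["SS_vs_CS"], de_tables["SS_vs_AC"]
        )
        gene_summary = patterns.summarize_patterns(calls)
        recovery = patterns.find_recovery_genes(
            de_tables["SS_vs_CS"],
            {t: de_tables[f"CS_vs_AC@{t}"] for t in time_labels},
            de_tables["SS_vs_AC"],
            month9_only=bool(cfg.get("recovery_month9_only", True)),
        )
        _write_tsv(calls, outdir / "pattern_calls.tsv")
        _write_tsv(gene_summary.to_frame(), outdir / "pattern_summary_genes.tsv",
                   index=True)
        (outdir / "recovery_genes.txt").write_text("\n".join(recovery) + "\n")
        manifest["stages"]["patterns"] = {
            "n_classified": gene_summary.total,
            "n_recovery": len(recovery),
            "tie_break": "distance rule on |log2FC|",
        }
        if sets is not None:
            path_calls, path_summary = patterns.classify_pathways(
                enr_tables["CS_vs_AC@9mo"],
                enr_tables["SS_vs_CS"],
                enr_tables["SS_vs_AC"],
            )
            _write_tsv(path_calls, outdir / "pattern_calls_pathways.tsv")
            _write_tsv(
                path_summary.to_frame(),
                outdir / "pattern_summary_pathways.tsv",
                index=True,
            )
    else:
        manifest["skipped"].append("patterns (no SS group)")

    # --- time trends ---
    stage = "trends"
    trend_res = None
    if len(time_labels) >= 3:
        trend_res = trends.trend_analysis(
            cm, time_labels=tuple(time_labels), alpha=fdr, nf=nf
        )
        _write_tsv(trend_res.reset_index(), outdir / "trend_results.tsv")
        manifest["stages"]["trends"] = {
            "categories": trend_res["category"].value_counts().to_dict(),
            "error_control": trend_res.attrs["error_control"],
        }
    else:
        manifest["skipped"].append("trends (<3 usable time points)")

    # --- concordance ---
    stage = "concord"
    conc = None
    if mm is not None and grid is not None:
        met_tests = {
            t: concord.test_metabolites(mm, "CS", "AC", t, t) for t in time_labels
        }
        cess_tests = concord.test_metabolites(mm, "SS", "AC", "9mo", "9mo")
        conc = concord.build_concordance(
            grid,
            met_tests,
            cess_tests,
            mm.pathway_members(),
            cessation_grid=cess_grid,
            alpha=float(cfg["metabolite_alpha"]),
            method=cfg.get("aggregation", "fisher"),
        )
        for t, tab in met_tests.items():
            _write_tsv(tab, outdir / f"metabolites_CS_vs_AC_{t}.tsv")
        _write_tsv(cess_tests, outdir / "metabolites_SS_vs_AC_9mo.tsv")
        _write_tsv(conc.to_frame(), outdir / "concordance.tsv", index=True)
        manifest["stages"]["concord"] = {
            "n_recurring": len(conc.pathways),
            "n_concordant_multi": int(conc.concordant.sum()),
        }
    else:
        manifest["skipped"].append("concord (no metabolite matrix or no sets)")

    # --- summary tables ---
    t1 = table1(de_tables, enr_tables, time_labels)
    _write_tsv(t1, outdir / "table1_counts.tsv", index=True)

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.is_file()
    }
    manifest["runtime_seconds"] = round(time.time() - t0, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline finished in %.1fs -> %s", time.time() - t0, outdir)
    return outdir


def table1(
    de_tables: dict[str, pd.DataFrame],
    enr_tables: dict[str, pd.DataFrame],
    time_labels,
) -> pd.DataFrame:
    """Counts of significant up/down genes and pathways per contrast."""
    cols = [f"CS_vs_AC@{t}" for t in time_labels] + [
        c for c in ("SS_vs_CS", "SS_vs_AC") if c in de_tables
    ]
    rows = {}
    for kind, tables in (("genes", de_tables), ("pathways", enr_tables)):
        up, down = [], []
        for c in cols:
            tab = tables.get(c)
            if tab is None or tab.empty:
                up.append(0)
                down.append(0)
            elif kind == "genes":
                sig = tab[tab["significant"]]
                up.append(int((sig["log2_fc"] > 0).sum()))
                down.append(int((sig["log2_fc"] < 0).sum()))
            else:
                sig = tab[tab["significant"]]
                up.append(int((sig["direction"] == "up").sum()))
                down.append(int((sig["direction"] == "down").sum()))
        rows[f"{kind}_up"] = up
        rows[f"{kind}_down"] = down
    return pd.DataFrame(rows, index=cols).T


__all__ = ["run_pipeline", "simulate_inputs", "table1", "PipelineError"]
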