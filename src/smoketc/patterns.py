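"""Cessation-pattern classification from the three month-9 contrasts.

A gene (or enriched pathway) is classified from the triple of pairwise
results CS-vs-AC (month 9), SS-vs-CS, and SS-vs-AC into
reversible / semi-reversible / persistent / semi-persistent / continuing,
with separately identified recovery genes (changes unique to SS-vs-CS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PATTERN_ORDER = (
    "reversible",
    "semi_reversible",
    "persistent",
    "semi_persistent",
    "continuing",
)
ALL_LABELS = PATTERN_ORDER + ("recovery", "unclassified")


@dataclass(frozen=True)
class ContrastTriple:
    """Per-gene (significance, signed log2FC) for the three contrasts."""

    gene: str
    sig_cs_ac: bool
    fc_cs_ac: float
    sig_ss_cs: bool
    fc_ss_cs: float
    sig_ss_ac: bool
    fc_ss_ac: float


@dataclass(frozen=True)
class PatternCall:
    gene: str
    label: str
    direction: str | None  # in CS vs AC; for recovery, in SS vs CS


def _sign(x: float) -> int:
    return int(np.sign(x))


def classify_gene(t: ContrastTriple) -> PatternCall:
    """Apply the cessation decision rules, in order of precedence.

    reversible: DE in CS-vs-AC, SS moved back (SS-vs-CS significant in the
    opposite direction) and indistinguishable from AC. persistent: DE in
    CS-vs-AC and SS-vs-AC with the same sign, SS indistinguishable from CS.
    semi classes: DE in all three, split by whether SS sits closer to AC
    (semi-reversible) or to CS (semi-persistent). continuing: the SS-vs-AC
    gap exceeds the original CS-vs-AC gap, same sign. recovery: DE only in
    SS-vs-CS.
    """
    s_a, s_b, s_c = _sign(t.fc_cs_ac), _sign(t.fc_ss_cs), _sign(t.fc_ss_ac)
    direction = "up" if s_a > 0 else ("down" if s_a < 0 else None)

    if t.sig_cs_ac and t.sig_ss_cs and s_b == -s_a != 0 and not t.sig_ss_ac:
        return PatternCall(t.gene, "reversible", direction)
    if t.sig_cs_ac and t.sig_ss_ac and s_c == s_a != 0 and not t.sig_ss_cs:
        return PatternCall(t.gene, "persistent", direction)
    if (
        t.sig_cs_ac
        and t.sig_ss_cs
        and t.sig_ss_ac
        and s_b == -s_a != 0
        and s_c == s_a
    ):
        if abs(t.fc_ss_ac) < abs(t.fc_ss_cs):
            return PatternCall(t.gene, "semi_reversible", direction)
        return PatternCall(t.gene, "semi_persistent", direction)
    if t.sig_ss_ac and s_c == s_a != 0 and abs(t.fc_ss_ac) > abs(t.fc_cs_ac):
        return PatternCall(t.gene, "continuing", direction)
    if t.sig_ss_cs and not t.sig_cs_ac and not t.sig_ss_ac:
        rec_dir = "up" if s_b > 0 else ("down" if s_b < 0 else None)
        return PatternCall(t.gene, "recovery", rec_dir)
    return PatternCall(t.gene, "unclassified", direction)


def build_triples(
    de_cs_ac: pd.DataFrame,
    de_ss_cs: pd.DataFrame,
    de_ss_ac: pd.DataFrame,
) -> list[ContrastTriple]:
    """Join the three DE tables into per-gene triples.

    Genes missing from a table (e.g. removed by independent filtering)
    count as not significant there with log2FC taken as 0.
    """
    frames = {"a": de_cs_ac, "b": de_ss_cs, "c": de_ss_ac}
    # gene order: union preserving first appearance
    genes: list[str] = []
    seen: set[str] = set()
    for df in frames.values():
        for g in df["gene"]:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    lookup = {
        key: df.set_index("gene")[["log2_fc", "significant"]]
        for key, df in frames.items()
    }

    def fetch(key: str, g: str) -> tuple[bool, float]:
        tab = lookup[key]
        if g in tab.index:
            row = tab.loc[g]
            return bool(row["significant"]), float(row["log2_fc"])
        return False, 0.0

    triples = []
    for g in genes:
        sa, fa = fetch("a", g)
        sb, fb = fetch("b", g)
        sc, fc = fetch("c", g)
        triples.append(ContrastTriple(g, sa, fa, sb, fb, sc, fc))
    return triples


def classify_genes(
    de_cs_ac: pd.DataFrame,
    de_ss_cs: pd.DataFrame,
    de_ss_ac: pd.DataFrame,
) -> pd.DataFrame:
    """Classify every gene significant in at least one of the contrasts."""
    triples = [
        t
        for t in build_triples(de_cs_ac, de_ss_cs, de_ss_ac)
        if t.sig_cs_ac or t.sig_ss_cs or t.sig_ss_ac
    ]
    calls = [classify_gene(t) for t in triples]
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "label": [c.label for c in calls],
            "direction": [c.direction for c in calls],
            "log2_fc_cs_ac": [t.fc_cs_ac for t in triples],
            "log2_fc_ss_cs": [t.fc_ss_cs for t in triples],
            "log2_fc_ss_ac": [t.fc_ss_ac for t in triples],
        }
    )


def find_recovery_genes(
    de_ss_cs: pd.DataFrame,
    de_cs_ac_by_time: dict[str, pd.DataFrame],
    de_ss_ac: pd.DataFrame,
    month9_only: bool = True,
) -> list[str]:
    """Genes whose differential expression is unique to SS-vs-CS.

    Significant in SS-vs-CS, not significant in SS-vs-AC, and not
    significant in the CS-vs-AC contrast at month 9 (default) or at any
    time point (``month9_only=False``).
    """
    sig_b = set(de_ss_cs.loc[de_ss_cs["significant"], "gene"])
    sig_c = set(de_ss_ac.loc[de_ss_ac["significant"], "gene"])
    if month9_only:
        tables = [de_cs_ac_by_time["9mo"]]
    else:
        tables = list(de_cs_ac_by_time.values())
    sig_a: set[str] = set()
    for tab in tables:
        sig_a |= set(tab.loc[tab["significant"], "gene"])
    return [g for g in de_ss_cs["gene"] if g in sig_b and g not in sig_a and g not in sig_c]


@dataclass
class PatternSummary:
    """Counts by pattern x direction plus percentages of the classified total.

    The percentage denominator covers the five CS-vs-AC cessation patterns
    (recovery and unclassified genes are excluded from it).
    """

    counts: pd.DataFrame  # index PATTERN_ORDER, columns ["up", "down"]

    @classmethod
    def from_counts(cls, up, down) -> "PatternSummary":
        up = list(up)
        down = list(down)
        if len(up) != len(PATTERN_ORDER) or len(down) != len(PATTERN_ORDER):
            raise ValueError(
                f"expected {len(PATTERN_ORDER)} counts per direction "
                f"in order {PATTERN_ORDER}"
            )
        counts = pd.DataFrame(
            {"up": up, "down": down}, index=list(PATTERN_ORDER), dtype=int
        )
        return cls(counts)

    @classmethod
    def from_calls(cls, calls: pd.DataFrame) -> "PatternSummary":
        counts = pd.DataFrame(0, index=list(PATTERN_ORDER), columns=["up", "down"])
        relevant = calls[calls["label"].isin(PATTERN_ORDER)]
        for _, row in relevant.iterrows():
            if row["direction"] in ("up", "down"):
                counts.loc[row["label"], row["direction"]] += 1
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def label_total(self, label: str) -> int:
        return int(self.counts.loc[label].sum())

    def percent(self, label: str, ndigits: int = 2) -> float:
        if self.total == 0:
            return 0.0
        return round(100.0 * self.label_total(label) / self.total, ndigits)

    def percent_reversible_or_semi(self, ndigits: int = 1) -> float:
        """Share of classified entries fully or partially (semi-) reversible."""
        if self.total == 0:
            return 0.0
        n = self.label_total("reversible") + self.label_total("semi_reversible")
        return round(100.0 * n / self.total, ndigits)

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.T.copy()
        out.index = ["Up (CS)", "Down (CS)"]
        pct = {lab: self.percent(lab) for lab in PATTERN_ORDER}
        out.loc["% of Total"] = [pct[lab] for lab in PATTERN_ORDER]
        return out


def summarize_patterns(calls: pd.DataFrame) -> PatternSummary:
    return PatternSummary.from_calls(calls)


# ---------------------------------------------------------------------------
# pathway-level classification


def _set_call(tab: pd.DataFrame, name: str) -> tuple[bool, float]:
    """(significant, signed magnitude) for one set in one enrichment table."""
    rows = tab[tab["set"] == name]
    if rows.empty:
        return False, 0.0
    sig_rows = rows[rows["significant"]]
    pick = sig_rows if len(sig_rows) else rows
    best = pick.loc[pick["p_value"].idxmin()]
    sign = 1.0 if best["direction"] == "up" else -1.0
    return bool(len(sig_rows)), sign * abs(float(best["set_stat"]))


def classify_pathways(
    enr_cs_ac: pd.DataFrame,
    enr_ss_cs: pd.DataFrame,
    enr_ss_ac: pd.DataFrame,
) -> tuple[pd.DataFrame, PatternSummary]:
    """Apply the gene rule set at pathway level (set_stat as magnitude)."""
    names: list[str] = []
    seen: set[str] = set()
    for tab in (enr_cs_ac, enr_ss_cs, enr_ss_ac):
        for s in tab["set"]:
            if s not in seen:
                seen.add(s)
                names.append(s)
    triples = []
    for name in names:
        sa, fa = _set_call(enr_cs_ac, name)
        sb, fb = _set_call(enr_ss_cs, name)
        sc, fc = _set_call(enr_ss_ac, name)
        if sa or sb or sc:
            triples.append(ContrastTriple(name, sa, fa, sb, fb, sc, fc))
    calls = [classify_gene(t) for t in triples]
    frame = pd.DataFrame(
        {
            "set": [c.gene for c in calls],
            "label": [c.label for c in calls],
            "direction": [c.direction for c in calls],
        }
    )
    summary = PatternSummary.from_calls(frame.rename(columns={"set": "gene"}))
    return frame, summary


__all__ = [
    "PATTERN_ORDER",
    "ALL_LABELS",
    "ContrastTriple",
    "PatternCall",
    "classify_gene",
    "build_triples",
    "classify_genes",
    "find_recovery_genes",
    "PatternSummary",
    "summarize_patterns",
    "classify_pathways",
]
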