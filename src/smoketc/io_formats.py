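"""Readers/writers for the pipeline's external formats plus design validation.

All tabular formats are tab-delimited text. Counts and metabolite
abundances are stored genes/metabolites-in-rows with a header row of
sample ids; the sample design is a three-column table
(sample_id, group, time_label); gene sets use GMT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

logger = logging.getLogger("smoketc")

GROUPS = ("AC", "CS", "SS")
TIME_LABELS = ("1d", "7d", "1mo", "3mo", "6mo", "9mo")

#: Day equivalents used for contrast spacing (months taken as 30 days).
TIME_DAYS = {"1d": 1, "7d": 7, "1mo": 30, "3mo": 90, "6mo": 180, "9mo": 270}

#: Time points excluded from analysis by default (QC exclusion); a config
#: switch re-includes them.
EXCLUDED_TIME_LABELS = ("1mo",)

DEFAULT_MISSING_TOKEN = "NA"


class FormatError(ValueError):
    """A malformed input file or an inconsistent sample design."""


@dataclass(frozen=True)
class SampleRecord:
    """One sample of the exposure design."""

    sample_id: str
    group: str
    time_label: str
    time_days: float = field(default=0.0)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown group {self.group!r} "
                f"(expected one of {GROUPS})"
            )
        if self.time_label not in TIME_LABELS:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown time label "
                f"{self.time_label!r} (expected one of {TIME_LABELS})"
            )
        if self.group == "SS" and self.time_label != "9mo":
            raise FormatError(
                f"sample {self.sample_id!r}: SS (cessation) samples exist "
                f"only at 9mo, got {self.time_label!r}"
            )
        expected = TIME_DAYS[self.time_label]
        if self.time_days == 0.0:
            object.__setattr__(self, "time_days", float(expected))
        elif self.time_days != expected:
            raise FormatError(
                f"sample {self.sample_id!r}: time_days={self.time_days} "
                f"inconsistent with {self.time_label!r} (expected {expected})"
            )


@dataclass
class CountMatrix:
    """Integer gene-by-sample counts with the sample design attached."""

    gene_ids: list[str]
    samples: list[SampleRecord]
    counts: np.ndarray  # shape (n_genes, n_samples), non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count for gene {self.gene_ids[g]!r} in sample "
                f"{self.samples[s].sample_id!r}"
            )
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise FormatError(f"duplicate gene id {g!r}")
            seen.add(g)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample id {dup[0]!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def select_samples(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            samples=[self.samples[i] for i in idx],
            counts=self.counts[:, idx].copy(),
        )

    def select_genes(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            samples=list(self.samples),
            counts=self.counts[idx, :].copy(),
        )

    def subset(self, group: str | None = None, time_label: str | None = None) -> "CountMatrix":
        mask = np.array(
            [
                (group is None or s.group == group)
                and (time_label is None or s.time_label == time_label)
                for s in self.samples
            ]
        )
        return self.select_samples(mask)

    def drop_excluded(self, include_excluded: bool = False) -> "CountMatrix":
        """Drop samples at QC-excluded time points unless re-included."""
        if include_excluded:
            return self
        mask = np.array(
            [s.time_label not in EXCLUDED_TIME_LABELS for s in self.samples]
        )
        n_dropped = int((~mask).sum())
        if n_dropped:
            logger.info(
                "dropping %d sample(s) at excluded time point(s) %s",
                n_dropped,
                EXCLUDED_TIME_LABELS,
            )
        return self.select_samples(mask)


@dataclass
class GeneSetDB:
    """Named gene sets (deduplicated, order-preserving member lists)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class MetaboliteMatrix:
    """Metabolite-by-sample abundances with an explicit missing mask."""

    metabolite_ids: list[str]
    samples: list[SampleRecord]
    abundances: np.ndarray  # float, genes x samples; NaN where missing
    pathway_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.metabolite_ids), len(self.samples)):
            raise FormatError(
                f"abundance matrix shape {self.abundances.shape} does not "
                f"match {len(self.metabolite_ids)} metabolites x "
                f"{len(self.samples)} samples"
            )
        with np.errstate(invalid="ignore"):
            neg = self.abundances < 0
        if neg.any():
            m, s = np.argwhere(neg)[0]
            raise FormatError(
                f"negative abundance for metabolite "
                f"{self.metabolite_ids[m]!r} in sample "
                f"{self.samples[s].sample_id!r}"
            )
        known = set(self.metabolite_ids)
        for mid in list(self.pathway_map):
            if mid not in known:
                logger.warning(
                    "metabolite %r in pathway map absent from matrix; ignored",
                    mid,
                )
                del self.pathway_map[mid]

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.abundances)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def pathway_members(self) -> dict[str, list[str]]:
        """Invert the metabolite -> pathways map to pathway -> metabolites."""
        out: dict[str, list[str]] = {}
        for mid, paths in self.pathway_map.items():
            for p in paths:
                out.setdefault(p, []).append(mid)
        return out


# ---------------------------------------------------------------------------
# design


def _split_table(text: str) -> list[list[str]]:
    rows = []
    for line in text.splitlines():
        if line.strip() == "":
            continue
        rows.append(line.rstrip("\n").split("\t"))
    return rows


def read_design(path) -> list[SampleRecord]:
    """Read the sample sheet: header sample_id/group/time_label."""
    with open(path) as fh:
        rows = _split_table(fh.read())
    if not rows:
        raise FormatError(f"{path}: empty design file")
    header = rows[0]
    required = ["sample_id", "group", "time_label"]
    try:
        cols = {name: header.index(name) for name in required}
    except ValueError as exc:
        raise FormatError(f"{path}: design header must contain {required}") from exc
    records = []
    for row in rows[1:]:
        if len(row) < len(required):
            raise FormatError(f"{path}: short design row {row!r}")
        records.append(
            SampleRecord(
                sample_id=row[cols["sample_id"]],
                group=row[cols["group"]],
                time_label=row[cols["time_label"]],
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate sample id {dup[0]!r} in design")
    return records


def write_design(records: list[SampleRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\ttime_label\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.group}\t{r.time_label}\n")


# ---------------------------------------------------------------------------
# counts


def read_counts(path, design_path) -> CountMatrix:
    """Read a gene-by-sample count table and its design.

    Columns of the result follow the design-file order.
    """
    design = read_design(design_path)
    with open(path) as fh:
        rows = _split_table(fh.read())
    if not rows:
        raise FormatError(f"{path}: empty count file")
    header = rows[0]
    matrix_samples = header[1:]
    known = set(matrix_samples)
    design_ids = [r.sample_id for r in design]
    for sid in design_ids:
        if sid not in known:
            raise FormatError(
                f"{path}: sample {sid!r} listed in design but absent "
                f"from count matrix"
            )
    for sid in matrix_samples:
        if sid not in set(design_ids):
            raise FormatError(
                f"{path}: sample {sid!r} in count matrix but absent "
                f"from design"
            )
    col_of = {sid: j for j, sid in enumerate(matrix_samples)}
    order = [col_of[sid] for sid in design_ids]

    gene_ids: list[str] = []
    counts = np.empty((len(rows) - 1, len(design_ids)), dtype=np.int64)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise FormatError(
                f"{path}: row for gene {row[0]!r} has {len(row) - 1} values, "
                f"expected {len(matrix_samples)}"
            )
        gene_ids.append(row[0])
        for k, j in enumerate(order):
            token = row[1 + j]
            try:
                value = int(token)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-integer count {token!r} for gene "
                    f"{row[0]!r}, sample {design_ids[k]!r}"
                ) from exc
            if value < 0:
                raise FormatError(
                    f"{path}: negative count {token!r} for gene "
                    f"{row[0]!r}, sample {design_ids[k]!r}"
                )
            counts[i, k] = value
    return CountMatrix(gene_ids=gene_ids, samples=design, counts=counts)


def write_counts(cm: CountMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(cm.sample_ids) + "\n")
        for g, row in zip(cm.gene_ids, cm.counts):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path) -> GeneSetDB:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m != ""]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetDB(sets=sets, descriptions=descriptions)


def write_gmt(db: GeneSetDB, path) -> None:
    with open(path, "w") as fh:
        for name, members in db.sets.items():
            desc = db.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# metabolites


def read_metabolites(
    path,
    map_path,
    design_path,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> MetaboliteMatrix:
    """Read an abundance table (missing cells = token, zero is a value)."""
    design = read_design(design_path)
    with open(path) as fh:
        rows = _split_table(fh.read())
    if not rows:
        raise FormatError(f"{path}: empty metabolite file")
    header = rows[0]
    matrix_samples = header[1:]
    design_ids = [r.sample_id for r in design]
    for sid in design_ids:
        if sid not in set(matrix_samples):
            raise FormatError(
                f"{path}: sample {sid!r} listed in design but absent "
                f"from metabolite matrix"
            )
    col_of = {sid: j for j, sid in enumerate(matrix_samples)}
    order = [col_of[sid] for sid in design_ids]

    met_ids: list[str] = []
    values = np.empty((len(rows) - 1, len(design_ids)), dtype=float)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise FormatError(
                f"{path}: row for metabolite {row[0]!r} has "
                f"{len(row) - 1} values, expected {len(matrix_samples)}"
            )
        met_ids.append(row[0])
        for k, j in enumerate(order):
            token = row[1 + j]
            if token == missing_token:
                values[i, k] = np.nan
                continue
            try:
                v = float(token)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: bad abundance {token!r} for metabolite "
                    f"{row[0]!r}, sample {design_ids[k]!r}"
                ) from exc
            if v < 0:
                raise FormatError(
                    f"{path}: negative abundance {token!r} for metabolite "
                    f"{row[0]!r}, sample {design_ids[k]!r}"
                )
            values[i, k] = v

    pathway_map: dict[str, list[str]] = {}
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{map_path}:{lineno}: expected 2 fields "
                    f"(metabolite, pathway), got {len(fields)}"
                )
            mid, pathway = fields
            pathway_map.setdefault(mid, [])
            if pathway not in pathway_map[mid]:
                pathway_map[mid].append(pathway)
    return MetaboliteMatrix(
        metabolite_ids=met_ids,
        samples=design,
        abundances=values,
        pathway_map=pathway_map,
    )


def write_metabolites(
    mm: MetaboliteMatrix,
    path,
    map_path=None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> None:
    def fmt(v: float) -> str:
        if np.isnan(v):
            return missing_token
        return repr(float(v))

    with open(path, "w") as fh:
        fh.write("metabolite_id\t" + "\t".join(mm.sample_ids) + "\n")
        for mid, row in zip(mm.metabolite_ids, mm.abundances):
            fh.write(mid + "\t" + "\t".join(fmt(v) for v in row) + "\n")
    if map_path is not None:
        with open(map_path, "w") as fh:
            for mid, paths in mm.pathway_map.items():
                for p in paths:
                    fh.write(f"{mid}\t{p}\n")


# ---------------------------------------------------------------------------
# configuration


DEFAULT_CONFIG = {
    "fdr": 0.10,
    "min_fc": 1.5,
    "metabolite_alpha": 0.05,
    "prior_df": 10.0,
    "min_set_size": 5,
    "include_excluded_times": False,
    "missing_token": DEFAULT_MISSING_TOKEN,
    "seed": 0,
}


def load_config(path=None, **overrides) -> dict:
    """Load a flat YAML config, fill defaults, apply keyword overrides."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError(f"{path}: config must be a mapping")
        cfg.update(user)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


__all__ = [
    "GROUPS",
    "TIME_LABELS",
    "TIME_DAYS",
    "EXCLUDED_TIME_LABELS",
    "FormatError",
    "SampleRecord",
    "CountMatrix",
    "GeneSetDB",
    "MetaboliteMatrix",
    "read_design",
    "write_design",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_metabolites",
    "write_metabolites",
    "load_config",
    "DEFAULT_CONFIG",
]
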