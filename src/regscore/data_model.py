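"""Core data containers and readers/writers shared by every analysis stage.

Expression is a genes x samples matrix of finite, log-scale values; the
pipeline treats it as already normalized upstream and never re-normalizes
across samples. Gene sets travel as GMT, clinical data as a TSV with
``sample_id``, ``time``, ``event`` and optional covariate columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("regscore")

__all__ = [
    "ExpressionMatrix",
    "SignatureSet",
    "SurvivalTable",
    "GroupAssignment",
    "read_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "align",
]

# 10 significant digits: round-trips float text within 1e-9 for log-scale data
_FLOAT_FMT = "%.10g"


class ExpressionMatrix:
    """Genes x samples expression with unique identifiers and finite values.

    Parameters
    ----------
    data : pandas.DataFrame
        Index = gene ids, columns = sample ids, float values (log scale).
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError(
                f"expression matrix needs >=2 genes and >=2 samples, got {data.shape}"
            )
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = data.index[~np.isfinite(values).all(axis=1)].tolist()
            raise ValueError(f"non-finite expression values in genes: {bad[:5]}")
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data[list(samples)])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id",
                         float_format=_FLOAT_FMT)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


@dataclass
class SignatureSet:
    """Named gene sets with an optional per-signature category label."""

    name: str
    sets: dict[str, list[str]]
    category: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self):
        for sig, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"signature {sig!r} is empty")
        for sig in self.sets:
            self.category.setdefault(sig, None)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def restrict(self, expr: ExpressionMatrix) -> tuple["SignatureSet", dict[str, list[str]]]:
        """Drop genes absent from *expr*; returns restricted set + dropped report.

        Signatures left empty after restriction are removed (reported under
        their name with the full original gene list).
        """
        universe = set(expr.gene_ids)
        kept: dict[str, list[str]] = {}
        dropped: dict[str, list[str]] = {}
        for sig, genes in self.sets.items():
            present = [g for g in genes if g in universe]
            gone = [g for g in genes if g not in universe]
            if gone:
                dropped[sig] = gone
            if present:
                kept[sig] = present
            else:
                logger.warning("signature %r empty after restriction; dropped", sig)
        if not kept:
            raise ValueError("all signatures empty after restriction to matrix")
        cat = {s: self.category.get(s) for s in kept}
        return SignatureSet(self.name, kept, cat), dropped


class SurvivalTable:
    """Right-censored survival: time, event (0/1) and covariates per sample."""

    def __init__(self, data: pd.DataFrame):
        if "time" not in data.columns or "event" not in data.columns:
            raise ValueError("survival table needs 'time' and 'event' columns")
        if data.index.has_duplicates:
            raise ValueError("duplicate sample ids in survival table")
        time = pd.to_numeric(data["time"], errors="raise")
        if (time <= 0).any():
            bad = data.index[time <= 0].tolist()
            raise ValueError(f"non-positive survival times for samples: {bad[:5]}")
        event = pd.to_numeric(data["event"], errors="raise")
        if not event.isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        self.data = data.copy()
        self.data["time"] = time.astype(float)
        self.data["event"] = event.astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])

    def subset(self, samples: list[str]) -> "SurvivalTable":
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from survival table: {missing[:10]}")
        return SurvivalTable(self.data.loc[list(samples)])

    def with_covariate(self, name: str, values: pd.Series) -> "SurvivalTable":
        out = self.data.copy()
        out[name] = values.reindex(out.index)
        return SurvivalTable(out)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id",
                         float_format=_FLOAT_FMT)

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return (f"SurvivalTable({len(self.data)} samples, "
                f"{int(self.data['event'].sum())} events)")


class GroupAssignment:
    """One categorical label per sample (cluster, high/low, response ...)."""

    def __init__(self, labels: pd.Series):
        if labels.index.has_duplicates:
            raise ValueError("duplicate sample ids in group assignment")
        if labels.isna().any():
            raise ValueError("every sample must carry a label")
        self.labels = labels.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def groups(self) -> dict[str, list[str]]:
        return {g: list(idx) for g, idx in self.labels.groupby(self.labels).groups.items()}

    def subset(self, samples: list[str]) -> "GroupAssignment":
        return GroupAssignment(self.labels.loc[list(samples)])

    def n_groups(self) -> int:
        return self.labels.nunique()

    def to_tsv(self, path) -> None:
        self.labels.rename("group").to_csv(path, sep="\t", index_label="sample_id")

    def __len__(self) -> int:
        return len(self.labels)


def read_expression(path, min_variance: float = 0.0) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Duplicate gene ids are collapsed by mean; rows with any missing value are
    dropped; genes with variance <= *min_variance* are removed. Counts of
    dropped rows are logged.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # malformed structure
        raise ValueError(f"cannot parse expression file {path}: {exc}") from exc
    if raw.shape[1] == 0:
        raise ValueError(f"expression file {path} has no sample columns")
    if raw.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in header of {path}")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    # distinguish genuinely-missing cells from non-numeric garbage
    nonempty = raw.notna() & raw.astype(str).apply(lambda c: c.str.strip() != "")
    bad_cells = numeric.isna() & nonempty
    if bad_cells.to_numpy().any():
        row_pos = int(np.argmax(bad_cells.any(axis=1).to_numpy()))
        # +2: header line is 1, first data row is 2
        raise ValueError(
            f"non-numeric cell in {path} at row {row_pos + 2} "
            f"(gene {raw.index[row_pos]!r})"
        )

    n_missing = int(numeric.isna().any(axis=1).sum())
    numeric = numeric.dropna(axis=0, how="any")
    if n_missing:
        logger.info("read_expression: dropped %d rows with missing values", n_missing)

    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        numeric = numeric.groupby(level=0, sort=False).mean()
        logger.info("read_expression: collapsed %d duplicate gene rows by mean", n_dup)

    var = numeric.var(axis=1, ddof=1)
    low = var <= min_variance
    if low.any():
        logger.info("read_expression: removed %d genes with variance <= %g",
                    int(low.sum()), min_variance)
    numeric = numeric.loc[~low]
    if numeric.shape[0] < 2:
        raise ValueError(f"expression file {path}: fewer than 2 genes after filtering")
    return ExpressionMatrix(numeric)


def read_gmt(path) -> SignatureSet:
    """Read a GMT file: per line ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    category: dict[str, str | None] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes: list[str] = []
            seen = set()
            for g in fields[2:]:
                g = g.strip()
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
            category[name] = desc if desc not in ("", "na", "NA") else None
    if not sets:
        raise ValueError(f"{path}: no signatures")
    import os
    return SignatureSet(os.path.basename(str(path)), sets, category)


def write_gmt(sigs: SignatureSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sigs.sets.items():
            desc = sigs.category.get(name) or "na"
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical(path) -> SurvivalTable:
    """Read a clinical TSV with columns sample_id, time, event, covariates..."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    return SurvivalTable(df)


def align(expr: ExpressionMatrix, surv: SurvivalTable) -> tuple[ExpressionMatrix, SurvivalTable]:
    """Restrict both inputs to their common samples, in expression order."""
    common = [s for s in expr.sample_ids if s in set(surv.sample_ids)]
    if not common:
        raise ValueError("no samples shared between expression and survival table")
    logger.info("align: %d shared samples", len(common))
    return expr.subset_samples(common), surv.subset(common)
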