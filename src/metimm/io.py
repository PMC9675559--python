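"""Domain types and typed readers/writers for the formats the pipeline touches.

Expression matrices travel as TSV (rows = genes, columns = samples, log-scale
normalized values); gene sets as GMT; clinical annotation and study-level
hazard-ratio tables as CSV/TSV with documented headers.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Two-sided 95% normal quantile used for every CI <-> SE conversion.
Z95 = 1.959964

__all__ = [
    "Z95",
    "FormatError",
    "ExpressionMatrix",
    "GeneSet",
    "WeightedGeneSet",
    "SignatureCollection",
    "StudyEffect",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_clinical_table",
    "write_clinical_table",
    "read_meta_table",
    "write_meta_table",
    "hr_ci_to_effect",
    "effect_to_hr_ci",
]


class FormatError(ValueError):
    """A file violated the documented format or an invariant of its type."""


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty collection of unique gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        if len(self.genes) == 0:
            raise ValueError(f"GeneSet {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"GeneSet {self.name!r} contains duplicate genes")
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class WeightedGeneSet:
    """An ordered gene list with one real weighting coefficient per gene.

    Houses signatures scored as weighted sums, e.g. the 18-gene
    T-cell-inflamed (GEP) signature.
    """

    name: str
    genes: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("WeightedGeneSet name must be non-empty")
        if len(self.genes) != len(self.weights):
            raise ValueError(
                f"WeightedGeneSet {self.name!r}: {len(self.genes)} genes but "
                f"{len(self.weights)} weights"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"WeightedGeneSet {self.name!r} contains duplicate genes")
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))

    def __len__(self) -> int:
        return len(self.genes)


#: name -> GeneSet (or WeightedGeneSet); names unique by construction of dict.
SignatureCollection = dict[str, GeneSet]


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """Genes x samples real matrix of log-scale normalized expression.

    Invariants enforced at construction: unique gene and sample identifiers,
    all entries finite, shape consistent with the identifier lists.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> None:
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=float)
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"values shape {values.shape} inconsistent with "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        dup = _first_duplicate(gene_ids)
        if dup is not None:
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        dup = _first_duplicate(sample_ids)
        if dup is not None:
            raise FormatError(f"duplicate sample identifier: {dup!r}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite expression value at gene {gene_ids[i]!r}, "
                f"sample {sample_ids[j]!r}"
            )
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self.values = values

    # -- construction / conversion ------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    # -- basic interface -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of `genes` (error on absent genes)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[idx])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene symbols, header sample ids).

    Raises :class:`FormatError` naming the offender for duplicate identifiers
    and citing row/column coordinates for missing or non-numeric cells.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.map(lambda g: str(g).strip())
    raw.columns = raw.columns.map(lambda s: str(s).strip())
    dup = _first_duplicate(list(raw.index))
    if dup is not None:
        raise FormatError(f"{path}: duplicate gene identifier {dup!r}")
    dup = _first_duplicate(list(raw.columns))
    if dup is not None:
        raise FormatError(f"{path}: duplicate sample identifier {dup!r}")
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = np.argwhere(~np.isfinite(numeric.to_numpy(dtype=float)))
    if bad.size:
        i, j = bad[0]
        cell = raw.iat[i, j]
        what = "missing" if cell.strip() == "" else f"non-numeric ({cell!r})"
        raise FormatError(
            f"{path}: {what} value at row {i + 2} (gene {raw.index[i]!r}), "
            f"column {j + 2} (sample {raw.columns[j]!r})"
        )
    return ExpressionMatrix.from_frame(numeric)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = expr.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> SignatureCollection:
    """Parse a GMT file: per line set name, description, then >=1 gene symbol.

    Duplicate genes within one line are dropped with a warning; a duplicated
    set name or a line with zero genes is a :class:`FormatError`.
    """
    collection: SignatureCollection = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: gene set {fields[0]!r} has zero genes"
                )
            name = fields[0].strip()
            genes: list[str] = []
            seen: set[str] = set()
            dupes: list[str] = []
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    dupes.append(g)
                    continue
                seen.add(g)
                genes.append(g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has zero genes")
            if dupes:
                warnings.warn(
                    f"{path}:{lineno}: gene set {name!r} lists duplicate genes "
                    f"{sorted(set(dupes))}; deduplicated"
                )
            if name in collection:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            collection[name] = GeneSet(name, tuple(genes))
    return collection


def write_gmt(collection: Mapping[str, GeneSet], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as handle:
        for name, gs in collection.items():
            handle.write("\t".join([name, description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

_EGFR_CANON = {
    "mutant": "mutant", "mut": "mutant", "mutated": "mutant", "mutation": "mutant",
    "wild-type": "wild-type", "wt": "wild-type", "wildtype": "wild-type",
    "wild_type": "wild-type", "wild type": "wild-type",
}

REQUIRED_CLINICAL_COLUMNS = ("sample_id", "egfr_status", "os_time", "os_event")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a clinical annotation table (CSV or TSV by extension).

    Required columns: sample_id, egfr_status ({mutant, wild-type}, case
    insensitive), os_time (months, >= 0), os_event ({0, 1}).  Optional:
    treatment, response, statin_use.  Returns a DataFrame indexed by
    sample_id with canonicalized categories.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep)
    for col in REQUIRED_CLINICAL_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    table["sample_id"] = table["sample_id"].astype(str).str.strip()
    dup = _first_duplicate(list(table["sample_id"]))
    if dup is not None:
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")

    def canon_egfr(v: str) -> str:
        key = str(v).strip().lower()
        if key not in _EGFR_CANON:
            raise FormatError(f"{path}: unrecognized egfr_status {v!r}")
        return _EGFR_CANON[key]

    table["egfr_status"] = table["egfr_status"].map(canon_egfr)
    table["os_time"] = pd.to_numeric(table["os_time"], errors="raise").astype(float)
    if (table["os_time"] < 0).any():
        offender = table.loc[table["os_time"] < 0, "sample_id"].iloc[0]
        raise FormatError(f"{path}: negative os_time for sample {offender!r}")
    events = pd.to_numeric(table["os_event"], errors="raise")
    if not events.isin([0, 1]).all():
        offender = table.loc[~events.isin([0, 1]), "sample_id"].iloc[0]
        raise FormatError(f"{path}: os_event outside {{0,1}} for sample {offender!r}")
    table["os_event"] = events.astype(int)
    return table.set_index("sample_id", drop=False)


def write_clinical_table(clinical: pd.DataFrame, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    clinical.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Study-level hazard ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyEffect:
    """One study's log hazard ratio with its standard error."""

    study_id: str
    log_hr: float
    se: float
    n: int
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_hr):
            raise ValueError(f"study {self.study_id!r}: non-finite log_hr")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"study {self.study_id!r}: se must be > 0")
        if self.n < 1:
            raise ValueError(f"study {self.study_id!r}: n must be >= 1")


def hr_ci_to_effect(hr: float, ci_lower: float, ci_upper: float) -> tuple[float, float]:
    """Convert a hazard ratio with 95% CI to (log_hr, se).

    se = (ln(ci_upper) - ln(ci_lower)) / (2 * 1.959964).
    """
    if hr <= 0 or ci_lower <= 0 or ci_upper <= 0:
        raise ValueError("hazard ratio and CI bounds must be positive")
    if ci_lower > ci_upper:
        raise ValueError(f"ci_lower {ci_lower} exceeds ci_upper {ci_upper}")
    if not (ci_lower <= hr <= ci_upper):
        warnings.warn(f"HR {hr} lies outside its CI ({ci_lower}, {ci_upper})")
    log_hr = math.log(hr)
    se = (math.log(ci_upper) - math.log(ci_lower)) / (2.0 * Z95)
    return log_hr, se


def effect_to_hr_ci(log_hr: float, se: float) -> tuple[float, float, float]:
    """Inverse of :func:`hr_ci_to_effect`: (hr, ci_lower, ci_upper)."""
    return (
        math.exp(log_hr),
        math.exp(log_hr - Z95 * se),
        math.exp(log_hr + Z95 * se),
    )


def read_meta_table(path: str | Path) -> list[StudyEffect]:
    """Read a study table (CSV) into StudyEffect rows.

    Accepts either (log_hr, se) columns directly or (hr, ci_lower, ci_upper),
    converted on the natural-log scale.  Optional columns: n (default 1),
    subgroup.
    """
    table = pd.read_csv(path)
    if "study_id" not in table.columns:
        raise FormatError(f"{path}: missing required column 'study_id'")
    has_direct = {"log_hr", "se"}.issubset(table.columns)
    has_ci = {"hr", "ci_lower", "ci_upper"}.issubset(table.columns)
    if not (has_direct or has_ci):
        raise FormatError(
            f"{path}: need either (log_hr, se) or (hr, ci_lower, ci_upper) columns"
        )
    studies: list[StudyEffect] = []
    for _, row in table.iterrows():
        if has_direct:
            log_hr, se = float(row["log_hr"]), float(row["se"])
        else:
            log_hr, se = hr_ci_to_effect(
                float(row["hr"]), float(row["ci_lower"]), float(row["ci_upper"])
            )
        if se <= 0:
            raise FormatError(
                f"{path}: study {row['study_id']!r} has non-positive se "
                "(degenerate confidence interval)"
            )
        subgroup = None
        if "subgroup" in table.columns and not pd.isna(row["subgroup"]):
            subgroup = str(row["subgroup"])
        n = int(row["n"]) if "n" in table.columns and not pd.isna(row["n"]) else 1
        studies.append(StudyEffect(str(row["study_id"]), log_hr, se, n, subgroup))
    return studies


def write_meta_table(studies: Sequence[StudyEffect], path: str | Path) -> None:
    pd.DataFrame(
        {
            "study_id": [s.study_id for s in studies],
            "log_hr": [s.log_hr for s in studies],
            "se": [s.se for s in studies],
            "n": [s.n for s in studies],
            "subgroup": [s.subgroup for s in studies],
        }
    ).to_csv(path, index=False)
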