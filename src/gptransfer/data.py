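"""Domain containers and delimited-text IO for genotype and phenotype data.

The interchange formats mirror what multi-environment trial pipelines produce:
a line x marker dosage matrix (rows = breeding lines / cultivars, columns =
genome-wide markers coded 0/1/2 or imputed reals) and a long-format phenotype
table of per-line adjusted means (BLUEs) keyed by (line, environment, trait).
Environments of one trial network share only a fraction of their lines, which
is why phenotype records — not matrices — are the interchange format.

Line matching is exact string equality after whitespace trimming; silent
mis-joins are worse than hard errors, so there is no fuzzy matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "PhenotypeTable",
    "EnvironmentPair",
    "AlignedDesign",
    "read_marker_matrix",
    "write_marker_matrix",
    "impute_missing",
    "read_phenotypes",
    "write_phenotypes",
    "align",
]

#: default number of significant digits for floating-point output
FLOAT_DIGITS = 6


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class MarkerMatrix:
    """Lines x markers dosage matrix with row/column identifiers.

    ``values`` is an ``(n_lines, p_markers)`` float array; missing genotypes
    are stored as NaN until :func:`impute_missing` is applied.
    """

    line_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "line_ids", tuple(str(s).strip() for s in self.line_ids))
        object.__setattr__(self, "marker_ids", tuple(str(s).strip() for s in self.marker_ids))
        if v.ndim != 2 or v.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"values shape {v.shape} does not match {len(self.line_ids)} lines "
                f"x {len(self.marker_ids)} markers"
            )
        _check_unique(self.line_ids, "line")
        _check_unique(self.marker_ids, "marker")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def p_markers(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def row_index(self) -> dict[str, int]:
        return {lid: i for i, lid in enumerate(self.line_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.line_ids), columns=list(self.marker_ids))


@dataclass(frozen=True)
class PhenotypeTable:
    """Long-format phenotype records (line, environment, trait, value).

    At most one record per (line, environment, trait); values are finite.
    ``n_dropped`` counts records discarded for missing values at read time.
    """

    records: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self):
        df = self.records.copy()
        required = ["line", "environment", "trait", "value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table is missing columns: {missing}")
        df = df[required]
        for c in ("line", "environment", "trait"):
            df[c] = df[c].astype(str).str.strip()
        df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)
        if not np.isfinite(df["value"]).all():
            raise ValueError("phenotype values must be finite")
        df = df.drop_duplicates()  # identical duplicates are harmless
        dup = df.duplicated(subset=["line", "environment", "trait"], keep=False)
        if dup.any():
            first = df.loc[dup, ["line", "environment", "trait"]].iloc[0]
            raise ValueError(
                "conflicting duplicate phenotype record for "
                f"(line={first['line']!r}, environment={first['environment']!r}, "
                f"trait={first['trait']!r})"
            )
        object.__setattr__(self, "records", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def environments(self) -> list[str]:
        return sorted(self.records["environment"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())

    def slice(self, environment: str, trait: str) -> pd.DataFrame:
        r = self.records
        return r[(r["environment"] == environment) & (r["trait"] == trait)]


@dataclass(frozen=True)
class EnvironmentPair:
    """A (proxy, goal) environment pairing for one trait.

    The proxy environment is the fully phenotyped source domain supplying the
    transferred coefficients; the goal environment is where predictions are
    wanted.
    """

    proxy_env: str
    goal_env: str
    trait: str

    def __post_init__(self):
        if self.proxy_env == self.goal_env:
            raise ValueError("proxy and goal environments must differ")

    def validate(self, pt: PhenotypeTable) -> None:
        for env in (self.proxy_env, self.goal_env):
            if len(pt.slice(env, self.trait)) == 0:
                raise ValueError(
                    f"no phenotype records for environment {env!r}, trait {self.trait!r}"
                )


@dataclass(frozen=True)
class AlignedDesign:
    """The (X, y) pair for one environment after genotype/phenotype alignment."""

    X: np.ndarray
    y: np.ndarray
    line_ids: tuple[str, ...]
    marker_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "line_ids", tuple(self.line_ids))
        if X.ndim != 2 or y.ndim != 1 or len(y) != X.shape[0] or len(self.line_ids) != len(y):
            raise ValueError("X rows, y length and line_ids must agree")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "AlignedDesign":
        idx = np.asarray(idx)
        return AlignedDesign(
            self.X[idx], self.y[idx], tuple(self.line_ids[i] for i in idx), self.marker_ids
        )


def read_marker_matrix(path, delimiter: str = "\t", missing_token: str = "NA") -> MarkerMatrix:
    """Parse a delimited genotype file: header row of marker ids, first column line id.

    Missing cells (``missing_token``) become NaN; they are flagged, not imputed.
    Duplicate identifiers and non-numeric cells are hard errors.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, index_col=0)
    line_ids = [str(s).strip() for s in df.index]
    marker_ids = [str(s).strip() for s in df.columns]
    _check_unique(line_ids, "line")
    _check_unique(marker_ids, "marker")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            s = cell.strip() if isinstance(cell, str) else cell
            if s is None or (isinstance(s, float) and np.isnan(s)) or s == missing_token:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(s)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric genotype cell {cell!r} at line {line_ids[i]!r}, "
                    f"marker {marker_ids[j]!r}"
                ) from None
    return MarkerMatrix(tuple(line_ids), tuple(marker_ids), values)


def _fmt(x: float, digits: int = FLOAT_DIGITS) -> str:
    if np.isnan(x):
        return "NA"
    if float(x).is_integer():
        return str(int(x))
    return f"{x:.{digits}g}"


def write_marker_matrix(m: MarkerMatrix, path, delimiter: str = "\t",
                        missing_token: str = "NA", digits: int = FLOAT_DIGITS) -> None:
    with open(path, "w") as fh:
        fh.write("line" + delimiter + delimiter.join(m.marker_ids) + "\n")
        for i, lid in enumerate(m.line_ids):
            row = delimiter.join(
                missing_token if np.isnan(v) else _fmt(v, digits) for v in m.values[i]
            )
            fh.write(lid + delimiter + row + "\n")


def impute_missing(m: MarkerMatrix) -> MarkerMatrix:
    """Replace each missing dosage with its marker's mean over observed lines."""
    if not m.has_missing:
        return m
    values = m.values.copy()
    nan_mask = np.isnan(values)
    all_missing = nan_mask.all(axis=0)
    if all_missing.any():
        j = int(np.argmax(all_missing))
        raise ValueError(f"marker {m.marker_ids[j]!r} has no observed genotypes to impute from")
    col_means = np.nanmean(values, axis=0)
    values[nan_mask] = np.broadcast_to(col_means, values.shape)[nan_mask]
    return replace(m, values=values)


def read_phenotypes(path, delimiter: str = "\t") -> PhenotypeTable:
    """Parse a long-format phenotype file with columns line, environment, trait, value.

    Records with a missing/blank value are dropped and counted in ``n_dropped``.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["line", "environment", "trait", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file is missing columns: {missing}")
    df = df[required]
    vals = pd.to_numeric(df["value"].str.strip() if df["value"].dtype == object else df["value"],
                         errors="coerce")
    keep = vals.notna()
    n_dropped = int((~keep).sum())
    df = df.loc[keep].copy()
    df["value"] = vals[keep].astype(float)
    return PhenotypeTable(df.reset_index(drop=True), n_dropped=n_dropped)


def write_phenotypes(pt: PhenotypeTable, path, delimiter: str = "\t",
                     digits: int = FLOAT_DIGITS) -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(["line", "environment", "trait", "value"]) + "\n")
        for row in pt.records.itertuples(index=False):
            fh.write(delimiter.join([row.line, row.environment, row.trait,
                                     _fmt(row.value, digits)]) + "\n")


def align(m: MarkerMatrix, pt: PhenotypeTable, environment: str, trait: str) -> AlignedDesign:
    """Build the (X, y) design of one environment by intersecting line ids.

    Rows follow MarkerMatrix row order, so designs built for different
    environments from the same matrix give shared lines identical X rows.
    The matrix must already be imputed (no missing dosages).
    """
    if m.has_missing:
        raise ValueError("marker matrix contains missing values; run impute_missing first")
    sl = pt.slice(environment, trait)
    pheno = dict(zip(sl["line"], sl["value"]))
    idx = [i for i, lid in enumerate(m.line_ids) if lid in pheno]
    n_geno, n_pheno = m.n_lines, len(pheno)
    if len(idx) < 2:
        raise ValueError(
            f"only {len(idx)} lines shared between {n_geno} genotyped and "
            f"{n_pheno} phenotyped lines for environment {environment!r}, trait {trait!r}"
        )
    line_ids = tuple(m.line_ids[i] for i in idx)
    X = m.values[idx]
    y = np.array([pheno[lid] for lid in line_ids])
    return AlignedDesign(X, y, line_ids, m.marker_ids)
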