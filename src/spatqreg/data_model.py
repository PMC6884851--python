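"""Tabular records, district adjacency and design construction.

The data model mirrors what a DHS-style extract provides: one row per
child with a continuous birth weight in kilograms, categorical maternal
covariates (BMI class, smoking, birth order class, education, wealth
quintile, height class, weight class), metrical covariates modelled
nonparametrically (mother age, antenatal visit count), and the district
where the child lives.  Districts are linked by a neighbour graph that
later drives the intrinsic CAR prior.

Conventions
-----------
* Rows with missing (or non-positive / non-finite) birth weight are
  dropped at read time and counted; rows with missing covariates are
  kept.  A missing categorical value becomes an explicit extra level
  ``"missing"`` (never the reference); a missing metrical value simply
  contributes no smooth term for that record.
* Fixed effects use treatment (dummy) coding against a declared
  reference level, intercept first, terms in declared order, levels in
  declared order — so the design is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "MISSING_LEVEL",
    "SchemaError",
    "DesignError",
    "DataSchema",
    "default_schema",
    "Dataset",
    "AdjacencyGraph",
    "FixedTerm",
    "SmoothTerm",
    "ModelSpec",
    "default_spec",
    "DesignMatrices",
    "read_dataset",
    "write_dataset",
    "read_adjacency",
    "write_adjacency",
    "build_design",
]

#: level label used for a missing categorical value
MISSING_LEVEL = "missing"


class SchemaError(ValueError):
    """A file does not conform to the declared column schema."""


class DesignError(ValueError):
    """A design matrix cannot be built (e.g. a term with no contrast)."""


# ---------------------------------------------------------------------------
# schema and dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DataSchema:
    """Column description for a birth-weight record file.

    Parameters
    ----------
    response
        Name of the continuous response column (kilograms).
    district
        Name of the district label column.
    categoricals
        Mapping covariate name -> ordered list of declared levels.
    references
        Mapping covariate name -> reference level (must be declared).
    metricals
        Names of metrical covariates (modelled by random-walk smooths).
    missing
        Marker string for a missing value in the file (default ``"NA"``).
    """

    categoricals: dict[str, list[str]]
    references: dict[str, str]
    metricals: tuple[str, ...] = ("mother_age", "antenatal_visits")
    response: str = "birth_weight"
    district: str = "district"
    missing: str = "NA"

    def __post_init__(self) -> None:
        for name, ref in self.references.items():
            if name not in self.categoricals:
                raise SchemaError(f"reference given for undeclared term {name!r}")
            if ref not in self.categoricals[name]:
                raise SchemaError(
                    f"reference level {ref!r} not among declared levels of {name!r}"
                )

    @property
    def columns(self) -> list[str]:
        return (
            [self.response]
            + list(self.categoricals)
            + list(self.metricals)
            + [self.district]
        )


def default_schema() -> DataSchema:
    """Schema of the MDHS-like extract used throughout the package.

    Reference levels are the baselines implicit in the study design:
    BMI < 18.5, non-smoker, first birth, no education, poorest quintile,
    height < 150 cm, weight < 45 kg.
    """
    categoricals = {
        "bmi_class": ["<18.5", "18.5-25", ">25"],
        "smoking": ["no", "yes"],
        "birth_order": ["1", "2-3", "4-5", "6+"],
        "education": ["none", "primary", "secondary", "higher"],
        "wealth": ["poorest", "poor", "rich", "richer", "richest"],
        "height_class": ["<150", ">=150"],
        "weight_class": ["<45", "45-70", ">70"],
    }
    references = {
        "bmi_class": "<18.5",
        "smoking": "no",
        "birth_order": "1",
        "education": "none",
        "wealth": "poorest",
        "height_class": "<150",
        "weight_class": "<45",
    }
    return DataSchema(categoricals=categoricals, references=references)


@dataclass
class Dataset:
    """Individual-level records plus category metadata.

    ``df`` holds one row per retained child: the response column (float,
    finite, positive), categorical columns (strings drawn from the
    declared levels, possibly :data:`MISSING_LEVEL`), metrical columns
    (float, NaN where missing) and the district column.
    ``category_levels`` lists, per categorical term, the levels actually
    usable in a design — the declared levels plus ``"missing"`` if any
    record carries it.
    """

    df: pd.DataFrame
    schema: DataSchema
    category_levels: dict[str, list[str]]
    n_dropped_response: int = 0

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def y(self) -> np.ndarray:
        return self.df[self.schema.response].to_numpy(dtype=float)

    def districts(self) -> list[str]:
        return sorted(self.df[self.schema.district].unique())

    def validate_against(self, graph: "AdjacencyGraph") -> None:
        """Raise if a record's district is absent from the graph."""
        unknown = set(self.df[self.schema.district]) - set(graph.nodes)
        if unknown:
            raise SchemaError(f"districts not in adjacency graph: {sorted(unknown)}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.category_levels == other.category_levels
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
        )


def _parse_float(series: pd.Series, missing: str, column: str) -> np.ndarray:
    vals = series.astype(str).str.strip()
    out = np.full(len(vals), np.nan)
    mask = vals != missing
    try:
        out[mask.to_numpy()] = vals[mask].astype(float)
    except ValueError as exc:
        raise SchemaError(f"non-numeric value in column {column!r}: {exc}") from exc
    return out


def read_dataset(path, schema: DataSchema | None = None) -> Dataset:
    """Read a delimited-text record file (CSV or TSV, sniffed).

    Rows whose response is missing, non-finite or non-positive are
    dropped and counted in ``n_dropped_response``.  Rows with missing
    covariates are retained; a missing categorical becomes the explicit
    ``"missing"`` level.  An undeclared categorical value raises
    :class:`SchemaError` naming the column and row.
    """
    schema = schema or default_schema()
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str,
                      keep_default_na=False, skipinitialspace=True)
    missing_cols = [c for c in schema.columns if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing declared columns: {missing_cols}")

    y = _parse_float(raw[schema.response], schema.missing, schema.response)
    keep = np.isfinite(y) & (y > 0)
    n_dropped = int((~keep).sum())
    raw = raw.loc[keep].reset_index(drop=True)
    orig_rows = np.flatnonzero(keep)

    out = pd.DataFrame({schema.response: y[keep]})
    category_levels: dict[str, list[str]] = {}
    for name, levels in schema.categoricals.items():
        vals = raw[name].astype(str).str.strip()
        is_missing = vals == schema.missing
        bad = ~(vals.isin(levels) | is_missing)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"column {name!r}, file row {orig_rows[i] + 2}: "
                f"value {vals.iloc[i]!r} is not a declared level"
            )
        vals = vals.where(~is_missing, MISSING_LEVEL)
        out[name] = vals.to_numpy()
        category_levels[name] = list(levels) + (
            [MISSING_LEVEL] if bool(is_missing.any()) else []
        )
    for name in schema.metricals:
        out[name] = _parse_float(raw[name], schema.missing, name)
    dist = raw[schema.district].astype(str).str.strip()
    if (dist == schema.missing).any():
        i = int(np.flatnonzero((dist == schema.missing).to_numpy())[0])
        raise SchemaError(f"missing district label at file row {orig_rows[i] + 2}")
    out[schema.district] = dist.to_numpy()

    return Dataset(df=out, schema=schema, category_levels=category_levels,
                   n_dropped_response=n_dropped)


def write_dataset(data: Dataset, path) -> None:
    """Write records back to CSV, restoring the schema's missing marker."""
    schema = data.schema
    out = data.df.copy()
    for name in schema.categoricals:
        out[name] = out[name].replace(MISSING_LEVEL, schema.missing)
    for name in schema.metricals:
        col = out[name]
        out[name] = col.map(lambda v: schema.missing if pd.isna(v) else repr(float(v)))
    out[schema.response] = out[schema.response].map(lambda v: repr(float(v)))
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# adjacency graph
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyGraph:
    """District neighbour graph: symmetric, no self-loops.

    Node order is the order of first definition in the source file and
    fixes the row/column order of the ICAR structure matrix.
    """

    nodes: list[str]
    neighbours: dict[str, set[str]]

    def __post_init__(self) -> None:
        for a, nbrs in self.neighbours.items():
            if a in nbrs:
                raise ValueError(f"self-loop at node {a!r}")
            for b in nbrs:
                if b not in self.neighbours:
                    raise ValueError(f"unknown neighbour label {b!r} of node {a!r}")
                if a not in self.neighbours[b]:
                    raise ValueError(f"asymmetric neighbour relation {a!r}->{b!r}")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def n_i(self) -> dict[str, int]:
        """Neighbour count per node (the ICAR conditional precision weight)."""
        return {a: len(self.neighbours[a]) for a in self.nodes}

    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.nodes)}

    def adjacency_matrix(self) -> np.ndarray:
        idx = self.index()
        A = np.zeros((self.n, self.n))
        for a, nbrs in self.neighbours.items():
            for b in nbrs:
                A[idx[a], idx[b]] = 1.0
        return A

    def n_edges(self) -> int:
        return sum(len(v) for v in self.neighbours.values()) // 2

    def n_components(self) -> int:
        ncomp, _ = connected_components(csr_matrix(self.adjacency_matrix()),
                                        directed=False)
        return int(ncomp)

    def component_labels(self) -> np.ndarray:
        _, labels = connected_components(csr_matrix(self.adjacency_matrix()),
                                         directed=False)
        return labels

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AdjacencyGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.neighbours == other.neighbours


def _graph_from_lists(order: list[str], nbrs: dict[str, set[str]]) -> AdjacencyGraph:
    for a in order:
        unknown = nbrs[a] - nbrs.keys()
        if unknown:
            raise ValueError(
                f"unknown neighbour label(s) {sorted(unknown)} of node {a!r}")
    asym = [(a, b) for a in order for b in nbrs[a] if a not in nbrs[b]]
    if asym:
        warnings.warn(
            f"asymmetric neighbour list symmetrized ({len(asym)} relations added)",
            stacklevel=3,
        )
        for a, b in asym:
            nbrs[b].add(a)
    return AdjacencyGraph(nodes=order, neighbours=nbrs)


def read_adjacency(path) -> AdjacencyGraph:
    """Read a neighbour-list text file.

    Two formats are accepted:

    * plain neighbour list, one line per node: ``label: nbr1 nbr2 ...``
      (comma or whitespace separated, empty list allowed);
    * the GAL format: a header line whose last integer is the node
      count, then per node a ``label k`` line followed by a line of
      ``k`` neighbour labels.

    An asymmetric input is symmetrized with a warning; a self-loop or an
    unknown neighbour label is an error.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    content = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not content:
        raise ValueError(f"empty adjacency file {path}")
    if ":" in content[0]:
        order: list[str] = []
        nbrs: dict[str, set[str]] = {}
        for ln in content:
            label, _, rest = ln.partition(":")
            label = label.strip()
            if label in nbrs:
                raise ValueError(f"duplicate node definition {label!r}")
            order.append(label)
            nbrs[label] = {t for t in rest.replace(",", " ").split() if t}
        return _graph_from_lists(order, nbrs)
    # GAL: header, then label/neighbour line pairs
    header = content[0].split()
    try:
        count = int(header[1] if len(header) > 1 else header[0])
    except ValueError as exc:
        raise ValueError(f"unreadable GAL header {content[0]!r}") from exc
    order, nbrs = [], {}
    pos = 1
    for _ in range(count):
        label, k = content[pos].split()[0], int(content[pos].split()[1])
        neigh = content[pos + 1].split() if k > 0 else []
        if k > 0:
            pos += 2
        else:
            # a zero-neighbour node may or may not carry an (empty) line
            pos += 1
            if pos < len(content) and len(content[pos].split()) == 0:
                pos += 1
        if len(neigh) != k:
            raise ValueError(f"GAL node {label!r}: expected {k} neighbours, "
                             f"got {len(neigh)}")
        order.append(label)
        nbrs[label] = set(neigh)
    return _graph_from_lists(order, nbrs)


def write_adjacency(graph: AdjacencyGraph, path) -> None:
    """Write the plain neighbour-list format (round-trips with reader)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for a in graph.nodes:
            fh.write(f"{a}: {' '.join(sorted(graph.neighbours[a]))}\n")


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedTerm:
    """A categorical fixed-effect term with its reference level."""

    name: str
    reference: str


@dataclass(frozen=True)
class SmoothTerm:
    """A metrical covariate smoothed by a random-walk prior of given order."""

    name: str
    order: int = 2

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError("smooth order must be 1 (RW1) or 2 (RW2)")


@dataclass
class ModelSpec:
    """Specification of one additive quantile model.

    The conditional tau-quantile is modelled as intercept + dummy-coded
    fixed effects + one random-walk smooth per metrical covariate + an
    ICAR district effect.  ``hyperpriors`` maps a block name (smooth
    covariate name or the spatial term) to the (shape, rate) of the
    Gamma prior on that block's precision delta; unlisted blocks get the
    diffuse default Gamma(1, 5e-5).
    """

    tau: float
    fixed_terms: list[FixedTerm] = field(default_factory=list)
    smooth_terms: list[SmoothTerm] = field(default_factory=list)
    spatial_term: str | None = "district"
    hyperpriors: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed_prior_precision: float = 1e-6

    DEFAULT_HYPERPRIOR = (1.0, 5e-5)

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must lie in (0, 1), got {self.tau}")
        if self.fixed_prior_precision <= 0:
            raise ValueError("fixed_prior_precision must be positive")

    def hyperprior(self, block: str) -> tuple[float, float]:
        return self.hyperpriors.get(block, self.DEFAULT_HYPERPRIOR)

    def with_tau(self, tau: float) -> "ModelSpec":
        return replace(self, tau=tau)


def default_spec(tau: float, schema: DataSchema | None = None,
                 covariates: list[str] | None = None) -> ModelSpec:
    """Full model over the schema's covariates (optionally restricted).

    ``covariates`` — e.g. the list retained by screening — limits which
    categorical terms and smooths enter; the spatial term always enters.
    """
    schema = schema or default_schema()
    keep = set(covariates) if covariates is not None else None
    fixed = [FixedTerm(name, schema.references[name])
             for name in schema.categoricals
             if keep is None or name in keep]
    smooths = [SmoothTerm(name, order=2) for name in schema.metricals
               if keep is None or name in keep]
    return ModelSpec(tau=tau, fixed_terms=fixed, smooth_terms=smooths,
                     spatial_term=schema.district)


@dataclass
class DesignMatrices:
    """Design pieces for one dataset under one model spec.

    ``W`` is the dense fixed-effect matrix (intercept + dummies,
    reference levels omitted).  Each smooth has a sorted-unique value
    grid and a per-record index into it (-1 where the covariate is
    missing, contributing no smooth term).  ``spatial_index`` maps each
    record to its node position in the adjacency graph's node order.
    """

    W: np.ndarray
    colnames: list[str]
    smooth_grids: dict[str, np.ndarray]
    smooth_index: dict[str, np.ndarray]
    spatial_index: np.ndarray | None
    spatial_labels: list[str] | None


def build_design(data: Dataset, spec: ModelSpec,
                 graph: AdjacencyGraph | None = None) -> DesignMatrices:
    """Build design matrices with deterministic column ordering.

    Columns are intercept first, then terms in spec order, levels in
    declared order (the ``"missing"`` level, if present, last).  A term
    whose observed values collapse to a single level has no estimable
    contrast and raises :class:`DesignError`.
    """
    df = data.df
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in spec.fixed_terms:
        if term.name not in df.columns:
            raise DesignError(f"term {term.name!r} not in dataset")
        levels = data.category_levels.get(term.name,
                                          list(pd.unique(df[term.name])))
        if term.reference not in levels:
            raise DesignError(
                f"reference {term.reference!r} not a level of {term.name!r}")
        observed = df[term.name].nunique()
        if observed < 2:
            raise DesignError(
                f"term {term.name!r} has a single observed level; no contrast")
        vals = df[term.name].to_numpy()
        for lev in levels:
            if lev == term.reference:
                continue
            cols.append((vals == lev).astype(float))
            names.append(f"{term.name}={lev}")
    W = np.column_stack(cols)

    smooth_grids: dict[str, np.ndarray] = {}
    smooth_index: dict[str, np.ndarray] = {}
    for sm in spec.smooth_terms:
        if sm.name not in df.columns:
            raise DesignError(f"smooth covariate {sm.name!r} not in dataset")
        vals = df[sm.name].to_numpy(dtype=float)
        obs = np.isfinite(vals)
        grid = np.unique(vals[obs])
        idx = np.full(n, -1, dtype=int)
        idx[obs] = np.searchsorted(grid, vals[obs])
        smooth_grids[sm.name] = grid
        smooth_index[sm.name] = idx

    spatial_index = None
    spatial_labels = None
    if spec.spatial_term is not None:
        if spec.spatial_term not in df.columns:
            raise DesignError(f"spatial column {spec.spatial_term!r} not in dataset")
        labels = list(graph.nodes) if graph is not None else data.districts()
        lut = {lab: i for i, lab in enumerate(labels)}
        try:
            spatial_index = np.array(
                [lut[d] for d in df[spec.spatial_term]], dtype=int)
        except KeyError as exc:
            raise DesignError(f"district {exc.args[0]!r} absent from graph") from exc
        spatial_labels = labels

    return DesignMatrices(W=W, colnames=names, smooth_grids=smooth_grids,
                          smooth_index=smooth_index,
                          spatial_index=spatial_index,
                          spatial_labels=spatial_labels)
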