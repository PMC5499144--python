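"""Fitness-profile assembly and similarity ranking across screens.

A gene deletion's fitness profile is its vector of fitness (or GIS) values
across multiple screens/conditions.  Genes with similar profiles tend to
share function — e.g. subunits of one complex cluster together — so ranking
the library by profile similarity to a query deletion is a discovery tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateColumnError,
    InconsistencyError,
    InvalidParameterError,
    NoProfileError,
)
from .growth import ScreenFitnessTable


@dataclass
class ProfileMatrix:
    """Genes × screen-conditions value matrix.

    ``values`` is a DataFrame indexed by ORF (lexicographic) with one column
    per screen condition ("screen_id|treatment", input order); NaN marks a
    gene absent from that screen.  ``value_kind`` is "fitness" or "gis";
    mixing the two in one matrix is forbidden.
    """

    values: pd.DataFrame = field(repr=False)
    value_kind: str = "fitness"
    gene_names: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise InconsistencyError("duplicate genes in profile matrix")
        if self.values.columns.duplicated().any():
            raise InconsistencyError("duplicate screen conditions in profile matrix")
        if self.value_kind not in ("fitness", "gis"):
            raise InvalidParameterError(f"unknown value_kind {self.value_kind!r}")
        arr = self.values.to_numpy(float)
        if np.any(np.isinf(arr)):
            raise InvalidParameterError("non-finite value in profile matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def screens(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SimilarityRanking:
    """Ranked profile similarity to one query gene.

    ``table`` columns: position (1-based), orf, gene, similarity, n_overlap;
    similarity non-increasing, ties broken lexicographically by ORF; the
    query gene is excluded from its own ranking.
    """

    query_orf: str
    metric: str
    min_overlap: int
    table: pd.DataFrame = field(repr=False)


def screen_condition_label(screen_id: str, treatment: str) -> str:
    return f"{screen_id}|{treatment}"


def build_profile_matrix(tables: list, value_kind: str = "fitness") -> ProfileMatrix:
    """Assemble a ProfileMatrix from screen outputs.

    ``tables`` is a list of ScreenFitnessTable (value_kind="fitness", using
    per-gene mean fitness) or of interaction DataFrames from
    ``compute_interactions`` (value_kind="gis").  Gene set is the union
    across screens; absent gene–screen pairs are missing.  At least two
    screen conditions are required; duplicate condition labels are an error.
    """
    if len(tables) < 2:
        raise InvalidParameterError("at least 2 screen conditions required")
    columns = {}
    gene_names: dict[str, str] = {}
    for tbl in tables:
        if isinstance(tbl, ScreenFitnessTable):
            if value_kind != "fitness":
                raise InvalidParameterError(
                    "fitness tables supplied but value_kind is not 'fitness'")
            label = screen_condition_label(tbl.screen_id, tbl.treatment)
            series = tbl.mean_by_orf
            names = tbl.data.set_index("orf")["gene"]
        elif isinstance(tbl, pd.DataFrame):
            if value_kind != "gis":
                raise InvalidParameterError(
                    "interaction tables supplied but value_kind is not 'gis'")
            label = screen_condition_label(tbl.attrs.get("screen_id", "?"),
                                           tbl.attrs.get("treatment", "?"))
            series = tbl.set_index("orf")["gis"]
            names = tbl.set_index("orf")["gene"]
        else:
            raise InvalidParameterError(f"unsupported table type {type(tbl)!r}")
        if label in columns:
            raise InconsistencyError(f"duplicate screen condition label {label!r}")
        columns[label] = series
        gene_names.update(names.to_dict())

    df = pd.DataFrame(columns)  # outer join on ORF index
    df = df.sort_index()
    df.index.name = "orf"
    return ProfileMatrix(values=df, value_kind=value_kind, gene_names=gene_names)


def normalize_profiles(matrix: ProfileMatrix) -> ProfileMatrix:
    """Per-column z-scores over non-missing entries (sample sd, ddof=1).

    Screens are run at different temperatures and on different scales;
    z-scoring makes profiles comparable across conditions.  Every column
    must have at least 3 non-missing values and nonzero spread.
    """
    df = matrix.values
    out = {}
    for col in df.columns:
        vals = df[col]
        ok = vals.dropna()
        if len(ok) < 3:
            raise DegenerateColumnError(
                f"screen {col!r} has only {len(ok)} non-missing values (3 required)")
        sd = ok.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateColumnError(f"screen {col!r} has zero spread")
        out[col] = (vals - ok.mean()) / sd
    return ProfileMatrix(values=pd.DataFrame(out, index=df.index),
                         value_kind=matrix.value_kind,
                         gene_names=matrix.gene_names)


def _pairwise_similarity(a: np.ndarray, b: np.ndarray, metric: str):
    """Similarity over screens where both profiles are non-missing."""
    mask = ~(np.isnan(a) | np.isnan(b))
    n = int(mask.sum())
    if n == 0:
        return np.nan, 0
    x, y = a[mask], b[mask]
    if metric == "pearson":
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return np.nan, n
        return float(np.corrcoef(x, y)[0, 1]), n
    # euclidean: negated root-mean-square difference, so larger is more similar
    return -float(np.sqrt(np.mean((x - y) ** 2))), n


def rank_similar_profiles(matrix: ProfileMatrix, query_orf: str,
                          metric: str = "pearson",
                          min_overlap: int = 4) -> SimilarityRanking:
    """Rank all other genes by profile similarity to ``query_orf``.

    Overlap is pairwise-complete: similarity uses only the screens where both
    the query and the candidate are non-missing, and candidates overlapping
    in fewer than ``min_overlap`` screens are excluded.  Positions are
    1-based; ties are broken lexicographically by ORF.
    """
    if metric not in ("pearson", "euclidean"):
        raise InvalidParameterError(f"unknown metric {metric!r}")
    if min_overlap < 2:
        raise InvalidParameterError(f"min_overlap must be >= 2, got {min_overlap}")
    df = matrix.values
    if query_orf not in df.index:
        raise NoProfileError(f"query gene {query_orf!r} not in profile matrix")
    qprof = df.loc[query_orf].to_numpy(float)
    if np.all(np.isnan(qprof)):
        raise NoProfileError(f"query gene {query_orf!r} has an entirely missing profile")

    rows = []
    for orf in df.index:
        if orf == query_orf:
            continue
        sim, n = _pairwise_similarity(qprof, df.loc[orf].to_numpy(float), metric)
        if n < min_overlap or np.isnan(sim):
            continue
        rows.append((orf, matrix.gene_names.get(orf, orf), sim, n))

    rows.sort(key=lambda rec: (-rec[2], rec[0]))
    table = pd.DataFrame(rows, columns=["orf", "gene", "similarity", "n_overlap"])
    table.insert(0, "position", np.arange(1, len(table) + 1))
    return SimilarityRanking(query_orf=query_orf, metric=metric,
                             min_overlap=min_overlap, table=table)
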