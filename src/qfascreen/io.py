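"""Tab-delimited readers and writers for every pipeline table.

All data products are plain TSV with fixed headers, "NA" for missing values
and numeric fields at 6 significant digits (raw time-series intensities keep
full double precision so simulation output round-trips exactly).  Times are
in days throughout; a raw file declaring a ``time_hours`` column is
converted on read.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError
from .growth import GrowthCurve, ScreenFitnessTable
from .profiles import ProfileMatrix, SimilarityRanking

NA = "NA"

RAW_COLUMNS = ["screen_id", "barcode", "row", "column", "orf", "gene",
               "background", "treatment", "time_days", "intensity"]
BACKGROUNDS = {"control", "query"}


def _fmt(value, precision: str = "%.6g") -> str:
    if value is None:
        return NA
    if isinstance(value, float) and np.isnan(value):
        return NA
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return precision % value


# ---------------------------------------------------------------------------
# raw time series
# ---------------------------------------------------------------------------

def read_raw_timeseries(path) -> list[GrowthCurve]:
    """Read a raw colony time-series table into GrowthCurve records.

    One row per culture per timepoint; cultures are keyed by
    (screen_id, barcode, row, column), so row order on disk does not matter.
    Within a culture, times must be strictly increasing after key-based
    grouping and time sorting is *not* applied — non-monotone times are a
    data error naming the culture.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"screen_id": str, "barcode": str,
                            "orf": str, "gene": str,
                            "background": str, "treatment": str})
    time_col = "time_days"
    hours = False
    if "time_days" not in df.columns and "time_hours" in df.columns:
        time_col, hours = "time_hours", True
    for col in RAW_COLUMNS:
        probe = time_col if col == "time_days" else col
        if probe not in df.columns:
            raise SchemaError(f"raw time-series file missing column {col!r}")
    bad = set(df["background"]) - BACKGROUNDS
    if bad:
        raise DataError(f"unknown background label(s): {sorted(bad)}")

    df = df.copy()
    if hours:
        df["time_days"] = df["time_hours"] / 24.0

    curves = []
    keys = ["screen_id", "barcode", "row", "column"]
    for key, grp in df.groupby(keys, sort=True):
        grp = grp.sort_index()  # keep file order within culture
        times = grp["time_days"].to_numpy(float)
        if np.any(np.diff(times) <= 0):
            raise DataError(f"non-monotone times for culture {key}")
        curves.append(GrowthCurve(
            screen_id=key[0], plate_barcode=key[1], row=int(key[2]),
            column=int(key[3]), orf=grp["orf"].iloc[0], gene=grp["gene"].iloc[0],
            background=grp["background"].iloc[0],
            treatment=grp["treatment"].iloc[0],
            times=times, intensities=grp["intensity"].to_numpy(float)))
    return curves


def write_raw_timeseries(curves: list[GrowthCurve], path) -> None:
    """Write GrowthCurves as a raw TSV; floats at full round-trip precision."""
    with open(path, "w") as fh:
        fh.write("\t".join(RAW_COLUMNS) + "\n")
        for c in curves:
            for t, y in zip(c.times, c.intensities):
                fh.write("\t".join([
                    c.screen_id, c.plate_barcode, str(c.row), str(c.column),
                    c.orf, c.gene, c.background, c.treatment,
                    _fmt(float(t), "%.17g"), _fmt(float(y), "%.17g"),
                ]) + "\n")


# ---------------------------------------------------------------------------
# fitness tables
# ---------------------------------------------------------------------------

def write_fitness_table(table: ScreenFitnessTable, path) -> None:
    """Fitness summary TSV; replicate fitnesses in fitness_rep1..repN columns."""
    max_n = int(table.data["n"].max()) if len(table.data) else 0
    rep_cols = [f"fitness_rep{i + 1}" for i in range(max_n)]
    header = ["screen_id", "orf", "gene", "background", "treatment", "n",
              "mdr_mean", "mdp_mean", "fitness_mean", "fitness_median"] + rep_cols
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for rec in table.data.itertuples(index=False):
            reps = list(rec.replicates) + [None] * (max_n - len(rec.replicates))
            fh.write("\t".join(
                [table.screen_id, rec.orf, rec.gene, table.background,
                 table.treatment, str(int(rec.n)),
                 _fmt(rec.mdr_mean), _fmt(rec.mdp_mean),
                 _fmt(rec.fitness_mean), _fmt(rec.fitness_median)]
                + [_fmt(v) for v in reps]) + "\n")


def read_fitness_table(path) -> ScreenFitnessTable:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False,
                     dtype={"screen_id": str, "orf": str, "gene": str,
                            "background": str, "treatment": str})
    required = ["screen_id", "orf", "gene", "background", "treatment", "n",
                "mdr_mean", "mdp_mean", "fitness_mean", "fitness_median"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"fitness table missing column {col!r}")
    rep_cols = [c for c in df.columns if c.startswith("fitness_rep")]
    rows = []
    for rec in df.itertuples(index=False):
        reps = [float(getattr(rec, c)) for c in rep_cols
                if not pd.isna(getattr(rec, c))]
        rows.append({"orf": rec.orf, "gene": rec.gene, "n": int(rec.n),
                     "fitness_mean": float(rec.fitness_mean),
                     "fitness_median": float(rec.fitness_median),
                     "mdr_mean": float(rec.mdr_mean),
                     "mdp_mean": float(rec.mdp_mean),
                     "replicates": reps})
    if df.empty:
        raise DataError(f"fitness table {path} has no rows")
    return ScreenFitnessTable(df["screen_id"].iloc[0], df["background"].iloc[0],
                              df["treatment"].iloc[0], pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# interaction / ranking / profile tables
# ---------------------------------------------------------------------------

INTERACTION_COLUMNS = ["screen_id", "orf", "gene", "F_control", "F_query",
                       "m", "F_pred", "gis", "p", "q", "call"]


def write_interaction_table(estimates: pd.DataFrame, path,
                            screen_id: str | None = None) -> None:
    """Genetic-interaction-strength TSV, one row per shared ORF."""
    sid = screen_id or estimates.attrs.get("screen_id", "NA")
    with open(path, "w") as fh:
        fh.write("\t".join(INTERACTION_COLUMNS) + "\n")
        for rec in estimates.itertuples(index=False):
            fh.write("\t".join([
                sid, rec.orf, rec.gene, _fmt(rec.F_control), _fmt(rec.F_query),
                _fmt(rec.m), _fmt(rec.F_pred), _fmt(rec.gis),
                _fmt(rec.p), _fmt(rec.q), rec.call]) + "\n")


def read_interaction_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False,
                     dtype={"screen_id": str, "orf": str, "gene": str, "call": str})
    for col in INTERACTION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"interaction table missing column {col!r}")
    if len(df):
        df.attrs["screen_id"] = df["screen_id"].iloc[0]
        df.attrs["m"] = float(df["m"].iloc[0])
    return df


RANKING_COLUMNS = ["query_orf", "position", "orf", "gene", "similarity", "n_overlap"]


def write_ranking_table(ranking: SimilarityRanking, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RANKING_COLUMNS) + "\n")
        for rec in ranking.table.itertuples(index=False):
            fh.write("\t".join([
                ranking.query_orf, str(int(rec.position)), rec.orf, rec.gene,
                _fmt(rec.similarity), str(int(rec.n_overlap))]) + "\n")


def read_ranking_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False,
                     dtype={"query_orf": str, "orf": str, "gene": str})
    for col in RANKING_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"ranking table missing column {col!r}")
    return df


def write_profile_matrix(matrix: ProfileMatrix, path) -> None:
    """Profile matrix TSV; first line records the value kind."""
    with open(path, "w") as fh:
        fh.write(f"# value_kind={matrix.value_kind}\n")
        fh.write("\t".join(["orf", "gene"] + matrix.screens) + "\n")
        for orf in matrix.genes:
            vals = matrix.values.loc[orf]
            fh.write("\t".join(
                [orf, matrix.gene_names.get(orf, orf)]
                + [_fmt(None if pd.isna(v) else float(v)) for v in vals]) + "\n")


def read_profile_matrix(path) -> ProfileMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# value_kind="):
            raise SchemaError("profile matrix file missing value_kind header line")
        value_kind = first.split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", na_values=[NA], keep_default_na=False,
                         dtype={"orf": str, "gene": str})
    if "orf" not in df.columns or "gene" not in df.columns:
        raise SchemaError("profile matrix file missing 'orf'/'gene' columns")
    gene_names = dict(zip(df["orf"], df["gene"]))
    values = df.drop(columns=["gene"]).set_index("orf").astype(float)
    return ProfileMatrix(values=values, value_kind=value_kind, gene_names=gene_names)


def write_ground_truth(truth, outdir) -> None:
    """Write simulator ground truth (gene labels and per-culture parameters)."""
    genes = truth.genes.copy()
    genes["m_true"] = truth.m_true
    genes["m_effective"] = truth.m_effective
    _write_df_tsv(genes, os.path.join(outdir, "ground_truth_genes.tsv"))
    _write_df_tsv(truth.cultures, os.path.join(outdir, "ground_truth_cultures.tsv"))


def _write_df_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for rec in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) if isinstance(v, (float, np.floating))
                               else str(v) for v in rec) + "\n")


def ensure_writable(outdir) -> None:
    """Fail before any partial writes if the output directory is unusable."""
    os.makedirs(outdir, exist_ok=True)
    if not os.access(outdir, os.W_OK):
        raise OSError(f"output directory {outdir!r} is not writable")


def write_results_tables(fitness_tables: list[ScreenFitnessTable],
                         interactions: pd.DataFrame | None,
                         rankings: list[SimilarityRanking],
                         outdir) -> dict[str, str]:
    """Write the full product set; returns {logical name: path}."""
    ensure_writable(outdir)
    written = {}
    for tbl in fitness_tables:
        name = f"fitness_{tbl.screen_id}_{tbl.background}.tsv"
        path = os.path.join(outdir, name)
        write_fitness_table(tbl, path)
        written[name] = path
    if interactions is not None:
        path = os.path.join(outdir, "interactions.tsv")
        write_interaction_table(interactions, path)
        written["interactions.tsv"] = path
    for ranking in rankings:
        name = f"ranking_{ranking.query_orf}.tsv"
        path = os.path.join(outdir, name)
        write_ranking_table(ranking, path)
        written[name] = path
    return written
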