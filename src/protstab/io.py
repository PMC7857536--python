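"""Reading and writing the pipeline's tabular and sequence formats.

Trajectories, truth tables, edge lists and disorder strings travel as
TSV; sequences as FASTA (via Biopython). A shim ingests the wide
two-column-per-time-point M/L / H/L spreadsheet layout used by
published pulsed-SILAC supplementary tables (XLSX via openpyxl or TSV)
and converts it to the tidy trajectory schema.
"""

from __future__ import annotations

import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import ProteinRecord
from .kinetics import IsotopeRatioSeries
from .simulate import SyntheticCohort

TRAJECTORY_COLUMNS = ["protein_id", "time_min", "ratio_ML", "ratio_HL",
                      "n_peptides"]


def write_trajectories(df: pd.DataFrame, path) -> None:
    df[TRAJECTORY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns {sorted(missing)}")
    return df


def series_from_frame(df: pd.DataFrame) -> list[IsotopeRatioSeries]:
    """Group a tidy trajectory table into per-protein series."""
    out = []
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            IsotopeRatioSeries(
                protein_id=str(pid),
                t=grp["time_min"].to_numpy(dtype=float),
                ratio_ML=grp["ratio_ML"].to_numpy(dtype=float),
                ratio_HL=grp["ratio_HL"].to_numpy(dtype=float),
                n_peptides=int(grp["n_peptides"].iloc[0]),
                ambiguous=bool(grp["ambiguous"].iloc[0])
                if "ambiguous" in grp else False,
            )
        )
    return out


def read_wide_ratio_table(path_or_df, id_column: str | None = None) -> pd.DataFrame:
    """Ingest a wide M/L-H/L ratio layout into the tidy trajectory schema.

    Expects one row per protein with paired columns named like
    ``Ratio M/L 15``, ``Ratio H/L 15`` (any text containing ``M/L`` or
    ``H/L`` and a number, the number read as minutes), an id column
    (first column by default) and optionally a peptide-count column
    containing ``peptide`` in its name. Accepts a DataFrame, TSV/CSV, or
    XLSX path.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        p = Path(path_or_df)
        if p.suffix in (".xlsx", ".xls"):
            df = pd.read_excel(p)
        else:
            df = pd.read_csv(p, sep="\t" if p.suffix != ".csv" else ",")
    if id_column is None:
        id_column = df.columns[0]

    pat = re.compile(r"([MH])\s*/\s*L\D*?([0-9]+(?:\.[0-9]+)?)")
    ml_cols, hl_cols = {}, {}
    pep_col = None
    for col in df.columns:
        if col == id_column:
            continue
        if "peptide" in str(col).lower():
            pep_col = col
            continue
        m = pat.search(str(col))
        if m:
            t = float(m.group(2))
            (ml_cols if m.group(1) == "M" else hl_cols)[t] = col
    times = sorted(set(ml_cols) | set(hl_cols))
    if not times:
        raise ValueError("no M/L or H/L ratio columns recognized")

    rows = []
    for _, r in df.iterrows():
        n_pep = int(r[pep_col]) if pep_col is not None else 2
        for t in times:
            ml = r[ml_cols[t]] if t in ml_cols else np.nan
            hl = r[hl_cols[t]] if t in hl_cols else np.nan
            if pd.isna(ml) and pd.isna(hl):
                continue
            rows.append(
                {
                    "protein_id": str(r[id_column]),
                    "time_min": t,
                    "ratio_ML": float(ml) if not pd.isna(ml) else np.nan,
                    "ratio_HL": float(hl) if not pd.isna(hl) else np.nan,
                    "n_peptides": n_pep,
                }
            )
    out = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    return out.dropna(subset=["ratio_ML"]).reset_index(drop=True)


def write_fasta(sequences: pd.DataFrame, path) -> None:
    records = [
        SeqRecord(Seq(row.sequence), id=str(row.protein_id), description="")
        for row in sequences.itertuples()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> pd.DataFrame:
    rows = [
        {"protein_id": rec.id, "sequence": str(rec.seq)}
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return pd.DataFrame(rows, columns=["protein_id", "sequence"])


def write_edges(edges: pd.DataFrame, path) -> None:
    edges[["id_a", "id_b"]].to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def graph_from_edges(edges: pd.DataFrame, nodes=None) -> nx.Graph:
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges[["id_a", "id_b"]].itertuples(index=False))
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def write_disorder(disorder: pd.DataFrame, path) -> None:
    disorder[["protein_id", "disorder"]].to_csv(path, sep="\t", index=False)


def read_disorder(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def records_from_tables(
    sequences: pd.DataFrame, disorder: pd.DataFrame | None = None
) -> list[ProteinRecord]:
    dis = (
        disorder.set_index("protein_id")["disorder"].to_dict()
        if disorder is not None
        else {}
    )
    return [
        ProteinRecord(row.protein_id, row.sequence,
                      dis.get(row.protein_id))
        for row in sequences.itertuples()
    ]


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write every table of a synthetic cohort; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectories": outdir / "trajectories.tsv",
        "truth": outdir / "truth.tsv",
        "sequences": outdir / "sequences.fasta",
        "edges": outdir / "edges.tsv",
        "disorder": outdir / "disorder.tsv",
    }
    write_trajectories(cohort.trajectories, paths["trajectories"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    write_fasta(cohort.sequences, paths["sequences"])
    write_edges(cohort.edges, paths["edges"])
    write_disorder(cohort.disorder, paths["disorder"])
    return paths
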