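"""File I/O: cohort matrices (HDF5 + TSV), atlases (TSV) and phenotypes.

Phenotype files use the GCTA/OSCA three-column whitespace dialect
(family id, subject id, value; missing coded ``NA``).
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .data import CohortMatrix, VertexAtlas

__all__ = [
    "write_cohort_h5",
    "read_cohort_h5",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_atlas",
    "read_atlas",
    "write_phenotype",
    "read_phenotype",
]


# ---------------------------------------------------------------------------
# cohort matrices
# ---------------------------------------------------------------------------


def write_cohort_h5(data: CohortMatrix, path) -> None:
    """Write a cohort to an HDF5 container.

    Datasets: ``values``, ``subject_id``, ``covariates`` (+ column names),
    and ``col_means``/``col_sds`` when the cohort is standardized.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=data.values)
        f.create_dataset(
            "subject_id", data=np.array(data.subject_id, dtype="S")
        )
        f.create_dataset("covariates", data=data.covariates.to_numpy(dtype=np.float64))
        f.create_dataset(
            "covariate_names",
            data=np.array(list(data.covariates.columns), dtype="S"),
        )
        f.attrs["standardized"] = bool(data.standardized)
        if data.col_means is not None:
            f.create_dataset("col_means", data=data.col_means)
        if data.col_sds is not None:
            f.create_dataset("col_sds", data=data.col_sds)


def read_cohort_h5(path) -> CohortMatrix:
    with h5py.File(path, "r") as f:
        subject_id = [s.decode() for s in f["subject_id"][()]]
        names = [s.decode() for s in f["covariate_names"][()]]
        cov = pd.DataFrame(f["covariates"][()], columns=names)
        return CohortMatrix(
            subject_id=subject_id,
            values=f["values"][()],
            covariates=cov,
            standardized=bool(f.attrs["standardized"]),
            col_means=f["col_means"][()] if "col_means" in f else None,
            col_sds=f["col_sds"][()] if "col_sds" in f else None,
        )


def write_cohort_tsv(data: CohortMatrix, values_path, covariates_path=None) -> None:
    """TSV fallback: subjects x vertices with vertex ids as header."""
    df = pd.DataFrame(
        data.values,
        index=pd.Index(data.subject_id, name="subject_id"),
        columns=np.arange(data.n_vertices),
    )
    df.to_csv(values_path, sep="\t")
    if covariates_path is not None:
        cov = data.covariates.copy()
        cov.insert(0, "subject_id", data.subject_id)
        cov.to_csv(covariates_path, sep="\t", index=False)


def read_cohort_tsv(values_path, covariates_path=None) -> CohortMatrix:
    df = pd.read_csv(values_path, sep="\t", index_col=0)
    subject_id = [str(s) for s in df.index]
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, sep="\t")
        cov = cov.drop(columns=["subject_id"], errors="ignore")
    else:
        cov = pd.DataFrame(index=range(len(df)))
    return CohortMatrix(
        subject_id=subject_id,
        values=df.to_numpy(dtype=np.float64),
        covariates=cov,
    )


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


def write_atlas(atlas: VertexAtlas, vertices_path, edges_path) -> None:
    """Two TSVs: vertex annotations and the edge list (smaller id first)."""
    atlas.table.to_csv(vertices_path, sep="\t", index=False)
    pd.DataFrame(atlas.edges, columns=["v1", "v2"]).to_csv(
        edges_path, sep="\t", index=False
    )


def read_atlas(vertices_path, edges_path) -> VertexAtlas:
    table = pd.read_csv(vertices_path, sep="\t")
    edges = pd.read_csv(edges_path, sep="\t").to_numpy(dtype=np.int64)
    atlas = VertexAtlas(table=table, edges=edges)
    atlas.validate()
    return atlas


# ---------------------------------------------------------------------------
# phenotypes (GCTA/OSCA dialect)
# ---------------------------------------------------------------------------


def write_phenotype(y, subject_id, path) -> None:
    """Three whitespace-separated columns: FID IID value (NA = missing)."""
    y = np.asarray(y, dtype=np.float64)
    with open(path, "w") as f:
        for sid, val in zip(subject_id, y):
            sval = "NA" if not np.isfinite(val) else repr(float(val))
            f.write(f"{sid} {sid} {sval}\n")


def read_phenotype(path, subject_id=None) -> np.ndarray:
    """Read a phenotype vector, optionally aligned to ``subject_id`` order.

    Missing values (``NA``) become ``nan``; subjects absent from the file
    also become ``nan`` when aligning.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "value"],
        dtype={"fid": str, "iid": str},
        na_values=["NA", "na"],
    )
    if subject_id is None:
        return df["value"].to_numpy(dtype=np.float64)
    lookup = dict(zip(df["iid"], df["value"].to_numpy(dtype=np.float64)))
    return np.array([lookup.get(str(s), np.nan) for s in subject_id])
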