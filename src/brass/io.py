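"""Plain-text and GCTA-format input/output.

Phenotypes and covariates travel as TSV with a header and an ``IID`` sample
column; missing values are rejected (no imputation).  GRMs are supported both
as square plain-text matrices with an ID header row and in the GCTA binary
pair (``.grm.bin`` lower-triangle float32 + ``.grm.id``).  Genotypes can be
read from PLINK ``.raw``-style dosage tables or plain matrix TSV.  Replicate
sets are written as TSV (samples x replicates) or HDF5 with a metadata block.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .transform import ReplicateSet

__all__ = [
    "read_phenotype", "read_covariates", "read_grm_text", "write_grm_text",
    "read_grm_gcta", "write_grm_gcta", "read_raw_genotypes",
    "write_replicates_tsv", "write_replicates_h5", "read_replicates_h5",
]


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "IID" not in df.columns:
        raise ValueError(f"{path}: expected an 'IID' sample-identifier column")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values are not supported")
    return df.set_index("IID")


def read_phenotype(path, column: str | None = None) -> pd.Series:
    """Binary phenotype from TSV (IID + one trait column)."""
    df = _read_table(path)
    col = column or df.columns[0]
    y = df[col].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"{path}: phenotype column {col!r} is not 0/1")
    return y


def read_covariates(path, add_intercept: bool = True) -> pd.DataFrame:
    """Covariate table from TSV; optionally prepend an intercept column."""
    df = _read_table(path).astype(float)
    if add_intercept and "intercept" not in df.columns:
        df.insert(0, "intercept", 1.0)
    return df


def read_grm_text(path) -> tuple[np.ndarray, list]:
    """Square plain-text GRM with sample IDs as header row; returns (matrix, ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    phi = df.to_numpy(dtype=float)
    if phi.shape[0] != phi.shape[1]:
        raise ValueError(f"{path}: GRM is not square")
    return phi, list(df.columns)


def write_grm_text(path, phi: np.ndarray, ids) -> None:
    pd.DataFrame(phi, index=list(ids), columns=list(ids)).to_csv(path, sep="\t")


def write_grm_gcta(prefix, phi: np.ndarray, ids) -> None:
    """GCTA pair: <prefix>.grm.bin (float32 lower triangle) and <prefix>.grm.id."""
    prefix = Path(prefix)
    n = phi.shape[0]
    tri = phi[np.tril_indices(n)].astype("<f4")
    tri.tofile(str(prefix) + ".grm.bin")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for s in ids:
            fh.write(f"{s}\t{s}\n")


def read_grm_gcta(prefix) -> tuple[np.ndarray, list]:
    prefix = str(prefix)
    ids = [line.split()[1] for line in open(prefix + ".grm.id")]
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError(f"{prefix}.grm.bin: size does not match {n} samples")
    phi = np.zeros((n, n))
    phi[np.tril_indices(n)] = tri
    phi = phi + np.tril(phi, -1).T
    return phi, ids


def read_raw_genotypes(path) -> pd.DataFrame:
    """PLINK .raw-style dosage table (or a plain IID + markers TSV).

    Drops the FID/PAT/MAT/SEX/PHENOTYPE bookkeeping columns if present;
    remaining columns are additive dosages indexed by IID.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if "IID" not in df.columns:
        raise ValueError(f"{path}: expected an 'IID' column")
    drop = [c for c in ("FID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    return df.drop(columns=drop).set_index("IID").astype(float)


def _replicate_metadata(reps: ReplicateSet) -> dict:
    meta = {"seed": reps.seed, "binary": reps.binary, "method": reps.method}
    meta.update({k: v for k, v in reps.metadata.items()})
    return meta


def write_replicates_tsv(path, reps: ReplicateSet, ids=None) -> None:
    """Samples x replicates TSV with a commented metadata header."""
    r = reps.replicates.T
    ids = ids if ids is not None else [f"S{i:06d}" for i in range(r.shape[0])]
    with open(path, "w") as fh:
        for k, v in _replicate_metadata(reps).items():
            fh.write(f"# {k}: {v}\n")
        pd.DataFrame(
            r, index=pd.Index(ids, name="IID"),
            columns=[f"rep{j}" for j in range(r.shape[1])],
        ).to_csv(fh, sep="\t")


def write_replicates_h5(path, reps: ReplicateSet, ids=None) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("replicates", data=reps.replicates)
        for k, v in _replicate_metadata(reps).items():
            if v is not None:
                ds.attrs[k] = v
        if ids is not None:
            fh.create_dataset("ids", data=np.asarray(ids, dtype="S"))


def read_replicates_h5(path) -> ReplicateSet:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["replicates"]
        attrs = dict(ds.attrs)
        return ReplicateSet(
            replicates=ds[...],
            seed=int(attrs.pop("seed")) if "seed" in attrs else None,
            binary=bool(attrs.pop("binary", False)),
            method=str(attrs.pop("method", "unknown")),
            metadata=attrs,
        )
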