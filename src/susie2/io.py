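"""File formats: genotype matrices, phenotype/summary tables, LD matrices.

All delimited files are tab-separated with ``#``-prefixed comment headers;
output tables carry a header naming the tool version and a hash of the
configuration that produced them.  VCF input (read-only, uncompressed or
bgzipped) is restricted to biallelic sites with dosage = ALT-allele count.
Genomic positions, where present, are 1-based inclusive (VCF convention);
fine-mapping itself operates on the variant index space.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

log = logging.getLogger("susie2")

__all__ = [
    "VariantTable",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_summary_stats",
    "write_table",
    "write_results",
    "write_credible_sets",
    "provenance_record",
    "config_hash",
]


class VariantTable(pd.DataFrame):
    """Per-variant metadata aligned with matrix columns.

    A thin DataFrame with at least a unique ``variant_id`` column and an
    implicit column-index correspondence; optional ``chrom``/``pos``
    (1-based).
    """

    @property
    def _constructor(self):
        return VariantTable


def _make_variant_table(ids, chrom=None, pos=None) -> VariantTable:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise ValueError(f"duplicated variant id: {dup}")
    d = {"variant_id": ids}
    if chrom is not None:
        d["chrom"] = chrom
    if pos is not None:
        d["pos"] = pos
    return VariantTable(d)


def config_hash(obj) -> str:
    """Short stable hash of a configuration object (dict-able or dataclass)."""
    if hasattr(obj, "__dict__"):
        obj = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in obj.__dict__.items()
        }
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(config=None) -> list[str]:
    lines = [f"# susie2 v{__version__}"]
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    return lines


def _standardize(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    nz = sd > 0
    X[:, nz] /= sd[nz]
    return X


def _read_genotypes_delimited(path) -> tuple[np.ndarray, VariantTable]:
    with open(path) as fh:  # pandas mangles duplicate header names
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
        else:
            raise ValueError(f"{path}: empty genotype table")
    if len(set(header)) != len(header):
        dup = pd.Series(header)[pd.Series(header).duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated variant id: {dup}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed genotype table ({exc})") from exc
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no variant columns found")
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        # report the first offending cell with its line number
        col = bad[0]
        row = int(pd.to_numeric(df[col], errors="coerce").isna().idxmax())
        raise ValueError(
            f"{path}: non-numeric genotype in column {col!r} near data "
            f"line {row + 1}"
        )
    X = df.to_numpy(dtype=float)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        log.info("%s: mean-imputing %d missing genotypes", path, n_missing)
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(col_mean, idx[1])
    return _standardize(X), _make_variant_table(df.columns)


def _read_genotypes_vcf(path) -> tuple[np.ndarray, VariantTable]:
    from cyvcf2 import VCF

    ids, chroms, poss, cols = [], [], [], []
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1:
            warnings.warn(
                f"{path}: skipping multiallelic record at "
                f"{rec.CHROM}:{rec.POS}"
            )
            continue
        gt = np.asarray(rec.gt_types, dtype=float)  # 0/1/2 hom-ref..hom-alt, 3 unknown
        dosage = np.where(gt == 3, np.nan, gt)
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        ids.append(vid)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        cols.append(dosage)
    if not cols:
        raise ValueError(f"{path}: no biallelic records found")
    X = np.column_stack(cols)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        log.info("%s: mean-imputing %d missing genotypes", path, n_missing)
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(col_mean, idx[1])
    return _standardize(X), _make_variant_table(ids, chroms, poss)


def read_genotypes(path, format: str = "delimited"):
    """Load a genotype matrix; returns (standardized X, VariantTable).

    ``format="delimited"``: TSV with a header row of variant ids, one row
    per sample, ``#`` comments allowed; missing cells are mean-imputed per
    variant (count logged).  ``format="vcf"``: biallelic records only,
    dosage = ALT-allele count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        return _read_genotypes_delimited(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(path, X: np.ndarray, variant_ids=None, config=None) -> None:
    """Write a genotype/dosage matrix as TSV (samples x variants)."""
    X = np.asarray(X)
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(X.shape[1])]
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(config)) + "\n")
        pd.DataFrame(X, columns=list(variant_ids)).to_csv(
            fh, sep="\t", index=False, float_format="%.10g"
        )


def read_phenotype(path) -> np.ndarray:
    """Read a single-column phenotype vector (``#`` comments allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.iloc[:, -1].to_numpy(dtype=float)


def write_phenotype(path, y: np.ndarray, name: str = "phenotype",
                    config=None) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(config)) + "\n")
        pd.DataFrame({name: np.asarray(y, float)}).to_csv(
            fh, sep="\t", index=False, float_format="%.10g"
        )


def read_ld_matrix(path) -> np.ndarray:
    """Square whitespace-delimited LD correlation matrix."""
    R = np.loadtxt(path, comments="#")
    R = np.atleast_2d(R)
    if R.shape[0] != R.shape[1]:
        raise ValueError(f"{path}: LD matrix is {R.shape}, expected square")
    return R


def write_ld_matrix(path, R: np.ndarray, config=None) -> None:
    header = "\n".join(line.lstrip("# ") for line in _header_lines(config))
    np.savetxt(path, np.asarray(R, float), fmt="%.8g", header=header)


def read_summary_stats(
    path, variant_ids: np.ndarray | None = None
) -> pd.DataFrame:
    """Summary-statistic table: columns variant_id, z (or bhat+shat), n.

    If ``variant_ids`` is given (e.g. the LD matrix row order), the table
    order must match exactly; a mismatch is a hard error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"variant_id"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {need - set(df.columns)}")
    if "z" not in df.columns and not {"bhat", "shat"}.issubset(df.columns):
        raise ValueError(f"{path}: need a 'z' column or 'bhat'+'shat'")
    if variant_ids is not None:
        ids = df["variant_id"].to_numpy()
        ref = np.asarray(variant_ids)
        if len(ids) != len(ref) or not np.array_equal(ids, ref):
            raise ValueError(
                f"{path}: variant order does not match the LD matrix order"
            )
    return df


def write_table(path, df: pd.DataFrame, config=None) -> None:
    """Write a tidy TSV with the standard provenance header."""
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(config)) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def write_results(path, fit, variant_ids=None, config=None) -> None:
    """Per-variant results: variant_id, pip, per-effect alpha, cs_id."""
    K, p = fit.alpha.shape
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(p)]
    cs_id = np.full(p, "", dtype=object)
    for i, cs in enumerate(fit.credible_sets):
        for j in cs.variant_indices:
            cs_id[j] = f"cs{i + 1}" if not cs_id[j] else cs_id[j]
    df = pd.DataFrame({"variant_id": list(variant_ids), "pip": fit.pip})
    for k in range(K):
        df[f"alpha{k + 1}"] = fit.alpha[k]
    df["cs_id"] = cs_id
    write_table(path, df, config=config)


def write_credible_sets(path, fit, variant_ids=None, config=None) -> None:
    """Credible sets: cs_id, variant_id, alpha, min_abs_corr."""
    p = fit.alpha.shape[1]
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(p)]
    rows = []
    for i, cs in enumerate(fit.credible_sets):
        for j in cs.variant_indices:
            rows.append(
                {
                    "cs_id": f"cs{i + 1}",
                    "variant_id": variant_ids[int(j)],
                    "alpha": fit.alpha[cs.effect_index, int(j)],
                    "min_abs_corr": cs.min_abs_corr,
                }
            )
    cols = ["cs_id", "variant_id", "alpha", "min_abs_corr"]
    write_table(path, pd.DataFrame(rows, columns=cols), config=config)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def provenance_record(out_path, config, seed=None, inputs=None) -> dict:
    """Write a machine-readable provenance JSON (config, seed, versions,
    input checksums); returns the record."""
    rec = {
        "tool": "susie2",
        "version": __version__,
        "seed": seed,
        "config": config
        if isinstance(config, (dict, type(None)))
        else {k: str(v) for k, v in config.__dict__.items()},
        "config_hash": config_hash(config) if config is not None else None,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "inputs": {str(p): _sha256(p) for p in (inputs or [])},
    }
    with open(out_path, "w") as fh:
        json.dump(rec, fh, indent=2, default=str)
    return rec
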