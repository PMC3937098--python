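"""File I/O: matrix TSVs, model archives, edge lists, interval and gene-set files.

Matrices travel as tab-separated text with a header row of column IDs (SNP or
gene IDs) and a first column of sample IDs, rendered at full decimal
precision so a write/read round trip is exact.  Fitted models are serialized
as canonical JSON (sorted keys, sparse triplets with ``repr`` floats), which
makes the determinism contract — identical config and seed give byte-identical
archives — directly auditable with a byte comparison.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CGGMModel, GeneExpressionMatrix, GenotypeMatrix
from .netanalysis import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_network_edgelist",
    "read_network_edgelist",
    "save_model",
    "load_model",
    "read_intervals_bed",
    "read_gene_sets",
    "align_samples",
]

ARCHIVE_VERSION = 1


def read_matrix_tsv(path, kind: str):
    """Read a genotype or expression TSV (header = column IDs, col 0 = sample IDs).

    ``kind`` is ``"genotype"`` (values validated to be allele counts in
    {0,1,2}) or ``"expression"`` (any finite reals).  Ragged rows, non-numeric
    cells and duplicate IDs raise a parse error naming the offending location.
    """
    if kind not in ("genotype", "expression"):
        raise ValueError(f"kind must be 'genotype' or 'expression', got {kind!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate column ID {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell at sample {df.index[i]!r}, "
                        f"column {df.columns[j]!r}: {cell!r} (line {i + 2})"
                    ) from exc
        raise
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: missing/non-finite value at sample {df.index[i]!r}, "
            f"column {df.columns[j]!r} (line {i + 2})"
        )
    sample_ids = [str(s) for s in df.index]
    col_ids = [str(c) for c in df.columns]
    if kind == "genotype":
        if values.size and not np.isin(values, (0.0, 1.0, 2.0)).all():
            i, j = np.argwhere(~np.isin(values, (0.0, 1.0, 2.0)))[0]
            raise ValueError(
                f"{path}: genotype value {values[i, j]!r} not in {{0,1,2}} at "
                f"sample {sample_ids[i]!r}, SNP {col_ids[j]!r} (line {i + 2})"
            )
        return GenotypeMatrix(values, col_ids, sample_ids, standardized=False)
    return GeneExpressionMatrix(values, col_ids, sample_ids, centered=False)


def write_matrix_tsv(values: np.ndarray, row_ids: list[str], col_ids: list[str], path) -> None:
    """Write a matrix as TSV with full-precision decimals (exact round trip)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(["id", *col_ids]) + "\n")
        for rid, row in zip(row_ids, np.asarray(values)):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def align_samples(
    X: GenotypeMatrix, Y: GeneExpressionMatrix
) -> tuple[GenotypeMatrix, GeneExpressionMatrix]:
    """Align genotype/expression matrices on their shared samples.

    Order follows the expression file; samples present in only one file are
    dropped and logged.
    """
    shared = [s for s in Y.sample_ids if s in set(X.sample_ids)]
    dropped = (set(X.sample_ids) | set(Y.sample_ids)) - set(shared)
    if dropped:
        logger.info("dropping %d unmatched sample(s): %s", len(dropped),
                    sorted(dropped)[:10])
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared samples between genotype and expression files")
    xi = {s: i for i, s in enumerate(X.sample_ids)}
    yi = {s: i for i, s in enumerate(Y.sample_ids)}
    Xa = GenotypeMatrix(X.values[[xi[s] for s in shared]], list(X.snp_ids), shared,
                        standardized=X.standardized)
    Ya = GeneExpressionMatrix(Y.values[[yi[s] for s in shared]], list(Y.gene_ids), shared,
                              centered=False)
    return Xa, Ya


def _triplets(M: np.ndarray) -> list[list]:
    rows, cols = np.nonzero(M)
    return [[int(i), int(j), repr(float(M[i, j]))] for i, j in zip(rows, cols)]


def save_model(model: CGGMModel, path) -> None:
    """Serialize a model as canonical JSON (sparse triplets, repr floats)."""
    p, q = model.n_genes, model.n_snps
    fit_info = {k: v for k, v in model.fit_info.items() if k != "objective_trace"}
    payload = {
        "format_version": ARCHIVE_VERSION,
        "p": p,
        "q": q,
        "lambda_net": repr(float(model.lambda_net)),
        "lambda_perturb": repr(float(model.lambda_perturb)),
        "Lambda": _triplets(model.Lambda),
        "Theta": _triplets(model.Theta),
        "gene_ids": model.gene_ids,
        "snp_ids": model.snp_ids,
        "fit_info": json.loads(json.dumps(fit_info, default=float)),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def load_model(path) -> CGGMModel:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != ARCHIVE_VERSION:
        raise ValueError(f"unsupported model archive version {version!r}")
    p, q = payload["p"], payload["q"]
    Lambda = np.zeros((p, p))
    for i, j, v in payload["Lambda"]:
        Lambda[i, j] = float(v)
    Theta = np.zeros((q, p))
    for i, j, v in payload["Theta"]:
        Theta[i, j] = float(v)
    return CGGMModel(
        Lambda=Lambda,
        Theta=Theta,
        lambda_net=float(payload["lambda_net"]),
        lambda_perturb=float(payload["lambda_perturb"]),
        fit_info=payload.get("fit_info", {}),
        gene_ids=payload.get("gene_ids"),
        snp_ids=payload.get("snp_ids"),
    )


def write_network_edgelist(
    Lambda: np.ndarray,
    path,
    format: str = "tsv",
    gene_ids: list[str] | None = None,
    tol: float = 0.0,
) -> None:
    """Write the upper-triangle nonzeros of Λ as an edge list.

    ``tsv`` rows are ``gene_i<TAB>gene_j<TAB>weight`` (full precision);
    ``sif`` rows are ``gene_i<TAB>pp<TAB>gene_j`` for network viewers.
    Ordering is deterministic (by index pair).
    """
    if format not in ("tsv", "sif"):
        raise ValueError(f"format must be 'tsv' or 'sif', got {format!r}")
    Lambda = np.asarray(Lambda, dtype=float)
    if np.max(np.abs(Lambda - Lambda.T), initial=0.0) > 1e-10:
        raise ValueError("Lambda must be symmetric")
    p = Lambda.shape[0]
    ids = gene_ids if gene_ids is not None else [f"g{j}" for j in range(p)]
    with open(path, "w") as fh:
        for i in range(p):
            for j in range(i + 1, p):
                w = Lambda[i, j]
                if abs(w) > tol:
                    if format == "tsv":
                        fh.write(f"{ids[i]}\t{ids[j]}\t{repr(float(w))}\n")
                    else:
                        fh.write(f"{ids[i]}\tpp\t{ids[j]}\n")


def read_network_edgelist(path, gene_ids: list[str]) -> np.ndarray:
    """Rebuild a symmetric matrix from a tsv edge list (inverse of the writer)."""
    idx = {g: i for i, g in enumerate(gene_ids)}
    M = np.zeros((len(gene_ids), len(gene_ids)))
    with open(path) as fh:
        for line in fh:
            a, b, w = line.rstrip("\n").split("\t")
            M[idx[a], idx[b]] = M[idx[b], idx[a]] = float(w)
    return M


def read_intervals_bed(path) -> dict[str, GenomicInterval]:
    """Read a BED-like interval file: chrom, start, end, id (tab-separated)."""
    out: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {ln}: expected 4 tab-separated fields")
            chrom, start, end, iid = parts[:4]
            out[iid] = GenomicInterval(chrom, int(start), int(end), iid)
    return out


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read gene sets: one per line, ``set_id<TAB>gene1,gene2,...``."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {ln}: expected 'set_id<TAB>genes'")
            out[parts[0]] = {g for g in parts[1].split(",") if g}
    return out
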