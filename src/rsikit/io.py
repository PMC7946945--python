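"""Reading and writing the pipeline's tabular formats.

Counts and expression travel as gene x sample TSV (first column = gene ids,
header row = sample ids) or MatrixMarket (.mtx plus row/column index files);
sample metadata, truth tables and DE results as TSV.  Lines starting with
``#`` are treated as comments so outputs can carry a provenance header.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .containers import CountMatrix, DEResult, EBayesParams, ExpressionMatrix


def _header_lines(params: dict | None) -> str:
    from . import __version__

    head = f"# rsikit v{__version__}\n"
    if params:
        head += "# parameters: " + json.dumps(params, sort_keys=True, default=str) + "\n"
    return head


def write_matrix_tsv(values: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        values.to_csv(fh, sep="\t", index_label="gene")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(None))
        samples.to_csv(fh, sep="\t", index=False)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def write_counts(counts: CountMatrix, prefix: str | Path, mtx: bool = False) -> None:
    """Write counts as ``<prefix>_counts.tsv`` + ``<prefix>_samples.tsv``
    (and optionally MatrixMarket with row/column index files)."""
    prefix = Path(prefix)
    write_matrix_tsv(counts.values, prefix.with_name(prefix.name + "_counts.tsv"))
    write_sample_table(counts.samples, prefix.with_name(prefix.name + "_samples.tsv"))
    if mtx:
        scipy_io.mmwrite(
            prefix.with_name(prefix.name + "_counts.mtx"),
            sparse.csr_matrix(counts.values.to_numpy()),
        )
        prefix.with_name(prefix.name + "_counts.mtx.rownames").write_text(
            "\n".join(map(str, counts.gene_ids)) + "\n"
        )
        prefix.with_name(prefix.name + "_counts.mtx.colnames").write_text(
            "\n".join(map(str, counts.sample_ids)) + "\n"
        )


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    values = read_matrix_tsv(counts_path)
    samples = read_sample_table(samples_path)
    return CountMatrix(values, samples)


def read_counts_mtx(mtx_path: str | Path, samples_path: str | Path) -> CountMatrix:
    mtx_path = Path(mtx_path)
    mat = scipy_io.mmread(mtx_path)
    genes = Path(str(mtx_path) + ".rownames").read_text().splitlines()
    cols = Path(str(mtx_path) + ".colnames").read_text().splitlines()
    values = pd.DataFrame(
        sparse.csr_matrix(mat).toarray(), index=pd.Index(genes, name="gene"), columns=cols
    )
    return CountMatrix(values, read_sample_table(samples_path))


def read_expression(matrix_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    return ExpressionMatrix(read_matrix_tsv(matrix_path), read_sample_table(samples_path))


def write_de_result(result: DEResult, path: str | Path) -> None:
    params: dict = {"contrast": result.contrast, **result.info}
    if result.priors is not None:
        params.update(
            d0=result.priors.d0, s0_sq=result.priors.s0_sq,
            p1=result.priors.p1, v0=result.priors.v0,
        )
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        result.table.to_csv(fh, sep="\t", index_label="gene")


def read_de_result(path: str | Path, contrast: str | None = None) -> DEResult:
    priors = None
    name = contrast
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# parameters: "):
                params = json.loads(line[len("# parameters: "):])
                if name is None:
                    name = params.get("contrast")
                if "d0" in params:
                    d0 = params["d0"]
                    priors = EBayesParams(
                        d0=float("inf") if d0 in ("inf", "Infinity") else float(d0),
                        s0_sq=float(params["s0_sq"]),
                        p1=float(params["p1"]),
                        v0=float(params["v0"]),
                    )
    table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return DEResult(table=table, contrast=name or "unknown", priors=priors)


def write_table(df: pd.DataFrame, path: str | Path, params: dict | None = None, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        df.to_csv(fh, sep="\t", index=index)
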