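"""File I/O: trace tables, coordinate tables, count matrices, atlases.

Formats are plain text throughout: long-form CSV for traces (one row per
frame), CSV for coordinates, MatrixMarket MTX with TSV sidecars (or a wide
TSV) for counts and atlas detection, TSV for score and candidate tables.
Every reader validates shape and domain and names the offending entry on
failure; write→read round-trips are identity on values and labels.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import FormatError
from .expression import AtlasDetection, CountMatrix
from .scoring import FluorescenceTrace

TRACE_COLUMNS = ["neuron_id", "fish_id", "genotype", "repeat", "roi_size", "frame_index", "F"]
COORD_COLUMNS = ["neuron_id", "genotype", "label", "x_um", "y_um", "z_um"]


# --- fluorescence traces ---------------------------------------------------
def traces_to_frame(traces: list[FluorescenceTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "neuron_id": tr.neuron_id,
                    "fish_id": tr.fish_id,
                    "genotype": tr.genotype,
                    "repeat": tr.repeat_index,
                    "roi_size": tr.roi_size,
                    "frame_index": np.arange(len(tr.frames)),
                    "F": tr.frames,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_traces(traces: list[FluorescenceTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def frame_to_traces(df: pd.DataFrame) -> list[FluorescenceTrace]:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trace table is missing columns: {missing}")
    out = []
    for (nid, rep), sub in df.groupby(["neuron_id", "repeat"], sort=False):
        sub = sub.sort_values("frame_index")
        idx = sub["frame_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise FormatError(f"neuron {nid!r} repeat {rep}: frame_index is not 0..n-1")
        out.append(
            FluorescenceTrace(
                neuron_id=str(nid),
                fish_id=str(sub["fish_id"].iloc[0]),
                genotype=str(sub["genotype"].iloc[0]),
                repeat_index=int(rep),
                roi_size=float(sub["roi_size"].iloc[0]),
                frames=sub["F"].to_numpy(dtype=float),
            )
        )
    return out


def read_traces(path: str | Path) -> list[FluorescenceTrace]:
    # keep_default_na: the genotype label "null" is data, not a missing value
    return frame_to_traces(pd.read_csv(path, keep_default_na=False))


# --- coordinates -----------------------------------------------------------
def write_coordinates(df: pd.DataFrame, path: str | Path) -> None:
    df[COORD_COLUMNS].to_csv(path, index=False)


def read_coordinates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in COORD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"coordinate table is missing columns: {missing}")
    coords = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        bad = df.index[~np.isfinite(coords).all(axis=1)][0]
        raise FormatError(f"non-finite coordinate at row {bad}")
    return df


# --- count matrices --------------------------------------------------------
def write_counts_mtx(counts: CountMatrix, out_dir: str | Path, prefix: str = "counts") -> None:
    """Write MatrixMarket MTX with genes.tsv / samples.tsv sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / f"{prefix}.mtx", sparse.csr_matrix(counts.counts.to_numpy()))
    pd.Series(counts.counts.index, name="gene_id").to_csv(
        out / f"{prefix}_genes.tsv", sep="\t", index=False
    )
    counts.condition.rename_axis("sample_id").reset_index().to_csv(
        out / f"{prefix}_samples.tsv", sep="\t", index=False
    )


def read_counts_mtx(out_dir: str | Path, prefix: str = "counts") -> CountMatrix:
    out = Path(out_dir)
    mat = spio.mmread(out / f"{prefix}.mtx")
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    neg = np.argwhere(dense < 0)
    if neg.size:
        i, j = neg[0]
        raise FormatError(f"negative count at gene row {i}, sample column {j}")
    genes = pd.read_csv(out / f"{prefix}_genes.tsv", sep="\t", keep_default_na=False)["gene_id"]
    samp = pd.read_csv(out / f"{prefix}_samples.tsv", sep="\t", keep_default_na=False)
    if dense.shape != (len(genes), len(samp)):
        raise FormatError(
            f"matrix is {dense.shape} but sidecars describe {(len(genes), len(samp))}"
        )
    counts = pd.DataFrame(dense.astype(np.int64), index=genes.tolist(), columns=samp["sample_id"].tolist())
    condition = pd.Series(samp["condition"].tolist(), index=samp["sample_id"].tolist(), name="condition")
    return CountMatrix(counts, condition)


def write_counts_tsv(counts: CountMatrix, path: str | Path) -> None:
    """Wide TSV: first column gene_id, one column per sample; condition row
    is carried in a '#condition:' header comment."""
    with open(path, "w") as fh:
        cond = "\t".join(counts.condition.loc[counts.counts.columns])
        fh.write(f"#condition:\t{cond}\n")
        counts.counts.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#condition:":
            raise FormatError("wide TSV must start with a '#condition:' line")
        cond = header[1:]
        df = pd.read_csv(fh, sep="\t", index_col="gene_id", keep_default_na=False)
        df.index.name = None
    if len(cond) != df.shape[1]:
        raise FormatError(
            f"condition line lists {len(cond)} labels for {df.shape[1]} sample columns"
        )
    if (df.to_numpy() < 0).any():
        gene = df.index[(df < 0).any(axis=1)][0]
        raise FormatError(f"negative count for gene {gene!r}")
    condition = pd.Series(cond, index=df.columns, name="condition")
    return CountMatrix(df.astype(np.int64), condition)


# --- atlas -----------------------------------------------------------------
def write_atlas_mtx(atlas: AtlasDetection, out_dir: str | Path, prefix: str = "atlas") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / f"{prefix}.mtx", sparse.csr_matrix(atlas.detection.to_numpy()))
    pd.Series(atlas.detection.index, name="gene_id").to_csv(
        out / f"{prefix}_genes.tsv", sep="\t", index=False
    )
    atlas.cluster.rename_axis("cell_id").reset_index().to_csv(
        out / f"{prefix}_cells.tsv", sep="\t", index=False
    )


def read_atlas_mtx(out_dir: str | Path, prefix: str = "atlas") -> AtlasDetection:
    out = Path(out_dir)
    mat = spio.mmread(out / f"{prefix}.mtx")
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    genes = pd.read_csv(out / f"{prefix}_genes.tsv", sep="\t", keep_default_na=False)["gene_id"]
    cells = pd.read_csv(out / f"{prefix}_cells.tsv", sep="\t", keep_default_na=False)
    if dense.shape != (len(genes), len(cells)):
        raise FormatError(
            f"atlas matrix is {dense.shape} but sidecars describe {(len(genes), len(cells))}"
        )
    det = pd.DataFrame(dense.astype(np.int8), index=genes.tolist(), columns=cells["cell_id"].tolist())
    cluster = pd.Series(cells["cluster"].tolist(), index=cells["cell_id"].tolist(), name="cluster")
    return AtlasDetection(det, cluster)


# --- bundled worked-example tables -----------------------------------------
def load_example_candidates() -> pd.DataFrame:
    """Candidate DE genes for projection neurons after motor-neuron loss,
    as reported at the 1%-detection filter: log2 fold change, adjusted p,
    and reference-atlas detection percentage per gene."""
    with resources.files("tiltpipe.data").joinpath("de_candidates_example.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="gene")


def load_example_insitu_panel() -> pd.DataFrame:
    """The eight-gene in-situ validation panel with its reported log2 fold
    changes and adjusted p-values (detection percentage where reported)."""
    with resources.files("tiltpipe.data").joinpath("insitu_panel_example.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="gene")
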