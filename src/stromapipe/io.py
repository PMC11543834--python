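"""Readers and writers for every external format the pipeline touches.

Count matrices use the 10x-style MatrixMarket triplet layout (matrix.mtx +
genes.tsv + barcodes.tsv); spot geometry uses the tissue-positions CSV
dialect (barcode, in_tissue, array_row, array_col, pxl_row, pxl_col) with a
pixel->micrometre scale supplied by the caller; annotation masks and
trichrome images are plain PNG/TIFF.  All geometry is converted to
micrometres at read time, in a single frame: 0-based pixel indices, y down,
pixel centers at (i + 0.5) * pixel_size.

Result tables are written as TSV with a leading ``#`` comment carrying the
configuration hash, for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .config import PipelineConfig


class FormatError(ValueError):
    """Input file violates the expected dialect."""


@dataclass(frozen=True)
class SpotGeometry:
    """One circular capture spot: center in um, lattice indices 0-based."""

    spot_id: str
    center_x: float
    center_y: float
    diameter: float = 55.0
    row: int = 0
    col: int = 0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("spot diameter must be positive")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> pd.DataFrame:
    """Read a gene-by-spot integer count matrix in MatrixMarket layout.

    Returns a dense DataFrame indexed by gene, columned by spot barcode.
    """
    mat = scipy.io.mmread(str(matrix_path))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes x "
            f"{len(barcodes)} barcodes"
        )
    dense = np.asarray(sp.coo_matrix(mat).todense())
    if np.any(dense < 0):
        raise FormatError("count matrix contains negative entries")
    return pd.DataFrame(dense.astype(np.int64), index=genes, columns=barcodes)


def write_count_matrix(
    counts: pd.DataFrame,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(counts.columns).to_csv(barcodes_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# spot positions
# ---------------------------------------------------------------------------

_POS_COLS = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]


def read_positions(
    csv_path: str | Path,
    pixel_size: float = 1.0,
    diameter: float = 55.0,
) -> list[SpotGeometry]:
    """Read a tissue-positions CSV; pixel coordinates are scaled to um."""
    df = pd.read_csv(csv_path, header=None, names=_POS_COLS)
    if df["barcode"].duplicated().any():
        dup = df["barcode"][df["barcode"].duplicated()].iloc[0]
        raise FormatError(f"duplicate barcode in positions table: {dup!r}")
    return [
        SpotGeometry(
            spot_id=str(r.barcode),
            center_x=float(r.pxl_col) * pixel_size,
            center_y=float(r.pxl_row) * pixel_size,
            diameter=diameter,
            row=int(r.array_row),
            col=int(r.array_col),
        )
        for r in df.itertuples()
    ]


def write_positions(
    spots: Sequence[SpotGeometry], csv_path: str | Path, pixel_size: float = 1.0
) -> None:
    rows = [
        (s.spot_id, 1, s.row, s.col, s.center_y / pixel_size, s.center_x / pixel_size)
        for s in spots
    ]
    pd.DataFrame(rows, columns=_POS_COLS).to_csv(csv_path, header=False, index=False)


# ---------------------------------------------------------------------------
# rasters and images
# ---------------------------------------------------------------------------

@dataclass
class MaskRaster:
    """Binary annotation raster with physical pixel size (um)."""

    mask: np.ndarray  # bool, (H, W)
    pixel_size: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def read_mask(image_path: str | Path, pixel_size: float) -> MaskRaster:
    """Read a PNG/TIFF annotation raster; any nonzero pixel is inside the class."""
    try:
        img = iio.imread(image_path)
    except (OSError, ValueError, RuntimeError) as exc:
        raise IOError(f"cannot read mask image {image_path}: {exc}") from exc
    if img.ndim == 3:
        img = img.max(axis=-1)
    return MaskRaster(mask=np.asarray(img) != 0, pixel_size=float(pixel_size))


def write_mask(mask: np.ndarray, image_path: str | Path) -> None:
    iio.imwrite(image_path, (np.asarray(mask, bool) * np.uint8(255)))


def read_rgb_image(image_path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image as (H, W, 3) uint8."""
    try:
        img = iio.imread(image_path)
    except (OSError, ValueError, RuntimeError) as exc:
        raise IOError(f"cannot read image {image_path}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] < 3:
        raise FormatError(f"{image_path} is not an RGB image (shape {img.shape})")
    return img[..., :3].astype(np.uint8)


def write_rgb_image(image: np.ndarray, image_path: str | Path) -> None:
    iio.imwrite(image_path, np.asarray(image, np.uint8))


# ---------------------------------------------------------------------------
# plain tables
# ---------------------------------------------------------------------------

def read_cell_counts(csv_path: str | Path) -> pd.Series:
    """Per-spot nuclei counts: CSV with columns spot_id, cell_count."""
    df = pd.read_csv(csv_path)
    if not {"spot_id", "cell_count"} <= set(df.columns):
        raise FormatError("cell count table needs columns spot_id, cell_count")
    return df.set_index("spot_id")["cell_count"].astype(int)


def write_cell_counts(cell_counts: pd.Series, csv_path: str | Path) -> None:
    cell_counts.rename("cell_count").rename_axis("spot_id").reset_index().to_csv(
        csv_path, index=False
    )


def read_table(csv_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(csv_path)


def write_table(df: pd.DataFrame, csv_path: str | Path) -> None:
    df.to_csv(csv_path, index=False)


def read_methylation(
    betas_path: str | Path, regions_path: str | Path
) -> tuple[pd.DataFrame, pd.Series]:
    """Read site-by-sample beta values plus per-site region annotation.

    Region labels follow the array convention: TSS1500, TSS200, 5'UTR and
    1stExon form the promoter; 3'UTR and Body form the gene body.
    """
    betas = pd.read_csv(betas_path, index_col=0)
    regions = pd.read_csv(regions_path, index_col=0).iloc[:, 0]
    missing = betas.index.difference(regions.index)
    if len(missing):
        raise FormatError(f"sites without region annotation: {list(missing)[:5]}")
    vals = betas.to_numpy(float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise FormatError("beta values must lie in [0, 1]")
    return betas, regions.loc[betas.index]


def write_methylation(
    betas: pd.DataFrame, regions: pd.Series, betas_path: str | Path, regions_path: str | Path
) -> None:
    betas.rename_axis("site").to_csv(betas_path)
    regions.rename("region").rename_axis("site").to_csv(regions_path)


# ---------------------------------------------------------------------------
# result output
# ---------------------------------------------------------------------------

def write_result_tsv(
    df: pd.DataFrame, path: str | Path, config: PipelineConfig | None = None
) -> None:
    """Write a result table as TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# stromapipe config_hash={config.hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_result_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
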