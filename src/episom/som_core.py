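"""Batch self-organizing map on gene-centric matrices.

Genes are the observations, samples the feature dimensions, so each grid
unit's prototype vector is a "metagene" profile over samples. Training is
the deterministic batch algorithm: principal-axis initialization, Gaussian
grid neighborhood with a linearly shrinking radius, and whole-data
prototype updates each epoch. Three variants differ only in their input
(raw beta values, centralized beta values, centralized log-expression)
and are tagged MetSOM / DmetSOM / DexSOM.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .datamodel_io import GeneSampleMatrix

__all__ = [
    "SOMModel",
    "train_som",
    "assign_bmu",
    "sample_portrait",
    "map_gene_group",
    "quantization_error",
    "save_model",
    "load_model",
]

VARIANTS = ("MetSOM", "DmetSOM", "DexSOM")

DEFAULT_GRID = 50
DEFAULT_EPOCHS = 30


@dataclass
class SOMModel:
    """Trained map: grid geometry, codebook and gene assignments.

    ``codebook`` has shape ``(grid_rows * grid_cols, n_samples)`` with
    units in row-major order; ``bmu[i]`` is the unit index of gene i.
    The training matrix is retained so spot modules can report gene-level
    profiles without re-reading the input.
    """

    grid_rows: int
    grid_cols: int
    codebook: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    bmu: np.ndarray
    data: np.ndarray
    variant: str
    seed: int
    epochs: int
    radius_initial: float
    radius_final: float
    qe_first: float = float("nan")
    qe_final: float = float("nan")

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def unit_coord(self, unit: int) -> tuple[int, int]:
        """0-based (row, col) of a row-major unit index."""
        return divmod(int(unit), self.grid_cols)

    def unit_index(self, row: int, col: int) -> int:
        return int(row) * self.grid_cols + int(col)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def gene_bmu(self, gene_id: str) -> int:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene {gene_id!r}") from None
        return int(self.bmu[i])


def _grid_coordinates(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _principal_axis_init(
    X: np.ndarray, rows: int, cols: int, rng: np.random.Generator
) -> np.ndarray:
    """Linear initialization along the first two principal axes.

    Falls back to seeded random initialization around the mean when the
    gene cloud has rank < 2. Principal-axis signs are fixed by making
    the largest-magnitude component positive, which keeps the codebook
    equivariant under permutations of the sample dimensions.
    """
    n_genes, n_samples = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    # economical SVD; rows of Vt are principal axes in sample-space
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    if rank < 2:
        span = X.std() if X.std() > 0 else 1.0
        return mean[None, :] + 0.01 * span * rng.standard_normal(
            (rows * cols, n_samples)
        )
    axes = []
    for k in range(2):
        v = Vt[k]
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v = -v
        # scale by the data's standard deviation along the axis
        axes.append(v * (s[k] / np.sqrt(max(n_genes - 1, 1))))
    coords = _grid_coordinates(rows, cols)
    a = 2.0 * coords[:, 0] / max(rows - 1, 1) - 1.0
    b = 2.0 * coords[:, 1] / max(cols - 1, 1) - 1.0
    return mean[None, :] + np.outer(a, axes[0]) + np.outer(b, axes[1])


def _bmus(X: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Best-matching units; argmin breaks ties at the lowest index."""
    d2 = cdist(X, codebook, metric="sqeuclidean")
    return np.argmin(d2, axis=1)


def quantization_error(X: np.ndarray, codebook: np.ndarray,
                       bmu: np.ndarray | None = None) -> float:
    """Mean Euclidean distance of each gene to its prototype."""
    if bmu is None:
        bmu = _bmus(X, codebook)
    diff = X - codebook[bmu]
    return float(np.mean(np.sqrt(np.sum(diff * diff, axis=1))))


def train_som(
    m: GeneSampleMatrix,
    grid_rows: int = DEFAULT_GRID,
    grid_cols: int = DEFAULT_GRID,
    epochs: int = DEFAULT_EPOCHS,
    seed: int = 0,
    variant: str = "MetSOM",
    radius_final: float = 1.0,
) -> SOMModel:
    """Train a batch SOM on a gene x sample matrix.

    The caller supplies already-centralized data for the DmetSOM /
    DexSOM variants. Deterministic for fixed seed and inputs; the mean
    quantization error at the final epoch never exceeds the one after
    the first epoch (the neighborhood radius shrinks monotonically).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if m.n_genes < 2 or m.n_samples < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    if grid_rows < 2 or grid_cols < 2:
        raise ValueError("grid dimensions must be >= 2")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    X = np.asarray(m.values, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix contains missing or non-finite values; "
                         "impute or drop incomplete genes before training")

    rng = np.random.default_rng(seed)
    codebook = _principal_axis_init(X, grid_rows, grid_cols, rng)
    coords = _grid_coordinates(grid_rows, grid_cols)
    grid_d2 = cdist(coords, coords, metric="sqeuclidean")
    radius_initial = max(grid_rows, grid_cols) / 2.0
    qe_first = float("nan")
    for epoch in range(epochs):
        if epochs > 1:
            frac = epoch / (epochs - 1)
        else:
            frac = 1.0
        sigma = radius_initial + frac * (radius_final - radius_initial)
        bmu = _bmus(X, codebook)
        if epoch == 0:
            qe_first = quantization_error(X, codebook, bmu)
        H = np.exp(-grid_d2 / (2.0 * sigma * sigma))
        W = H[:, bmu]  # (n_units, n_genes)
        denom = W.sum(axis=1)
        numer = W @ X
        nonzero = denom > 0
        codebook[nonzero] = numer[nonzero] / denom[nonzero, None]
    bmu = _bmus(X, codebook)
    qe_final = quantization_error(X, codebook, bmu)
    return SOMModel(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        codebook=codebook,
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        bmu=bmu.astype(int),
        data=X,
        variant=variant,
        seed=int(seed),
        epochs=int(epochs),
        radius_initial=float(radius_initial),
        radius_final=float(radius_final),
        qe_first=qe_first,
        qe_final=qe_final,
    )


def assign_bmu(model: SOMModel, gene_vector: np.ndarray) -> int:
    """Unit index minimizing Euclidean distance to the vector
    (lowest index on ties)."""
    v = np.asarray(gene_vector, dtype=float).ravel()
    if v.size != model.n_samples:
        raise ValueError(
            f"vector length {v.size} != n_samples {model.n_samples}"
        )
    d2 = np.sum((model.codebook - v[None, :]) ** 2, axis=1)
    return int(np.argmin(d2))


def sample_portrait(model: SOMModel, sample_id: str) -> np.ndarray:
    """The (grid_rows x grid_cols) metagene landscape of one sample."""
    j = model.sample_index(sample_id)
    return model.codebook[:, j].reshape(model.grid_rows, model.grid_cols)


def map_gene_group(
    model: SOMModel, genes: Iterable[str]
) -> dict[tuple[int, int], int]:
    """Occupied unit coordinates with per-unit gene counts.

    Genes unknown to the model are skipped with a warning; counts sum to
    the number of genes actually mapped.
    """
    lookup = {g: int(u) for g, u in zip(model.gene_ids, model.bmu)}
    counts: dict[tuple[int, int], int] = {}
    n_unknown = 0
    n_mapped = 0
    for g in genes:
        if g not in lookup:
            n_unknown += 1
            continue
        coord = model.unit_coord(lookup[g])
        counts[coord] = counts.get(coord, 0) + 1
        n_mapped += 1
    if n_unknown:
        warnings.warn(f"{n_unknown} gene(s) unknown to the model; skipped")
    if n_mapped == 0:
        warnings.warn("no genes could be mapped")
    return counts


# ---------------------------------------------------------------------------
# serialization (directory of text files: TSVs + JSON metadata)
# ---------------------------------------------------------------------------


def save_model(model: SOMModel, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "codebook.tsv", "w") as fh:
        fh.write("unit\t" + "\t".join(model.sample_ids) + "\n")
        for u in range(model.n_units):
            fh.write(
                str(u)
                + "\t"
                + "\t".join(repr(float(v)) for v in model.codebook[u])
                + "\n"
            )
    with open(out / "bmu.tsv", "w") as fh:
        fh.write("gene_id\tunit\trow\tcol\n")
        for g, u in zip(model.gene_ids, model.bmu):
            r, c = model.unit_coord(u)
            fh.write(f"{g}\t{int(u)}\t{r}\t{c}\n")
    with open(out / "data.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(model.sample_ids) + "\n")
        for i, g in enumerate(model.gene_ids):
            fh.write(
                g
                + "\t"
                + "\t".join(repr(float(v)) for v in model.data[i])
                + "\n"
            )
    meta = {
        "grid_rows": model.grid_rows,
        "grid_cols": model.grid_cols,
        "variant": model.variant,
        "seed": model.seed,
        "epochs": model.epochs,
        "radius_initial": model.radius_initial,
        "radius_final": model.radius_final,
        "qe_first": model.qe_first,
        "qe_final": model.qe_final,
        "n_genes": len(model.gene_ids),
        "n_samples": model.n_samples,
    }
    with open(out / "model.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def load_model(model_dir: str | Path) -> SOMModel:
    d = Path(model_dir)
    with open(d / "model.json") as fh:
        meta = json.load(fh)
    import pandas as pd

    cb = pd.read_csv(d / "codebook.tsv", sep="\t", index_col=0)
    bmu_df = pd.read_csv(d / "bmu.tsv", sep="\t", dtype={"gene_id": str})
    data = pd.read_csv(d / "data.tsv", sep="\t", index_col=0)
    return SOMModel(
        grid_rows=int(meta["grid_rows"]),
        grid_cols=int(meta["grid_cols"]),
        codebook=cb.to_numpy(dtype=float),
        gene_ids=[str(g) for g in data.index],
        sample_ids=[str(s) for s in cb.columns],
        bmu=bmu_df["unit"].to_numpy(dtype=int),
        data=data.to_numpy(dtype=float),
        variant=str(meta["variant"]),
        seed=int(meta["seed"]),
        epochs=int(meta["epochs"]),
        radius_initial=float(meta["radius_initial"]),
        radius_final=float(meta["radius_final"]),
        qe_first=float(meta["qe_first"]),
        qe_final=float(meta["qe_final"]),
    )
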