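"""Core data types and file I/O.

Gene x sample matrices travel as :class:`GeneSampleMatrix` (values as a
float array with NaN marking missing entries), sample class labels as
:class:`SampleAnnotation` and gene sets as :class:`GeneSetCollection`.
On disk everything is plain text: TSV matrices (first column = gene
symbol, header = sample ids), two-column annotation TSVs and standard
GMT gene-set files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MODALITY_METHYLATION",
    "MODALITY_EXPRESSION",
    "GeneSampleMatrix",
    "SampleAnnotation",
    "GeneSetCollection",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
    "centralize",
    "match_genes",
]

MODALITY_METHYLATION = "methylation_beta"
MODALITY_EXPRESSION = "log_expression"
_MODALITIES = (MODALITY_METHYLATION, MODALITY_EXPRESSION)

#: tolerance for beta values marginally outside [0, 1] (rounding in files)
BETA_TOL = 1e-9

_MISSING_TOKENS = {"", "na", "nan", "n/a", "null"}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class GeneSampleMatrix:
    """Gene x sample value matrix with a modality flag.

    Parameters
    ----------
    values
        Float array of shape ``(n_genes, n_samples)``; NaN marks missing.
    gene_ids, sample_ids
        Unique row / column identifiers.
    modality
        ``"methylation_beta"`` or ``"log_expression"``.
    centralized
        True once per-gene means have been subtracted; beta-range
        validation is suspended for centralized methylation data.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    modality: str
    centralized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.modality == MODALITY_METHYLATION and not self.centralized:
            self._check_beta_range()

    def _check_beta_range(self) -> None:
        bad = np.where(
            (self.values < -BETA_TOL) | (self.values > 1.0 + BETA_TOL)
        )
        if bad[0].size:
            g, s = bad[0][0], bad[1][0]
            raise ValueError(
                "beta value outside [0, 1]: "
                f"{self.values[g, s]!r} at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    # -- convenience -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean array, True where a value is missing."""
        return np.isnan(self.values)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_lookup[gene_id]
        except AttributeError:
            self._gene_lookup = {g: i for i, g in enumerate(self.gene_ids)}
            return self._gene_lookup[gene_id]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_lookup[sample_id]
        except AttributeError:
            self._sample_lookup = {s: i for i, s in enumerate(self.sample_ids)}
            return self._sample_lookup[sample_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    def subset_genes(self, genes: Sequence[str]) -> "GeneSampleMatrix":
        idx = [self.gene_index(g) for g in genes]
        return GeneSampleMatrix(
            self.values[idx, :],
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.modality,
            centralized=self.centralized,
        )


@dataclass
class SampleAnnotation:
    """Mapping sample id -> class label."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}
        if not self.labels:
            raise ValueError("annotation is empty")

    def classes(self) -> list[str]:
        """Class labels in first-seen order."""
        out: list[str] = []
        for lab in self.labels.values():
            if lab not in out:
                out.append(lab)
        return out

    def samples_of(self, label: str) -> list[str]:
        return [s for s, lab in self.labels.items() if lab == label]

    def label_of(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def validate_against(self, m: GeneSampleMatrix) -> None:
        missing = [s for s in m.sample_ids if s not in self.labels]
        if missing:
            raise ValueError(
                f"{len(missing)} matrix samples lack a class label, "
                f"first: {missing[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class GeneSetCollection:
    """Named gene sets with symbols stored upper-cased and de-duplicated."""

    sets: dict[str, list[str]]
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            seen: list[str] = []
            have = set()
            for g in genes:
                gu = str(g).upper()
                if gu and gu not in have:
                    seen.append(gu)
                    have.add(gu)
            if not seen:
                raise ValueError(f"gene set {name!r} is empty")
            clean[str(name)] = seen
        self.sets = clean

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, modality: str) -> GeneSampleMatrix:
    """Read a TSV gene x sample matrix.

    First column holds gene symbols, the header row sample ids. Missing
    values may be encoded as empty cells, ``NA``, ``NaN`` or ``null``.
    Any other non-numeric cell raises a :class:`ValueError` naming the
    offending gene and sample, as does a duplicated identifier or (for
    methylation) a beta value outside [0, 1].
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    gene_ids = [str(g) for g in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    values = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy()
    for j in range(arr.shape[1]):
        col = arr[:, j]
        for i, cell in enumerate(col):
            text = cell.strip()
            if text.lower() in _MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(text)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at gene {gene_ids[i]!r}, "
                    f"sample {sample_ids[j]!r} in {path}"
                ) from None
    return GeneSampleMatrix(values, gene_ids, sample_ids, modality)


def write_matrix(m: GeneSampleMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; values round-trip bit-exactly (shortest repr)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for i, gene in enumerate(m.gene_ids):
            cells = [
                "NA" if np.isnan(v) else repr(float(v))
                for v in m.values[i, :]
            ]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a two-column TSV (``sample_id<TAB>class``, header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"annotation file {path} needs two columns")
    labels: dict[str, str] = {}
    for sample, label in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if sample in labels:
            raise ValueError(f"duplicate sample id in annotation: {sample!r}")
        labels[str(sample)] = str(label)
    return SampleAnnotation(labels)


def write_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\n")
        for sample, label in ann.labels.items():
            fh.write(f"{sample}\t{label}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated symbols)."""
    sets: dict[str, list[str]] = {}
    sources: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"GMT line {lineno} has fewer than 3 fields in {path}"
                )
            name, desc = parts[0], parts[1]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} in {path}")
            genes = [g for g in parts[2:] if g.strip()]
            sets[name] = genes
            sources[name] = desc
    return GeneSetCollection(sets, sources)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in coll.names():
            desc = coll.sources.get(name, "na")
            fh.write(name + "\t" + desc + "\t" + "\t".join(coll[name]) + "\n")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def centralize(m: GeneSampleMatrix) -> GeneSampleMatrix:
    """Subtract each gene's mean over its non-missing samples.

    Genes with no observed value at all are left all-missing (with a
    warning). The result carries ``centralized=True``; applying
    :func:`centralize` twice is a no-op.
    """
    if m.n_samples < 1:
        raise ValueError("need at least one sample")
    values = m.values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(values, axis=1)
    all_missing = np.isnan(means)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} gene(s) have no observed values; "
            "rows left missing"
        )
        means = np.where(all_missing, 0.0, means)
    values -= means[:, None]
    return GeneSampleMatrix(
        values,
        list(m.gene_ids),
        list(m.sample_ids),
        m.modality,
        centralized=True,
    )


def match_genes(
    a: GeneSampleMatrix | Sequence[str],
    b: GeneSampleMatrix | Sequence[str],
) -> list[tuple[str, str]]:
    """Case-insensitive symbol matching between two gene lists.

    Each upper-cased symbol participates in at most one pair per side
    (first occurrence wins). An empty intersection is legal and only
    warns. Returns pairs ``(gene_in_a, gene_in_b)`` in a's order.
    """
    genes_a = a.gene_ids if isinstance(a, GeneSampleMatrix) else list(a)
    genes_b = b.gene_ids if isinstance(b, GeneSampleMatrix) else list(b)
    lookup_b: dict[str, str] = {}
    for g in genes_b:
        key = str(g).upper()
        if key not in lookup_b:
            lookup_b[key] = g
    pairs: list[tuple[str, str]] = []
    used_a: set[str] = set()
    for g in genes_a:
        key = str(g).upper()
        if key in used_a:
            continue
        used_a.add(key)
        if key in lookup_b:
            pairs.append((g, lookup_b[key]))
    if not pairs:
        warnings.warn("gene lists share no symbols")
    return pairs
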