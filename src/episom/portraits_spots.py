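"""Class-mean portraits, variance maps, overview spot masks and
spot-module segmentation.

A spot module is an 8-connected region of grid units whose metagene
values are extreme (high or low tail) in at least one sample, together
with the genes whose best-matching unit falls inside the region and
their per-sample / per-class summary profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .datamodel_io import SampleAnnotation
from .som_core import SOMModel, map_gene_group

__all__ = [
    "SpotModule",
    "CrossMapResult",
    "class_mean_portrait",
    "variance_map",
    "overview_spot_map",
    "detect_spots",
    "spot_profile",
    "cross_map",
]

DEFAULT_SPOT_QUANTILE = 0.98
DEFAULT_MIN_UNITS = 4

#: 8-connectivity structuring element for component labeling
_STRUCTURE_8 = np.ones((3, 3), dtype=int)


@dataclass
class SpotModule:
    """Connected grid region with its member genes and profiles."""

    label: str
    polarity: str  # "high" | "low"
    units: set[tuple[int, int]]
    gene_ids: list[str]
    sample_ids: list[str]
    per_sample_profile: np.ndarray  # mean over member genes, per sample
    variant: str = ""

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def bounding_box(self) -> tuple[int, int, int, int]:
        rows = [r for r, _ in self.units]
        cols = [c for _, c in self.units]
        return min(rows), min(cols), max(rows), max(cols)


@dataclass
class CrossMapResult:
    """Occupancy of a spot's genes in another SOM."""

    occupancy: dict[tuple[int, int], int]
    n_spot_genes: int
    n_mapped: int
    concentration: float  # units covering 50% of genes / mapped genes
    spot_overlap: dict[str, int] = field(default_factory=dict)

    @property
    def fraction_mapped(self) -> float:
        if self.n_spot_genes == 0:
            return 0.0
        return self.n_mapped / self.n_spot_genes


def class_mean_portrait(
    model: SOMModel, ann: SampleAnnotation, class_label: str
) -> np.ndarray:
    """Per-unit arithmetic mean of the portraits of a class's samples."""
    members = [s for s in ann.samples_of(class_label) if s in model.sample_ids]
    if not members:
        raise ValueError(f"class {class_label!r} has no samples in the model")
    cols = [model.sample_index(s) for s in members]
    return model.codebook[:, cols].mean(axis=1).reshape(
        model.grid_rows, model.grid_cols
    )


def variance_map(model: SOMModel) -> np.ndarray:
    """Population variance of each prototype vector across samples."""
    if model.n_samples < 2:
        raise ValueError("variance map needs >= 2 samples")
    return model.codebook.var(axis=1, ddof=0).reshape(
        model.grid_rows, model.grid_cols
    )


def overview_spot_map(
    model: SOMModel, tail: str = "high", q: float = DEFAULT_SPOT_QUANTILE
) -> np.ndarray:
    """Union over samples of each sample's extreme-tail units.

    For ``tail="high"`` a unit enters the mask when its portrait value
    strictly exceeds that sample's q-quantile; for ``tail="low"`` when
    it falls strictly below the (1-q)-quantile.
    """
    if not 0.5 < q < 1.0:
        raise ValueError("q must lie in (0.5, 1)")
    if tail not in ("high", "low"):
        raise ValueError("tail must be 'high' or 'low'")
    mask = np.zeros(model.n_units, dtype=bool)
    for j in range(model.n_samples):
        landscape = model.codebook[:, j]
        if tail == "high":
            thr = np.quantile(landscape, q)
            mask |= landscape > thr
        else:
            thr = np.quantile(landscape, 1.0 - q)
            mask |= landscape < thr
    return mask.reshape(model.grid_rows, model.grid_cols)


def detect_spots(
    mask: np.ndarray,
    model: SOMModel,
    min_units: int = DEFAULT_MIN_UNITS,
    polarity: str = "high",
) -> list[SpotModule]:
    """8-connected components of the mask, materialized as spot modules.

    Components smaller than ``min_units`` are dropped; the survivors are
    labeled "1", "2", ... in decreasing unit-count order (ties broken by
    top-left bounding-box corner for determinism).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (model.grid_rows, model.grid_cols):
        raise ValueError("mask shape does not match the model grid")
    labeled, n_comp = ndimage.label(mask, structure=_STRUCTURE_8)
    comps = []
    for k in range(1, n_comp + 1):
        rows, cols = np.where(labeled == k)
        if rows.size < min_units:
            continue
        units = set(zip(rows.tolist(), cols.tolist()))
        comps.append(units)
    comps.sort(key=lambda u: (-len(u), min(u)))
    spots = []
    for rank, units in enumerate(comps, start=1):
        unit_idx = {model.unit_index(r, c) for r, c in units}
        member_idx = [
            i for i, u in enumerate(model.bmu) if int(u) in unit_idx
        ]
        genes = [model.gene_ids[i] for i in member_idx]
        if member_idx:
            profile = model.data[member_idx, :].mean(axis=0)
        else:
            profile = np.full(model.n_samples, np.nan)
        spots.append(
            SpotModule(
                label=str(rank),
                polarity=polarity,
                units=units,
                gene_ids=genes,
                sample_ids=list(model.sample_ids),
                per_sample_profile=profile,
                variant=model.variant,
            )
        )
    return spots


def spot_profile(spot: SpotModule, ann: SampleAnnotation) -> pd.DataFrame:
    """Per-class mean and standard deviation of the spot's per-sample
    profile. Classes without samples in the spot's cohort are omitted
    with a warning."""
    if spot.n_genes < 1:
        raise ValueError("spot has no member genes")
    idx = {s: j for j, s in enumerate(spot.sample_ids)}
    rows = []
    for label in ann.classes():
        members = [s for s in ann.samples_of(label) if s in idx]
        if not members:
            warnings.warn(f"class {label!r} absent from the spot's cohort")
            continue
        vals = spot.per_sample_profile[[idx[s] for s in members]]
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        rows.append(
            {
                "class": label,
                "mean": float(np.mean(vals)),
                "sd": sd,
                "n": len(members),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def _concentration(occupancy: dict[tuple[int, int], int], n_mapped: int) -> float:
    """Minimum number of units whose occupancy covers >= 50% of the
    mapped genes, divided by the number of mapped genes. Small values
    mean the genes pile into few units (spatial concentration)."""
    if n_mapped == 0:
        return float("nan")
    counts = sorted(occupancy.values(), reverse=True)
    need = 0.5 * n_mapped
    covered = 0
    for k, c in enumerate(counts, start=1):
        covered += c
        if covered >= need:
            return k / n_mapped
    return len(counts) / n_mapped


def cross_map(
    spot: SpotModule,
    other: SOMModel,
    pairs: list[tuple[str, str]],
    other_spots: list[SpotModule] | None = None,
) -> CrossMapResult:
    """Map a spot's genes into another SOM via matched gene pairs.

    Returns the occupied coordinates with counts, the fraction of spot
    genes that could be mapped, a spatial concentration score and
    (optionally) per-spot overlap counts with the other SOM's spots.
    """
    if not pairs:
        raise ValueError("empty gene pairing")
    translate = {a.upper(): b for a, b in pairs}
    targets = [
        translate[g.upper()] for g in spot.gene_ids if g.upper() in translate
    ]
    if not targets:
        warnings.warn("no spot gene present in the other SOM")
        return CrossMapResult({}, spot.n_genes, 0, float("nan"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        occupancy = map_gene_group(other, targets)
    n_mapped = sum(occupancy.values())
    overlap: dict[str, int] = {}
    if other_spots:
        target_set = {g.upper() for g in targets}
        for osp in other_spots:
            overlap[osp.label] = len(
                target_set & {g.upper() for g in osp.gene_ids}
            )
    return CrossMapResult(
        occupancy=occupancy,
        n_spot_genes=spot.n_genes,
        n_mapped=n_mapped,
        concentration=_concentration(occupancy, n_mapped),
        spot_overlap=overlap,
    )
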