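"""Methylation-expression coupling of gene groups across classes.

The two cohorts may be unmatched (different patients per modality); class
labels are the join key. For a gene group, each class is summarized by
the class-averaged mean centralized methylation (x) and expression (y)
of the group, with standard deviations over the class's samples of the
gene-averaged value. The across-class correlation of (x, y) plus the
ranges of x and y classify the group into one of the coupling patterns:
positive, negative, methylation-only, expression-only or silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel_io import GeneSampleMatrix, SampleAnnotation, match_genes

__all__ = [
    "CouplingSummary",
    "coupling_summary",
    "classify_coupling",
    "slope_indicator",
    "read_class_map",
    "DEFAULT_DX_MIN",
    "DEFAULT_DY_MIN",
    "DEFAULT_RHO_MIN",
]

DEFAULT_DX_MIN = 0.05  # beta units
DEFAULT_DY_MIN = 0.3  # log2 units
DEFAULT_RHO_MIN = 0.6

PATTERNS = ("positive", "negative", "methylation-only", "expression-only",
            "silent")


@dataclass
class CouplingSummary:
    group_name: str
    classes: list[str]
    x: dict[str, float]  # class -> mean centralized methylation
    y: dict[str, float]  # class -> mean centralized expression
    sd_x: dict[str, float]
    sd_y: dict[str, float]
    n_x: dict[str, int]
    n_y: dict[str, int]
    correlation: float
    ref_class: str
    target_class: str
    n_genes_met: int
    n_genes_exp: int
    pattern: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.classes:
            rows.append(
                {
                    "class": c,
                    "mean_met": self.x[c],
                    "mean_exp": self.y[c],
                    "sd_met": self.sd_x[c],
                    "sd_exp": self.sd_y[c],
                    "n_met": self.n_x[c],
                    "n_exp": self.n_y[c],
                }
            )
        return pd.DataFrame(rows).set_index("class")


def _per_class_group_stats(
    m: GeneSampleMatrix,
    ann: SampleAnnotation,
    gene_idx: list[int],
) -> tuple[dict[str, float], dict[str, float], dict[str, int]]:
    """Mean / sd / n over class samples of the gene-averaged value."""
    present = set(m.sample_ids)
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    n: dict[str, int] = {}
    block = m.values[gene_idx, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        per_sample = np.nanmean(block, axis=0)
    for label in ann.classes():
        cols = [m.sample_index(s) for s in ann.samples_of(label)
                if s in present]
        if not cols:
            continue
        vals = per_sample[cols]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        mean[label] = float(vals.mean())
        sd[label] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
        n[label] = int(vals.size)
    return mean, sd, n


def coupling_summary(
    met: GeneSampleMatrix,
    exp: GeneSampleMatrix,
    group: list[str],
    met_ann: SampleAnnotation,
    exp_ann: SampleAnnotation,
    ref_class: str,
    target_class: str,
    group_name: str = "group",
    class_map: dict[str, str] | None = None,
) -> CouplingSummary:
    """Class-level coupling summary of one gene group.

    ``class_map`` optionally renames expression-annotation classes to
    the methylation nomenclature before joining. Both matrices should be
    centralized. Correlation needs >= 3 shared classes, else NaN with a
    warning.
    """
    if class_map:
        exp_ann = SampleAnnotation(
            {s: class_map.get(lab, lab) for s, lab in exp_ann.labels.items()}
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        met_pairs = match_genes(group, met)
        exp_pairs = match_genes(group, exp)
    if not met_pairs or not exp_pairs:
        raise ValueError(
            f"group {group_name!r} matches no genes in one of the matrices"
        )
    met_idx = [met.gene_index(b) for _, b in met_pairs]
    exp_idx = [exp.gene_index(b) for _, b in exp_pairs]
    x, sd_x, n_x = _per_class_group_stats(met, met_ann, met_idx)
    y, sd_y, n_y = _per_class_group_stats(exp, exp_ann, exp_idx)
    shared = [c for c in x if c in y]
    for c in (ref_class, target_class):
        if c not in shared:
            raise ValueError(f"class {c!r} missing from one of the cohorts")
    if len(shared) >= 3:
        xv = np.array([x[c] for c in shared])
        yv = np.array([y[c] for c in shared])
        if xv.std() > 0 and yv.std() > 0:
            rho = float(np.corrcoef(xv, yv)[0, 1])
        else:
            rho = float("nan")
    else:
        warnings.warn("fewer than 3 shared classes; correlation undefined")
        rho = float("nan")
    return CouplingSummary(
        group_name=group_name,
        classes=shared,
        x={c: x[c] for c in shared},
        y={c: y[c] for c in shared},
        sd_x={c: sd_x[c] for c in shared},
        sd_y={c: sd_y[c] for c in shared},
        n_x={c: n_x[c] for c in shared},
        n_y={c: n_y[c] for c in shared},
        correlation=rho,
        ref_class=ref_class,
        target_class=target_class,
        n_genes_met=len(met_idx),
        n_genes_exp=len(exp_idx),
    )


def classify_coupling(
    summary: CouplingSummary,
    dx_min: float = DEFAULT_DX_MIN,
    dy_min: float = DEFAULT_DY_MIN,
    rho_min: float = DEFAULT_RHO_MIN,
) -> str:
    """Coupling pattern from the across-class ranges and correlation.

    Rx < dx_min and Ry < dy_min        -> silent
    Rx >= dx_min and Ry < dy_min       -> methylation-only
    Rx < dx_min and Ry >= dy_min       -> expression-only
    otherwise: positive if rho >= rho_min, negative if rho <= -rho_min,
    else silent (with a warning: both modalities vary but uncorrelated).
    """
    if len(summary.classes) < 3:
        raise ValueError("classification needs >= 3 classes")
    xv = np.array([summary.x[c] for c in summary.classes])
    yv = np.array([summary.y[c] for c in summary.classes])
    rx = float(np.ptp(xv))
    ry = float(np.ptp(yv))
    if rx < dx_min and ry < dy_min:
        pattern = "silent"
    elif rx >= dx_min and ry < dy_min:
        pattern = "methylation-only"
    elif rx < dx_min and ry >= dy_min:
        pattern = "expression-only"
    else:
        rho = summary.correlation
        if np.isfinite(rho) and rho >= rho_min:
            pattern = "positive"
        elif np.isfinite(rho) and rho <= -rho_min:
            pattern = "negative"
        else:
            warnings.warn(
                f"group {summary.group_name!r}: both modalities vary but "
                f"|rho| < {rho_min}; labeled silent"
            )
            pattern = "silent"
    summary.pattern = pattern
    return pattern


def slope_indicator(
    summary: CouplingSummary,
) -> tuple[tuple[float, float], tuple[str, str]]:
    """Vector from the reference-class dot to the target-class dot and
    its sign pair ('+', '-' or '0')."""
    for c in (summary.ref_class, summary.target_class):
        if c not in summary.x or c not in summary.y:
            raise ValueError(f"class {c!r} missing from the summary")
    dx = summary.x[summary.target_class] - summary.x[summary.ref_class]
    dy = summary.y[summary.target_class] - summary.y[summary.ref_class]

    def sign(v: float) -> str:
        return "+" if v > 0 else ("-" if v < 0 else "0")

    return (float(dx), float(dy)), (sign(dx), sign(dy))


def read_class_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping expression class labels to methylation
    class labels (header optional)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"class-map line needs two columns: {line!r}")
            if parts[0].lower() in ("from", "source", "exp_class"):
                continue
            out[parts[0]] = parts[1]
    return out
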