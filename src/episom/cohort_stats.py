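"""Cohort-level methylation summary statistics.

Differential methylation against a reference class, integral hyper- and
hypomethylation (means of the positive and negative delta-beta values),
total methylation level, per-sample variance and pooled beta-value
histograms with Sarle's bimodality coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import GeneSampleMatrix, SampleAnnotation

__all__ = [
    "BIMODALITY_UNIFORM",
    "delta_beta",
    "integral_differential_methylation",
    "per_sample_variance",
    "bimodality_coefficient",
    "beta_distribution",
    "summarize_classes",
    "IntegralMethylation",
    "BetaDistribution",
]

#: Sarle's bimodality coefficient of the uniform distribution (5/9);
#: values above it indicate bimodality.
BIMODALITY_UNIFORM = 5.0 / 9.0


@dataclass
class IntegralMethylation:
    hyper: float  # mean of positive deltas (>= 0)
    hypo: float  # mean of negative deltas (<= 0)
    n_pos: int
    n_neg: int


@dataclass
class BetaDistribution:
    counts: np.ndarray
    bin_edges: np.ndarray
    bimodality: float
    n_values: int


def delta_beta(
    m: GeneSampleMatrix, ann: SampleAnnotation, reference_class: str
) -> pd.DataFrame:
    """Per-gene, per-class differential methylation.

    ``delta(gene, class) = mean(class samples) - mean(reference samples)``
    with missing values excluded from both means. The reference column is
    identically zero (where the reference mean exists).
    """
    ann.validate_against(m)
    classes = ann.classes()
    if reference_class not in classes:
        raise ValueError(f"unknown reference class {reference_class!r}")
    present = set(m.sample_ids)
    class_means = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for label in classes:
            cols = [
                m.sample_index(s)
                for s in ann.samples_of(label)
                if s in present
            ]
            if not cols:
                raise ValueError(f"class {label!r} has no samples in matrix")
            class_means[label] = np.nanmean(m.values[:, cols], axis=1)
    ref = class_means[reference_class]
    out = pd.DataFrame(
        {label: class_means[label] - ref for label in classes},
        index=m.gene_ids,
    )
    return out


def integral_differential_methylation(
    deltas: np.ndarray,
) -> IntegralMethylation:
    """Mean differential methylation averaged separately over the
    positive and the negative delta values."""
    d = np.asarray(deltas, dtype=float).ravel()
    d = d[np.isfinite(d)]
    if d.size == 0:
        warnings.warn("empty delta vector; integral methylation set to 0")
        return IntegralMethylation(0.0, 0.0, 0, 0)
    pos = d[d > 0]
    neg = d[d < 0]
    hyper = float(pos.mean()) if pos.size else 0.0
    hypo = float(neg.mean()) if neg.size else 0.0
    return IntegralMethylation(hyper, hypo, int(pos.size), int(neg.size))


def per_sample_variance(m: GeneSampleMatrix) -> pd.Series:
    """Population variance of values across genes, one entry per sample.

    Samples with fewer than two observed genes get NaN with a warning.
    """
    if m.n_genes < 2:
        raise ValueError("need at least two genes")
    out = np.full(m.n_samples, np.nan)
    n_bad = 0
    for j in range(m.n_samples):
        col = m.values[:, j]
        col = col[np.isfinite(col)]
        if col.size < 2:
            n_bad += 1
            continue
        out[j] = float(np.var(col))  # ddof=0, population variance
    if n_bad:
        warnings.warn(f"{n_bad} sample(s) with <2 observed genes; variance NaN")
    return pd.Series(out, index=m.sample_ids, name="variance")


def bimodality_coefficient(x: np.ndarray) -> float:
    """Sarle's bimodality coefficient b = (g1^2 + 1) / (g2 + c_n).

    ``g1``/``g2`` are the bias-corrected sample skewness and excess
    kurtosis, ``c_n = 3 (n-1)^2 / ((n-2)(n-3))``. b equals 5/9 for the
    uniform distribution and exceeds it for bimodal shapes. Requires
    n >= 4 and non-degenerate data.
    """
    x = np.asarray(x, dtype=float).ravel()
    x = x[np.isfinite(x)]
    n = x.size
    if n < 4:
        raise ValueError(f"bimodality coefficient needs n >= 4, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("bimodality coefficient undefined for constant data")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, fisher=True, bias=False)
    corr = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return float((g1**2 + 1.0) / (g2 + corr))


def beta_distribution(
    m: GeneSampleMatrix,
    ann: SampleAnnotation,
    class_label: str,
    n_bins: int = 50,
) -> BetaDistribution:
    """Histogram of beta values pooled over the samples of one class,
    with equal-width bins over [0, 1], plus the bimodality coefficient."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    samples = ann.samples_of(class_label)
    if not samples:
        raise ValueError(f"class {class_label!r} has no samples")
    cols = [m.sample_index(s) for s in samples]
    pooled = m.values[:, cols].ravel()
    pooled = pooled[np.isfinite(pooled)]
    counts, edges = np.histogram(pooled, bins=n_bins, range=(0.0, 1.0))
    b = bimodality_coefficient(pooled)
    return BetaDistribution(counts, edges, b, int(pooled.size))


def summarize_classes(
    m: GeneSampleMatrix,
    ann: SampleAnnotation,
    reference_class: str,
) -> pd.DataFrame:
    """Per-class summary table: integral hyper/hypomethylation vs the
    reference, delta counts, mean total beta, mean per-sample variance
    and the pooled bimodality coefficient."""
    deltas = delta_beta(m, ann, reference_class)
    variances = per_sample_variance(m)
    rows = []
    present = set(m.sample_ids)
    for label in ann.classes():
        integral = integral_differential_methylation(deltas[label].to_numpy())
        members = [s for s in ann.samples_of(label) if s in present]
        cols = [m.sample_index(s) for s in members]
        block = m.values[:, cols]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_beta = float(np.nanmean(block))
        var_mean = float(np.nanmean(variances.loc[members].to_numpy()))
        try:
            b = beta_distribution(m, ann, label).bimodality
        except ValueError:
            b = float("nan")
        rows.append(
            {
                "class": label,
                "n_samples": len(cols),
                "integral_hyper": integral.hyper,
                "integral_hypo": integral.hypo,
                "n_pos": integral.n_pos,
                "n_neg": integral.n_neg,
                "mean_beta": mean_beta,
                "mean_sample_variance": var_mean,
                "bimodality": b,
            }
        )
    return pd.DataFrame(rows).set_index("class")
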