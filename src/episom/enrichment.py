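"""Gene-set enrichment.

GSZ is the finite-population-corrected z-score of a set's mean score:
drawing n_S of the N universe genes without replacement, the set mean has
standard error sd(universe)/sqrt(n_S) * sqrt((N - n_S)/(N - 1)), so

    GSZ = (mean(set) - mean(universe)) / SE.

Class profiles apply the score to class-mean centralized values, and
profiles are stratified into high / moderate / low by a fixed threshold.
Spot-vs-set overlaps are reported as percentages with upper-tail
hypergeometric p-values (Benjamini-Hochberg adjusted across a table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import GeneSampleMatrix, SampleAnnotation

__all__ = [
    "GSZProfile",
    "gsz_score",
    "gsz_class_profile",
    "stratify_levels",
    "set_overlap_percentage",
    "overlap_table",
    "benjamini_hochberg",
]

DEFAULT_STRATUM_THRESHOLD = 1.0


@dataclass
class GSZProfile:
    """Per-class GSZ values for one gene set."""

    set_name: str
    values: dict[str, float]  # class -> GSZ
    universe_size: int
    set_size: int  # genes of the set present in the universe
    strata: dict[str, str] = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.set_name)


def _normalize(genes: Iterable[str]) -> list[str]:
    out, seen = [], set()
    for g in genes:
        gu = str(g).upper()
        if gu not in seen:
            out.append(gu)
            seen.add(gu)
    return out


def gsz_score(scores: pd.Series, gene_set: Sequence[str]) -> float:
    """GSZ of one gene set against per-gene scores (the universe).

    NaN scores are dropped from the universe. Returns NaN when the set
    does not intersect the universe; returns 0 with a warning when the
    universe has zero dispersion or the correction term vanishes
    (set = universe).
    """
    scores = scores.dropna()
    if len(scores) < 2:
        raise ValueError("universe needs >= 2 scored genes")
    universe_index = {str(g).upper(): g for g in scores.index}
    members = [universe_index[g] for g in _normalize(gene_set)
               if g in universe_index]
    if not members:
        warnings.warn("gene set does not intersect the universe")
        return float("nan")
    x = scores.to_numpy(dtype=float)
    N = x.size
    n_s = len(members)
    mu = x.mean()
    sd = x.std(ddof=0)
    if sd == 0:
        warnings.warn("universe has zero dispersion; GSZ set to 0")
        return 0.0
    fpc = (N - n_s) / (N - 1)
    if fpc <= 0:
        warnings.warn("set spans the whole universe; GSZ set to 0")
        return 0.0
    se = sd / np.sqrt(n_s) * np.sqrt(fpc)
    set_mean = float(scores.loc[members].mean())
    return float((set_mean - mu) / se)


def gsz_class_profile(
    m: GeneSampleMatrix,
    ann: SampleAnnotation,
    gene_set: Sequence[str],
    set_name: str = "set",
    threshold: float = DEFAULT_STRATUM_THRESHOLD,
) -> GSZProfile:
    """GSZ per class, scored on class-mean centralized values.

    For each class the per-gene score is the mean centralized value over
    that class's samples; the gene set is then z-scored against all
    genes of the matrix (the measured universe).
    """
    ann.validate_against(m)
    present = set(m.sample_ids)
    values: dict[str, float] = {}
    set_size = 0
    universe_size = 0
    for label in ann.classes():
        cols = [m.sample_index(s) for s in ann.samples_of(label)
                if s in present]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            class_mean = np.nanmean(m.values[:, cols], axis=1)
        scores = pd.Series(class_mean, index=m.gene_ids).dropna()
        universe_size = len(scores)
        norm_universe = {str(g).upper() for g in scores.index}
        set_size = len(set(_normalize(gene_set)) & norm_universe)
        values[label] = gsz_score(scores, gene_set)
    profile = GSZProfile(
        set_name=set_name,
        values=values,
        universe_size=universe_size,
        set_size=set_size,
    )
    profile.strata = stratify_levels(profile, threshold)
    return profile


def stratify_levels(
    profile: GSZProfile | dict[str, float],
    t: float = DEFAULT_STRATUM_THRESHOLD,
) -> dict[str, str]:
    """High / moderate / low per class: GSZ > t -> high, GSZ < -t -> low,
    otherwise (including exactly +/-t and NaN) moderate."""
    if t <= 0:
        raise ValueError("threshold must be positive")
    values = profile.values if isinstance(profile, GSZProfile) else profile
    out = {}
    for label, z in values.items():
        if np.isfinite(z) and z > t:
            out[label] = "high"
        elif np.isfinite(z) and z < -t:
            out[label] = "low"
        else:
            out[label] = "moderate"
    return out


def set_overlap_percentage(
    a: Sequence[str], b: Sequence[str], universe: Sequence[str]
) -> tuple[float, float]:
    """Percentage of set ``a`` found in set ``b`` plus the upper-tail
    hypergeometric p-value of observing at least that overlap when
    drawing |a| genes from the universe containing |b| successes."""
    uni = set(_normalize(universe))
    if not uni:
        raise ValueError("empty universe")
    set_a = [g for g in _normalize(a) if g in uni]
    set_b = set(_normalize(b)) & uni
    if not set_a:
        raise ValueError("set a has no genes in the universe")
    k = len(set(set_a) & set_b)
    n_a = len(set_a)
    percent = 100.0 * k / n_a
    # P(X >= k) for X ~ Hypergeom(N=|U|, K=|b|, n=|a|)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(set_b), n_a))
    return percent, p


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(ranked, 0.0, 1.0)
    return q


def overlap_table(
    spot_genes: dict[str, Sequence[str]],
    collection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Overlap percentages and (BH-adjusted) hypergeometric p-values for
    every (spot, gene set) pair."""
    rows = []
    for spot_label, genes in spot_genes.items():
        for set_name in collection.names():
            try:
                percent, p = set_overlap_percentage(
                    genes, collection[set_name], universe
                )
            except ValueError:
                continue
            rows.append(
                {
                    "spot": spot_label,
                    "gene_set": set_name,
                    "overlap_percent": percent,
                    "p_value": p,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df
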