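"""Synthetic paired methylation/expression cohorts with planted modules.

The generator emulates the statistical structure the analysis assumes:
per-gene baseline beta values drawn from a two-mode beta mixture (maxima
near 0 and 1), class-specific shifts on the beta scale that collapse the
bimodality in affected classes, and gene modules whose expression
changes are positively, negatively or not coupled to the methylation
changes. Methylation and expression sample sets are disjoint (unmatched
cohorts) but share class labels. Everything is bit-reproducible for a
fixed seed, and the planted ground truth is emitted alongside the data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .datamodel_io import (
    MODALITY_EXPRESSION,
    MODALITY_METHYLATION,
    GeneSampleMatrix,
    GeneSetCollection,
    SampleAnnotation,
)

__all__ = [
    "ClassSpec",
    "ModuleSpec",
    "SyntheticCohortConfig",
    "SyntheticTruth",
    "CohortBundle",
    "generate_cohort",
    "default_paper_like_config",
]

COUPLINGS = ("positive", "negative", "met_only", "exp_only")


@dataclass
class ClassSpec:
    label: str
    n_met: int
    n_exp: int


@dataclass
class ModuleSpec:
    """One planted gene module.

    ``beta_shift`` is added on the beta scale in the affected classes
    (ignored for exp_only coupling); ``expr_shift`` is added on the log2
    scale (ignored for met_only coupling).
    """

    name: str
    n_genes: int
    classes: list[str]
    beta_shift: float
    expr_shift: float
    coupling: str

    def __post_init__(self) -> None:
        if self.coupling not in COUPLINGS:
            raise ValueError(
                f"coupling must be one of {COUPLINGS}, got {self.coupling!r}"
            )
        if not -1.0 <= self.beta_shift <= 1.0:
            raise ValueError("beta_shift must lie in [-1, 1]")
        if self.coupling == "positive" and self.beta_shift * self.expr_shift < 0:
            raise ValueError("positive coupling needs matching shift signs")
        if self.coupling == "negative" and self.beta_shift * self.expr_shift > 0:
            raise ValueError("negative coupling needs opposite shift signs")

    @property
    def effective_beta_shift(self) -> float:
        return 0.0 if self.coupling == "exp_only" else self.beta_shift

    @property
    def effective_expr_shift(self) -> float:
        return 0.0 if self.coupling == "met_only" else self.expr_shift


@dataclass
class SyntheticCohortConfig:
    classes: list[ClassSpec]
    n_background_genes: int
    modules: list[ModuleSpec] = field(default_factory=list)
    beta_low: tuple[float, float] = (2.0, 20.0)
    beta_high: tuple[float, float] = (20.0, 2.0)
    high_fraction: float = 0.4
    sample_noise_sd: float = 0.05
    expression_noise_sd: float = 0.4
    expression_baseline_mean: float = 8.0
    expression_baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate class labels")
        for mod in self.modules:
            for c in mod.classes:
                if c not in labels:
                    raise ValueError(
                        f"module {mod.name!r} targets unknown class {c!r}"
                    )

    @property
    def n_genes(self) -> int:
        return self.n_background_genes + sum(m.n_genes for m in self.modules)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "classes": [[c.label, c.n_met, c.n_exp] for c in self.classes],
            "n_background_genes": self.n_background_genes,
            "modules": [
                {
                    "name": m.name,
                    "n_genes": m.n_genes,
                    "classes": list(m.classes),
                    "beta_shift": m.beta_shift,
                    "expr_shift": m.expr_shift,
                    "coupling": m.coupling,
                }
                for m in self.modules
            ],
            "beta_low": list(self.beta_low),
            "beta_high": list(self.beta_high),
            "high_fraction": self.high_fraction,
            "sample_noise_sd": self.sample_noise_sd,
            "expression_noise_sd": self.expression_noise_sd,
            "expression_baseline_mean": self.expression_baseline_mean,
            "expression_baseline_sd": self.expression_baseline_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCohortConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            classes=[ClassSpec(str(l), int(nm), int(ne))
                     for l, nm, ne in payload["classes"]],
            n_background_genes=int(payload["n_background_genes"]),
            modules=[ModuleSpec(**m) for m in payload.get("modules", [])],
            beta_low=tuple(payload.get("beta_low", (2.0, 20.0))),
            beta_high=tuple(payload.get("beta_high", (20.0, 2.0))),
            high_fraction=float(payload.get("high_fraction", 0.4)),
            sample_noise_sd=float(payload.get("sample_noise_sd", 0.05)),
            expression_noise_sd=float(payload.get("expression_noise_sd", 0.4)),
            expression_baseline_mean=float(
                payload.get("expression_baseline_mean", 8.0)
            ),
            expression_baseline_sd=float(
                payload.get("expression_baseline_sd", 1.5)
            ),
            seed=int(payload["seed"]),
        )


@dataclass
class SyntheticTruth:
    """Planted module membership, shifts and coupling signs."""

    gene_module: dict[str, str]  # gene -> module name or "background"
    modules: dict[str, dict]  # name -> {classes, beta_shift, expr_shift, coupling, genes}
    expected_delta_beta: dict[str, dict[str, float]]  # module -> class -> delta

    def module_genes(self, name: str) -> list[str]:
        return list(self.modules[name]["genes"])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "gene_module": self.gene_module,
                    "modules": self.modules,
                    "expected_delta_beta": self.expected_delta_beta,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            gene_module=payload["gene_module"],
            modules=payload["modules"],
            expected_delta_beta=payload["expected_delta_beta"],
        )

    def to_gmt(self) -> GeneSetCollection:
        return GeneSetCollection(
            {name: info["genes"] for name, info in self.modules.items()},
            {name: "planted_module" for name in self.modules},
        )


@dataclass
class CohortBundle:
    met: GeneSampleMatrix
    exp: GeneSampleMatrix
    met_ann: SampleAnnotation
    exp_ann: SampleAnnotation
    truth: SyntheticTruth


def _sample_ids(prefix: str, classes: list[ClassSpec], which: str) -> tuple[list[str], dict[str, str]]:
    ids: list[str] = []
    labels: dict[str, str] = {}
    for spec in classes:
        n = spec.n_met if which == "met" else spec.n_exp
        for i in range(n):
            sid = f"{prefix}_{spec.label}_{i + 1:03d}"
            ids.append(sid)
            labels[sid] = spec.label
    return ids, labels


def generate_cohort(config: SyntheticCohortConfig) -> CohortBundle:
    """Generate an unmatched methylation/expression cohort pair.

    Module genes are listed first (grouped by module), then background
    genes. For beta shifts the module baselines come from the mode that
    leaves headroom for the shift (low mode for hypermethylation, high
    mode for hypomethylation), so clipping stays rare; a warning reports
    clipping when it affects more than 5% of the methylation values.
    """
    rng = np.random.default_rng(config.seed)
    a_lo, b_lo = config.beta_low
    a_hi, b_hi = config.beta_high

    gene_ids: list[str] = []
    gene_module: dict[str, str] = {}
    module_of_gene: list[ModuleSpec | None] = []
    for mod in config.modules:
        for i in range(mod.n_genes):
            g = f"{mod.name.upper()}_G{i + 1:04d}"
            gene_ids.append(g)
            gene_module[g] = mod.name
            module_of_gene.append(mod)
    for i in range(config.n_background_genes):
        g = f"BG_G{i + 1:05d}"
        gene_ids.append(g)
        gene_module[g] = "background"
        module_of_gene.append(None)
    n_genes = len(gene_ids)

    # per-gene baselines (shared across samples and classes)
    baseline_beta = np.empty(n_genes)
    for i, mod in enumerate(module_of_gene):
        shift = mod.effective_beta_shift if mod is not None else 0.0
        if mod is not None and shift > 0:
            baseline_beta[i] = rng.beta(a_lo, b_lo)
        elif mod is not None and shift < 0:
            baseline_beta[i] = rng.beta(a_hi, b_hi)
        else:
            if rng.random() < config.high_fraction:
                baseline_beta[i] = rng.beta(a_hi, b_hi)
            else:
                baseline_beta[i] = rng.beta(a_lo, b_lo)
    baseline_expr = (
        config.expression_baseline_mean
        + config.expression_baseline_sd * rng.standard_normal(n_genes)
    )

    met_ids, met_labels = _sample_ids("MET", config.classes, "met")
    exp_ids, exp_labels = _sample_ids("EXP", config.classes, "exp")

    met_shift = np.zeros((n_genes, len(met_ids)))
    exp_shift = np.zeros((n_genes, len(exp_ids)))
    for i, mod in enumerate(module_of_gene):
        if mod is None:
            continue
        affected = set(mod.classes)
        if mod.effective_beta_shift != 0.0:
            for j, s in enumerate(met_ids):
                if met_labels[s] in affected:
                    met_shift[i, j] = mod.effective_beta_shift
        if mod.effective_expr_shift != 0.0:
            for j, s in enumerate(exp_ids):
                if exp_labels[s] in affected:
                    exp_shift[i, j] = mod.effective_expr_shift

    met_raw = (
        baseline_beta[:, None]
        + met_shift
        + config.sample_noise_sd * rng.standard_normal((n_genes, len(met_ids)))
    )
    met_values = np.clip(met_raw, 0.0, 1.0)
    n_clipped = int(np.sum(met_raw != met_values))
    if n_clipped > 0.05 * met_values.size:
        warnings.warn(
            f"clipping affected {n_clipped} of {met_values.size} "
            "methylation values (> 5%)"
        )
    exp_values = (
        baseline_expr[:, None]
        + exp_shift
        + config.expression_noise_sd
        * rng.standard_normal((n_genes, len(exp_ids)))
    )

    met = GeneSampleMatrix(met_values, gene_ids, met_ids, MODALITY_METHYLATION)
    exp = GeneSampleMatrix(exp_values, gene_ids, exp_ids, MODALITY_EXPRESSION)

    modules_info: dict[str, dict] = {}
    expected_delta: dict[str, dict[str, float]] = {}
    for mod in config.modules:
        genes = [g for g in gene_ids if gene_module[g] == mod.name]
        modules_info[mod.name] = {
            "classes": list(mod.classes),
            "beta_shift": mod.effective_beta_shift,
            "expr_shift": mod.effective_expr_shift,
            "coupling": mod.coupling,
            "genes": genes,
        }
        expected_delta[mod.name] = {
            spec.label: (
                mod.effective_beta_shift if spec.label in mod.classes else 0.0
            )
            for spec in config.classes
        }
    truth = SyntheticTruth(
        gene_module=gene_module,
        modules=modules_info,
        expected_delta_beta=expected_delta,
    )
    return CohortBundle(
        met=met,
        exp=exp,
        met_ann=SampleAnnotation(met_labels),
        exp_ann=SampleAnnotation(exp_labels),
        truth=truth,
    )


def default_paper_like_config(seed: int = 0) -> SyntheticCohortConfig:
    """Desk-scale stand-in for the source cohorts: 8 classes with the
    published methylation sample counts (133 samples total), 768 genes,
    five planted differential-methylation modules and one expression-only
    proliferation module.

    All five differential-methylation modules carry beta shifts (two
    positive-coupling, one negative-coupling, two methylation-only) so
    each is recoverable as a methylation spot; the sixth module varies
    in expression only.
    """
    classes = [
        ClassSpec("DLBCL", 54, 54),
        ClassSpec("mBL", 18, 18),
        ClassSpec("IntL", 16, 16),
        ClassSpec("FL", 14, 14),
        ClassSpec("MCL", 10, 10),
        ClassSpec("MM", 14, 14),
        ClassSpec("B", 5, 5),
        ClassSpec("GCB", 2, 2),
    ]
    modules = [
        ModuleSpec("mod_i", 40, ["DLBCL", "IntL"], 0.35, 1.2, "positive"),
        ModuleSpec("mod_v", 40, ["DLBCL", "FL"], 0.30, 1.0, "positive"),
        ModuleSpec("mod_iii", 40, ["DLBCL", "IntL"], -0.35, 1.2, "negative"),
        ModuleSpec("mod_iv", 40, ["MM"], 0.30, 0.0, "met_only"),
        ModuleSpec("mod_ii", 40, ["mBL", "MCL"], 0.30, 0.0, "met_only"),
        ModuleSpec("mod_prolif", 40, ["mBL"], 0.0, 1.5, "exp_only"),
    ]
    return SyntheticCohortConfig(
        classes=classes,
        n_background_genes=768 - 240,
        modules=modules,
        seed=seed,
    )
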