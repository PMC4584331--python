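"""Sample similarity networks over metagene landscapes.

Samples are connected when the Pearson correlation of their landscapes
strictly exceeds a threshold (default r > 0.5); clusters are the
connected components of the resulting graph, with isolated samples kept
as singleton components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel_io import SampleAnnotation
from .som_core import SOMModel

__all__ = [
    "SampleNetwork",
    "sample_similarity",
    "build_network",
    "component_composition",
]

DEFAULT_R_MIN = 0.5


@dataclass
class SampleNetwork:
    graph: nx.Graph
    r_min: float
    components: list[set[str]]  # decreasing size, ties by smallest member

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"sample_a": a, "sample_b": b, "r": d["r"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["sample_a", "sample_b", "r"])

    def membership(self) -> dict[str, int]:
        """sample -> 0-based component index."""
        out = {}
        for k, comp in enumerate(self.components):
            for s in comp:
                out[s] = k
        return out


def sample_similarity(model: SOMModel, raw: bool = False) -> pd.DataFrame:
    """Pearson correlation between sample landscapes.

    By default landscapes are the codebook columns (metagene level); with
    ``raw=True`` the original gene-level vectors are correlated instead.
    Samples with zero-variance landscapes get NaN correlations.
    """
    X = model.data if raw else model.codebook
    if model.n_samples < 2:
        raise ValueError("need >= 2 samples")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 units/genes")
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} sample(s) with zero-variance "
            "landscape; correlations set to NaN"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, np.where(degenerate, np.nan, 1.0))
    return pd.DataFrame(r, index=model.sample_ids, columns=model.sample_ids)


def build_network(
    sim: pd.DataFrame,
    ann: SampleAnnotation | None = None,
    r_min: float = DEFAULT_R_MIN,
) -> SampleNetwork:
    """Threshold a similarity matrix into a graph (strictly r > r_min).

    Isolated samples are retained as nodes; components are sorted by
    decreasing size (ties by smallest member id).
    """
    if not np.allclose(
        sim.to_numpy(), sim.to_numpy().T, equal_nan=True, atol=1e-12
    ):
        raise ValueError("similarity matrix is not symmetric")
    g = nx.Graph()
    samples = list(sim.index)
    for s in samples:
        label = ann.labels.get(s, "unknown") if ann is not None else "unknown"
        g.add_node(s, label=label)
    values = sim.to_numpy()
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            r = values[i, j]
            if np.isfinite(r) and r > r_min:
                g.add_edge(samples[i], samples[j], r=float(r))
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return SampleNetwork(graph=g, r_min=float(r_min), components=comps)


def component_composition(net: SampleNetwork) -> pd.DataFrame:
    """Count and percentage of each class inside every component.

    Percentages are per class: across all components they sum to 100
    for every class present in the network.
    """
    class_totals: dict[str, int] = {}
    for _, d in net.graph.nodes(data=True):
        class_totals[d["label"]] = class_totals.get(d["label"], 0) + 1
    rows = []
    for k, comp in enumerate(net.components):
        counts: dict[str, int] = {}
        for s in comp:
            lab = net.graph.nodes[s]["label"]
            counts[lab] = counts.get(lab, 0) + 1
        for lab, n in sorted(counts.items()):
            rows.append(
                {
                    "component": k,
                    "component_size": len(comp),
                    "class": lab,
                    "count": n,
                    "percent_of_class": 100.0 * n / class_totals[lab],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "component",
            "component_size",
            "class",
            "count",
            "percent_of_class",
        ],
    )
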