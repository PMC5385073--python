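"""Genus co-occurrence networks from relative-abundance profiles.

Every genus pair is tested by Pearson correlation across samples; edges are
kept at p < alpha (two-sided t-transform of r, optionally BH-corrected).
Nodes carry mean relative abundance and a strain-enrichment label so the
network can be rendered with enriched-in-A / enriched-in-B coloring.  No
compositional transform is applied by default: correlations are computed on
the relative abundances as analyzed (the compositionality caveat is
documented in the methods note).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError
from .quantify import AbundanceProfile
from .stats import adjust_pvalues

logger = logging.getLogger(__name__)


def build_network(
    genus_profile: AbundanceProfile | pd.DataFrame,
    enrichment: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    correction: str | None = None,
) -> nx.Graph:
    """Co-occurrence network over all genus pairs at p < alpha.

    Constant (zero-variance) genera have undefined correlations: they are
    retained as nodes but excluded from edge testing (logged).  Edge
    attributes: ``r``, ``p``, ``sign``; node attributes: ``mean_abundance``,
    ``enrichment`` ('A', 'B' or 'none').
    """
    data = genus_profile.data if isinstance(genus_profile, AbundanceProfile) else genus_profile
    if len(data) < 3:
        raise InvalidInputError("network construction requires at least 3 samples")
    if data.shape[1] < 2:
        raise InvalidInputError("network construction requires at least 2 genera")
    enrichment = dict(enrichment or {})

    graph = nx.Graph()
    values = data.to_numpy(dtype=float)
    constant = (values == values[0]).all(axis=0)
    for j, genus in enumerate(data.columns):
        graph.add_node(
            str(genus),
            mean_abundance=float(values[:, j].mean()),
            enrichment=enrichment.get(genus, "none"),
        )
    if constant.any():
        logger.warning(
            "constant genera excluded from correlation testing: %s",
            list(data.columns[constant]),
        )

    testable = np.flatnonzero(~constant)
    candidates = []
    for ai in range(len(testable)):
        for bi in range(ai + 1, len(testable)):
            j, k = testable[ai], testable[bi]
            r, p = sps.pearsonr(values[:, j], values[:, k])
            candidates.append((data.columns[j], data.columns[k], float(r), float(p)))
    if correction is not None and candidates:
        adjusted = adjust_pvalues([c[3] for c in candidates], correction)
        candidates = [(u, v, r, float(pa)) for (u, v, r, _), pa in zip(candidates, adjusted)]
    for u, v, r, p in candidates:
        if p < alpha:
            graph.add_edge(str(u), str(v), r=r, p=p, sign=1 if r >= 0 else -1)
    return graph


def edge_list_frame(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        [u, v, d["r"], d["p"], d["sign"]]
        for u, v, d in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1]))
    ]
    return pd.DataFrame(rows, columns=["genus_a", "genus_b", "r", "p", "sign"])


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    edge_list_frame(graph).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))
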