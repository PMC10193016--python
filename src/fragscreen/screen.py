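"""Library scoring support: Tanimoto similarity network, 2-D embedding,
and probability/neighbor/property hit filters.

A screened molecule is nominated as a hit when its predicted activity
probability falls in a mid-confidence band (the off-target triage regime:
very high probabilities tend to be trivial rediscoveries of the training
chemistry), it sits in a structurally coherent neighborhood of the
similarity network, and its properties fall in drug-like ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import DataStructs
from sklearn.manifold import TSNE

from .chem import MoleculeRecord, ecfp_fingerprint


@dataclass
class HitFilterCriteria:
    prob_min: float = 0.6
    prob_max: float = 0.9   # set to 1.0 for a pure "larger than 0.6" rule
    min_neighbors: int = 3
    hba_range: tuple = (0, 10)
    hbd_range: tuple = (0, 5)
    clogp_range: tuple = (0.0, 5.0)
    mw_range: tuple = (300.0, 1000.0)  # g/mol

    def __post_init__(self):
        for lo, hi in (self.hba_range, self.hbd_range, self.clogp_range,
                       self.mw_range, (self.prob_min, self.prob_max)):
            if lo > hi:
                raise ValueError("filter range has min > max")

    def to_dict(self) -> dict:
        return {"prob_min": self.prob_min, "prob_max": self.prob_max,
                "min_neighbors": self.min_neighbors,
                "hba_range": list(self.hba_range),
                "hbd_range": list(self.hbd_range),
                "clogp_range": list(self.clogp_range),
                "mw_range": list(self.mw_range)}


def build_similarity_network(library: list[MoleculeRecord],
                             edge_threshold: float = 0.4,
                             fp_radius: int = 2,
                             fp_bits: int = 2048) -> nx.Graph:
    """All-pairs ECFP Tanimoto graph with edges at similarity >= threshold.

    Node attribute ``neighbor_count`` holds the degree; edge attribute
    ``similarity`` the Tanimoto value. No self-edges.
    """
    graph = nx.Graph()
    ids = [r.id for r in library]
    graph.add_nodes_from(ids)
    fps = [ecfp_fingerprint(r, fp_radius, fp_bits) for r in library]
    for i in range(len(fps)):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
        for j_off, sim in enumerate(sims):
            if sim >= edge_threshold:
                graph.add_edge(ids[i], ids[i + 1 + j_off], similarity=float(sim))
    nx.set_node_attributes(graph, dict(graph.degree()), "neighbor_count")
    return graph


def embed_2d(features: np.ndarray, perplexity: float = 30.0,
             rng_seed: int = 0) -> np.ndarray:
    """t-SNE map of the feature matrix; reporting only, never a filter."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 3:
        raise ValueError("need at least 3 molecules to embed")
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < n ({n})")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=rng_seed,
                init="pca")
    return tsne.fit_transform(features)


def filter_hits(records: pd.DataFrame,
                criteria: HitFilterCriteria) -> tuple[list, pd.DataFrame]:
    """Apply all hit criteria (inclusive bounds) to a screen table.

    ``records`` needs columns: id, probability, neighbor_count, hba, hbd,
    logp, mw. Returns ``(hit ids, audit table)``; the audit table keeps
    one row per input molecule with per-criterion pass flags. Molecules
    with a missing probability are flagged, never silently dropped.
    """
    audit = records.copy()
    missing = audit["probability"].isna()
    audit["missing_probability"] = missing
    audit["pass_probability"] = (~missing
                                 & (audit["probability"] >= criteria.prob_min)
                                 & (audit["probability"] <= criteria.prob_max))
    audit["pass_neighbors"] = audit["neighbor_count"] >= criteria.min_neighbors
    for flag, col, (lo, hi) in (
            ("pass_hba", "hba", criteria.hba_range),
            ("pass_hbd", "hbd", criteria.hbd_range),
            ("pass_clogp", "logp", criteria.clogp_range),
            ("pass_mw", "mw", criteria.mw_range)):
        audit[flag] = (audit[col] >= lo) & (audit[col] <= hi)
    flag_cols = ["pass_probability", "pass_neighbors", "pass_hba",
                 "pass_hbd", "pass_clogp", "pass_mw"]
    audit["is_hit"] = audit[flag_cols].all(axis=1)
    hits = audit.loc[audit["is_hit"], "id"].tolist()
    return hits, audit
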