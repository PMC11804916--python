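"""Thresholded Pearson correlation networks and their scalar summaries.

Nodes are items, edges are pairwise Pearson correlations across patients;
coefficients whose magnitude falls below the threshold (default |r| < 0.2)
are set to zero, and items left without any edge can be dropped.  Global
strength (sum of absolute edge weights) and density (fraction of possible
node pairs with an edge) are the summaries used to compare networks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import SymptomDataset
from .items import ItemSpec, items_to_frame

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-10


@dataclass
class SymptomNetwork:
    """Symmetric weighted item-by-item network with a zero diagonal.

    Every stored weight w is either 0 or satisfies |w| >= threshold.
    """

    weights: np.ndarray
    items: list[ItemSpec]
    threshold: float = 0.0
    cohort_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if len(self.items) != w.shape[0]:
            raise ValueError("one ItemSpec per node required")
        if not np.allclose(w, w.T, atol=_SYM_TOL):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(np.diag(w)) > _SYM_TOL):
            raise ValueError("diagonal must be zero")
        nz = w[w != 0]
        if nz.size and np.min(np.abs(nz)) < self.threshold - _SYM_TOL:
            raise ValueError(
                "nonzero weight below the stated threshold "
                f"({np.min(np.abs(nz)):.4g} < {self.threshold})"
            )
        self.items = list(self.items)

    @property
    def n_items(self) -> int:
        return self.weights.shape[0]

    @property
    def labels(self) -> list[str]:
        return [it.label for it in self.items]

    def edges(self) -> list[tuple[str, str, float]]:
        """Nonzero unordered pairs as (label_a, label_b, weight)."""
        iu, ju = np.triu_indices(self.n_items, k=1)
        out = []
        for i, j in zip(iu, ju):
            w = self.weights[i, j]
            if w != 0:
                out.append((self.labels[i], self.labels[j], float(w)))
        return out

    @property
    def edge_count(self) -> int:
        iu, ju = np.triu_indices(self.n_items, k=1)
        return int(np.count_nonzero(self.weights[iu, ju]))


def _generic_items(m: int) -> list[ItemSpec]:
    return [ItemSpec(f"v{i}", "psychopathology") for i in range(m)]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def correlation_matrix(ds: SymptomDataset) -> np.ndarray:
    """Pairwise Pearson correlations across patients, diagonal zeroed.

    Requires complete data, at least 3 subjects, and no zero-variance
    column (such columns should have been caught upstream).
    """
    if not ds.is_complete:
        raise ValueError("correlation_matrix requires complete data")
    if ds.n_subjects < 3:
        raise ValueError("need at least 3 subjects for a correlation network")
    sd = ds.scores.std(axis=0)
    if np.any(sd == 0):
        bad = [ds.labels[j] for j in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance items: {bad}")
    corr = np.corrcoef(ds.scores, rowvar=False)
    np.fill_diagonal(corr, 0.0)
    return corr


def apply_threshold(
    corr: np.ndarray,
    threshold: float = 0.2,
    items: Sequence[ItemSpec] | None = None,
    mode: str = "absolute",
    cohort_id: str = "",
) -> SymptomNetwork:
    """Zero out weak correlations and wrap the result as a network.

    ``mode="absolute"`` (default) zeroes entries with |r| < threshold and
    keeps the sign of survivors; ``mode="signed"`` zeroes every entry with
    r < threshold, i.e. discards all negative correlations.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    if mode not in ("absolute", "signed"):
        raise ValueError("mode must be 'absolute' or 'signed'")
    corr = np.asarray(corr, dtype=float)
    if not np.allclose(corr, corr.T, atol=_SYM_TOL):
        raise ValueError("input matrix must be symmetric")
    if np.any(np.abs(np.diag(corr)) > _SYM_TOL):
        raise ValueError("input matrix must have a zero diagonal")
    w = corr.copy()
    if mode == "absolute":
        w[np.abs(w) < threshold] = 0.0
    else:
        w[w < threshold] = 0.0
    np.fill_diagonal(w, 0.0)
    if items is None:
        items = _generic_items(w.shape[0])
    return SymptomNetwork(w, list(items), threshold=threshold, cohort_id=cohort_id)


def build_network(
    ds: SymptomDataset, threshold: float = 0.2, mode: str = "absolute"
) -> SymptomNetwork:
    """correlation_matrix + apply_threshold in one step."""
    return apply_threshold(
        correlation_matrix(ds), threshold, ds.items, mode=mode, cohort_id=ds.cohort_id
    )


def drop_isolated_nodes(net: SymptomNetwork) -> SymptomNetwork:
    """Remove items whose correlations with every other item fell below
    the threshold (all-zero rows); the removal list is logged."""
    deg = np.count_nonzero(net.weights, axis=1)
    keep = np.where(deg > 0)[0]
    if keep.size == 0:
        raise ValueError("every node is isolated; no network remains")
    dropped = [net.labels[i] for i in np.where(deg == 0)[0]]
    if dropped:
        logger.info(
            "dropping %d isolated node(s) from %s: %s",
            len(dropped), net.cohort_id or "network", dropped,
        )
    return SymptomNetwork(
        net.weights[np.ix_(keep, keep)],
        [net.items[i] for i in keep],
        threshold=net.threshold,
        cohort_id=net.cohort_id,
    )


# ---------------------------------------------------------------------------
# scalar summaries
# ---------------------------------------------------------------------------

def global_strength(net: SymptomNetwork | np.ndarray) -> float:
    """Weighted sum of absolute connections over unordered node pairs."""
    w = net.weights if isinstance(net, SymptomNetwork) else np.asarray(net)
    iu, ju = np.triu_indices(w.shape[0], k=1)
    return float(np.sum(np.abs(w[iu, ju])))


def network_density(net: SymptomNetwork | np.ndarray) -> float:
    """Fraction of possible unordered node pairs with a nonzero edge."""
    w = net.weights if isinstance(net, SymptomNetwork) else np.asarray(net)
    m = w.shape[0]
    if m < 2:
        raise ValueError("density needs at least 2 nodes")
    iu, ju = np.triu_indices(m, k=1)
    return float(np.count_nonzero(w[iu, ju]) / (m * (m - 1) / 2))


# ---------------------------------------------------------------------------
# I/O: TSV edge list + JSON node table
# ---------------------------------------------------------------------------

def write_network(
    net: SymptomNetwork, edge_path: str | Path, node_path: str | Path
) -> None:
    """Serialize as a TSV edge list (weights at 10 significant digits) and
    a JSON node table carrying item metadata and the threshold."""
    rows = [
        {"item_a": a, "item_b": b, "weight": f"{w:.10g}"} for a, b, w in net.edges()
    ]
    pd.DataFrame(rows, columns=["item_a", "item_b", "weight"]).to_csv(
        edge_path, sep="\t", index=False
    )
    nodes = items_to_frame(net.items).to_dict(orient="records")
    payload = {
        "cohort_id": net.cohort_id,
        "threshold": net.threshold,
        "nodes": nodes,
    }
    Path(node_path).write_text(json.dumps(payload, indent=2))


def read_network(edge_path: str | Path, node_path: str | Path) -> SymptomNetwork:
    payload = json.loads(Path(node_path).read_text())
    items = []
    for row in payload["nodes"]:
        levels = row.get("likert_levels")
        items.append(
            ItemSpec(
                label=row["label"],
                domain=row["domain"],
                polarity=row["polarity"],
                response_type=row["response_type"],
                likert_levels=None if levels is None or pd.isna(levels) else int(levels),
                worry=bool(row.get("worry_flag", 0)),
            )
        )
    labels = [it.label for it in items]
    m = len(items)
    w = np.zeros((m, m))
    edges = pd.read_csv(edge_path, sep="\t")
    for _, row in edges.iterrows():
        i, j = labels.index(str(row["item_a"])), labels.index(str(row["item_b"]))
        w[i, j] = w[j, i] = float(row["weight"])
    return SymptomNetwork(
        w, items, threshold=float(payload["threshold"]), cohort_id=payload["cohort_id"]
    )
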