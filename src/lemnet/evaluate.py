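"""Scoring of inferred edge rankings against a signed gold standard.

The universe is the full set of signed directed edges over the gene list
(2 N^2 with self-edges, the default; a flag drops them or collapses
signs). Rankings are scored with AUC-ROC (Mann-Whitney tie convention:
half credit for ties, so an uninformative constant ranking scores exactly
0.5), AUPR (step-wise interpolation), and extracted binary networks with
the Matthews correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .model_core import EdgeModel, Sign
from .infer import NodePosterior

__all__ = [
    "GoldStandard",
    "EdgeRanking",
    "roc_auc",
    "aupr",
    "mcc",
    "rank_table",
    "ranking_from_posteriors",
    "edges_to_digraph",
]


def edges_to_digraph(edges: "list[EdgeModel]"):
    """Signed edge list as a networkx DiGraph (regulator -> target, edge
    attribute ``sign`` in {'a', 'r'}); handy for drawing and graph queries."""
    import networkx as nx

    G = nx.DiGraph()
    for e in edges:
        G.add_edge(e.regulator, e.target, sign=e.sign.value)
    return G


@dataclass
class GoldStandard:
    """Signed directed gold-standard network over a fixed gene list.

    ``positives`` must be drawn from the universe of all signed directed
    gene pairs (self-edges included unless ``include_self`` is False).
    """

    genes: list[str]
    positives: set[EdgeModel]
    include_self: bool = True

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene names must be unique")
        self.positives = set(self.positives)
        universe = set(self.universe())
        stray = self.positives - universe
        if stray:
            raise ValueError(f"positive edges outside the universe: {sorted(map(str, stray))}")

    def universe(self) -> list[EdgeModel]:
        """All candidate signed directed edges, in deterministic order."""
        out = []
        for tgt in self.genes:
            for reg in self.genes:
                if not self.include_self and tgt == reg:
                    continue
                for sign in (Sign.ACTIVATION, Sign.REPRESSION):
                    out.append(EdgeModel(tgt, reg, sign))
        return out

    def labels(self) -> np.ndarray:
        return np.array([e in self.positives for e in self.universe()], dtype=int)


@dataclass
class EdgeRanking:
    """Scores in [0, 1] for signed directed edges; universe edges missing
    from the map are treated as scored 0."""

    scores: dict[EdgeModel, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e, v in self.scores.items():
            if not np.isfinite(v) or v < 0 or v > 1:
                raise ValueError(f"score for {e} must be finite in [0, 1], got {v}")

    def vector(self, gold: GoldStandard) -> np.ndarray:
        return np.array([self.scores.get(e, 0.0) for e in gold.universe()])


def ranking_from_posteriors(posteriors: list[NodePosterior]) -> EdgeRanking:
    """Pool per-node posterior probabilities into one edge ranking.

    Each node's posterior sums to 1, so probabilities are comparable
    across targets and can be ranked jointly.
    """
    scores: dict[EdgeModel, float] = {}
    for post in posteriors:
        for edge, p in post.probabilities.items():
            scores[edge] = float(np.clip(p, 0.0, 1.0))
    return EdgeRanking(scores)


def _check_gold(gold: GoldStandard) -> None:
    y = gold.labels()
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(
            "gold standard must contain at least one positive and one "
            "negative edge in the universe"
        )


def roc_auc(ranking: EdgeRanking, gold: GoldStandard) -> float:
    """Area under the ROC curve of the ranking over the universe.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg) for a
    random positive/negative pair; a constant ranking scores exactly 0.5.
    """
    _check_gold(gold)
    return float(roc_auc_score(gold.labels(), ranking.vector(gold)))


def aupr(ranking: EdgeRanking, gold: GoldStandard) -> float:
    """Area under the precision-recall curve (step-wise interpolation).

    A constant ranking scores the prevalence of positives in the universe;
    a perfect ranking scores 1.
    """
    _check_gold(gold)
    return float(average_precision_score(gold.labels(), ranking.vector(gold)))


def mcc(predicted: "set[EdgeModel] | list[EdgeModel]", gold: GoldStandard) -> float:
    """Matthews correlation of a binary edge prediction over the universe.

    Returns 0 when any confusion-matrix marginal is zero (the correlation
    is undefined there).
    """
    predicted = set(predicted)
    universe = set(gold.universe())
    stray = predicted - universe
    if stray:
        raise ValueError(f"predicted edges outside the universe: {sorted(map(str, stray))}")
    tp = len(predicted & gold.positives)
    fp = len(predicted - gold.positives)
    fn = len(gold.positives - predicted)
    tn = len(universe) - tp - fp - fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def rank_table(
    posteriors: list[NodePosterior], gold: GoldStandard | None = None
) -> pd.DataFrame:
    """All scored edges sorted by probability (descending), deterministic.

    Columns: target, regulator, sign, probability, and ``in_gold`` when a
    gold standard is supplied. Ties are ordered by (target, regulator,
    sign) so the table is reproducible.
    """
    ranking = ranking_from_posteriors(posteriors)
    rows = [
        {
            "target": e.target,
            "regulator": e.regulator,
            "sign": e.sign.value,
            "probability": p,
        }
        for e, p in ranking.scores.items()
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["probability", "target", "regulator", "sign"],
        ascending=[False, True, True, True],
    ).reset_index(drop=True)
    if gold is not None:
        pos = gold.positives
        df["in_gold"] = [
            EdgeModel(t, r, s) in pos
            for t, r, s in zip(df["target"], df["regulator"], df["sign"])
        ]
    return df
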