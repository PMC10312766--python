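"""Detection validation against the simulator truth table."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .voronoi import EvCluster


@dataclass
class DetectionScore:
    n_true: int
    n_detected: int
    n_matched: int
    precision: float
    recall: float

    @property
    def f1(self) -> float:
        if self.precision + self.recall == 0:
            return 0.0
        return 2 * self.precision * self.recall / (self.precision + self.recall)


def score_detection(
    clusters: list[EvCluster],
    truth: pd.DataFrame,
    roi_id: str,
    min_true_loc: int = 1,
    purity: float = 0.5,
) -> DetectionScore:
    """Score detected clusters of one ROI against the truth table.

    A cluster matches a vesicle when at least ``purity`` of its member
    localizations come from that vesicle; precision is the fraction of
    clusters matching some vesicle, recall the fraction of detectable
    vesicles (those with at least ``min_true_loc`` localizations in the
    table) matched by some cluster.
    """
    t = truth[truth["roi_id"] == roi_id]
    ev_of_loc = dict(zip(t["loc_id"], t["ev_id"]))
    true_sizes = t[t["ev_id"] >= 0].groupby("ev_id").size()
    detectable = set(true_sizes[true_sizes >= min_true_loc].index)

    matched_evs: set[int] = set()
    n_matched_clusters = 0
    for cl in clusters:
        sources = pd.Series([ev_of_loc.get(i, -1) for i in cl.member_loc_ids])
        counts = sources[sources >= 0].value_counts()
        if len(counts) and counts.iloc[0] >= purity * len(sources):
            n_matched_clusters += 1
            matched_evs.add(int(counts.index[0]))

    n_true = len(detectable)
    n_det = len(clusters)
    precision = n_matched_clusters / n_det if n_det else 1.0
    recall = len(matched_evs & detectable) / n_true if n_true else 1.0
    return DetectionScore(n_true, n_det, n_matched_clusters, precision, recall)


def pool_scores(scores: list[DetectionScore]) -> DetectionScore:
    """Pool per-ROI scores by total counts (micro-average)."""
    n_true = sum(s.n_true for s in scores)
    n_det = sum(s.n_detected for s in scores)
    n_matched = sum(s.n_matched for s in scores)
    matched_true = sum(round(s.recall * s.n_true) for s in scores)
    return DetectionScore(
        n_true,
        n_det,
        n_matched,
        precision=n_matched / n_det if n_det else 1.0,
        recall=matched_true / n_true if n_true else 1.0,
    )
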