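"""K-nearest-neighbour ancestry assignment with fallback majority voting.

Queries are matched against a labelled reference panel by Euclidean distance
over raw dosages at a chosen marker set (no standardization — rescaling
would silently re-weight markers). The K=5 nearest reference samples vote;
if no strict majority (> half) emerges among 5, the 4 nearest are polled,
then the 3 nearest, and finally the sample is left UNASSIGNED. A prediction
is scored correct when it names the true population or a population whose
pairwise Fst with the truth is below the indistinct threshold; UNASSIGNED is
never correct.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .aims import MarkerRanking
from .io import MISSING, GenotypeDataset

UNASSIGNED = "UNASSIGNED"

#: Vote ladder: poll the 5 nearest, then 4, then 3.
VOTE_LEVELS = (5, 4, 3)


@dataclass
class AssignmentReport:
    """Per-sample predictions plus (after scoring) per-population accuracy."""

    samples: pd.DataFrame          # sample_id, predicted, vote_level, neighbours
    marker_count: int
    k: int
    per_population: pd.DataFrame | None = None  # population, n, n_correct, n_unassigned, accuracy

    @property
    def predicted(self) -> pd.Series:
        return self.samples.set_index("sample_id")["predicted"]

    def overall_accuracy(self) -> float:
        if self.per_population is None:
            raise ValueError("run score_assignments first")
        n = self.per_population["n"].sum()
        return float(self.per_population["n_correct"].sum() / n) if n else float("nan")


def majority_vote(neighbour_labels: Sequence[str]) -> tuple[str, int | None]:
    """Apply the 5 -> 4 -> 3 fallback strict-majority ladder.

    ``neighbour_labels`` must be ordered nearest-first with length >= 3. A
    majority means a label held by strictly more than half of the labels
    polled at that level; the first level that produces one wins.
    """
    labels = list(neighbour_labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 neighbour labels")
    for level in VOTE_LEVELS:
        if level > len(labels):
            continue
        polled = labels[:level]
        label, count = Counter(polled).most_common(1)[0]
        if count * 2 > level:
            return label, level
    return UNASSIGNED, None


def _tiny_panel_vote(labels: Sequence[str]) -> tuple[str, int | None]:
    # Reference smaller than 3: the ladder cannot apply; require a strict
    # majority among whatever neighbours exist.
    label, count = Counter(labels).most_common(1)[0]
    if count * 2 > len(labels):
        return label, len(labels)
    return UNASSIGNED, None


def knn_assign(
    reference: GenotypeDataset,
    query: GenotypeDataset,
    markers: Sequence[str],
    k: int = 5,
) -> AssignmentReport:
    """Assign each query sample by majority vote of its k nearest reference
    samples in raw-dosage space over ``markers``.

    Missing dosages (reference and query alike) are imputed with the
    reference per-marker mean, so assignments do not depend on which other
    queries are in the batch. Exact distance ties are broken by reference
    sample order.
    """
    markers = list(markers)
    if not markers:
        raise ValueError("empty marker set")
    missing_ref = set(markers) - set(reference.snp_ids)
    missing_query = set(markers) - set(query.snp_ids)
    if missing_ref or missing_query:
        raise KeyError(
            f"markers absent from reference {sorted(missing_ref)[:10]} "
            f"or query {sorted(missing_query)[:10]}"
        )
    ref = reference.select_snps(markers)
    qry = query.select_snps(markers)
    r = ref.dosages.astype(float)
    q = qry.dosages.astype(float)
    r_called = ref.dosages != MISSING
    means = np.where(
        r_called.sum(0) > 0,
        np.where(r_called, r, 0.0).sum(0) / np.maximum(r_called.sum(0), 1),
        1.0,
    )
    r = np.where(r_called, r, means[None, :])
    q = np.where(qry.dosages != MISSING, q, means[None, :])
    k_eff = min(k, ref.n_samples)
    if k_eff < k:
        warnings.warn(f"reference has only {ref.n_samples} samples; k truncated to {k_eff}")
    dist = cdist(q, r)
    order = np.argsort(dist, axis=1, kind="stable")  # stable: ties by reference order
    ref_labels = np.asarray(ref.populations)
    rows = []
    for i, sid in enumerate(qry.sample_ids):
        neigh = ref_labels[order[i, :k_eff]].tolist()
        if k_eff >= 3:
            label, level = majority_vote(neigh)
        else:
            label, level = _tiny_panel_vote(neigh)
        rows.append(
            {"sample_id": sid, "predicted": label, "vote_level": level, "neighbours": neigh}
        )
    return AssignmentReport(pd.DataFrame(rows), marker_count=len(markers), k=k)


def score_assignments(
    report: AssignmentReport,
    truth: pd.Series | dict[str, str],
    indistinct_pairs: Iterable[frozenset[str]] = (),
) -> AssignmentReport:
    """Mark predictions correct under the Fst-equivalence rule and attach
    per-population accuracy (populations taken from the truth labels)."""
    truth = pd.Series(truth)
    pairs = {frozenset(p) for p in indistinct_pairs}
    t = report.samples.copy()
    missing = [s for s in t["sample_id"] if s not in truth.index]
    if missing:
        raise KeyError(f"truth labels missing for {missing[:10]}")
    t["truth"] = truth.loc[t["sample_id"]].to_numpy()
    t["correct"] = [
        pred != UNASSIGNED and (pred == tru or frozenset((pred, tru)) in pairs)
        for pred, tru in zip(t["predicted"], t["truth"])
    ]
    per_pop = (
        t.groupby("truth", sort=True)
        .agg(
            n=("sample_id", "size"),
            n_correct=("correct", "sum"),
            n_unassigned=("predicted", lambda s: int((s == UNASSIGNED).sum())),
        )
        .reset_index()
        .rename(columns={"truth": "population"})
    )
    per_pop["accuracy"] = per_pop["n_correct"] / per_pop["n"]
    return AssignmentReport(t, report.marker_count, report.k, per_pop)


DEFAULT_MARKER_COUNTS = (10, 25, 50, 100, 250, 500, 1000)


def accuracy_curve(
    reference: GenotypeDataset,
    query: GenotypeDataset,
    ranking: MarkerRanking,
    marker_counts: Sequence[int] = DEFAULT_MARKER_COUNTS,
    k: int = 5,
    truth: pd.Series | dict[str, str] | None = None,
    indistinct_pairs: Iterable[frozenset[str]] = (),
) -> pd.DataFrame:
    """Assignment accuracy per population for growing prefixes of a ranking.

    Returns a long-format frame (marker_count, population, n, n_correct,
    n_unassigned, accuracy) including an ``OVERALL`` row per marker count.
    Truth defaults to the query's own population labels.
    """
    counts = sorted(set(int(c) for c in marker_counts))
    if not counts or counts[0] < 1:
        raise ValueError("marker_counts must be positive")
    if counts[-1] > len(ranking):
        raise ValueError(f"ranking has only {len(ranking)} markers, {counts[-1]} requested")
    if truth is None:
        truth = pd.Series(query.populations, index=query.sample_ids)
    frames = []
    for c in counts:
        rep = score_assignments(
            knn_assign(reference, query, ranking.top(c), k=k), truth, indistinct_pairs
        )
        pp = rep.per_population.copy()
        overall = pd.DataFrame(
            [{
                "population": "OVERALL",
                "n": pp["n"].sum(),
                "n_correct": pp["n_correct"].sum(),
                "n_unassigned": pp["n_unassigned"].sum(),
                "accuracy": rep.overall_accuracy(),
            }]
        )
        block = pd.concat([pp, overall], ignore_index=True)
        block.insert(0, "marker_count", c)
        frames.append(block)
    return pd.concat(frames, ignore_index=True)
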