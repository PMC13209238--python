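"""Conformational clustering of binding sites and representative selection.

The pairwise site-RMSD matrix is clustered with hierarchical agglomerative
clustering under complete linkage, so the height of every merge equals the
maximum pairwise distance between the merged groups.  Each cluster
contributes one to three representatives: the medoid first, then members
picked greedily by maximum minimum distance to the already-chosen ones.
A docking-fidelity filter can replace representatives that fail to
reproduce the crystallographic pose of their own ligand on re-docking
(pose deviation above a threshold) with the nearest passing neighbour in
the same cluster.  Classical (Torgerson) multidimensional scaling is
provided to project the distance matrix for visualization.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from kinsel.structures import DistanceMatrix

logger = logging.getLogger(__name__)

MEDOID = "medoid"
MAXMIN = "maxmin"
LBI_REPLACEMENT = "lbi-replacement"


@dataclass
class ClusterModel:
    """A flat k-partition of structures cut from a complete-linkage tree."""

    labels: list[str]
    assignments: dict[str, int]
    k: int
    merge_tree: np.ndarray  # scipy linkage matrix

    def members(self, cluster: int) -> list[str]:
        return [l for l in self.labels if self.assignments[l] == cluster]

    def clusters(self) -> list[int]:
        return sorted(set(self.assignments.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"structure_id": self.labels,
             "cluster": [self.assignments[l] for l in self.labels]}
        )


@dataclass
class Representative:
    structure_id: str
    annotation: str  # medoid | maxmin | lbi-replacement
    flagged: bool = False  # kept despite failing docking fidelity


@dataclass
class RepresentativeSet:
    """Ordered representatives per cluster with selection provenance."""

    per_cluster: dict[int, list[Representative]]
    parameters: dict = field(default_factory=dict)

    def all_ids(self) -> list[str]:
        return [r.structure_id for reps in self.per_cluster.values() for r in reps]

    def to_jsonable(self) -> dict:
        return {
            "parameters": self.parameters,
            "clusters": {
                str(c): [
                    {"structure_id": r.structure_id, "annotation": r.annotation,
                     "flagged": r.flagged}
                    for r in reps
                ]
                for c, reps in self.per_cluster.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_jsonable(), indent=2) + "\n")


@dataclass
class LbiRecord:
    """Re-docking fidelity of one conformation.

    ``pose_deviation`` is the heavy-atom deviation (Å) of the re-docked
    crystallographic ligand from its crystal pose; a conformation passes
    when the deviation does not exceed the threshold (default 2.0 Å).
    """

    structure_id: str
    pose_deviation: float
    threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.pose_deviation < 0:
            raise ValueError("pose deviation must be non-negative")

    @property
    def passes(self) -> bool:
        return self.pose_deviation <= self.threshold


def load_lbi_table(path: str | Path, threshold: float = 2.0) -> dict[str, LbiRecord]:
    df = pd.read_csv(path)
    return {
        str(r.structure_id): LbiRecord(str(r.structure_id), float(r.pose_deviation_A), threshold)
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# Clustering


def complete_linkage_cluster(D: DistanceMatrix, k: int) -> ClusterModel:
    """Cut the complete-linkage dendrogram of ``D`` into ``k`` clusters.

    Cluster indices are renumbered 1..k in order of first appearance along
    the label order, so output is independent of scipy's internal ordering.
    """
    D.validate()
    n = len(D.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if n == 1:
        return ClusterModel(list(D.labels), {D.labels[0]: 1}, 1, np.empty((0, 4)))
    Z = linkage(squareform(D.values, checks=False), method="complete")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber deterministically by first appearance
    remap: dict[int, int] = {}
    assignments = {}
    for lab, c in zip(D.labels, raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        assignments[lab] = remap[c]
    return ClusterModel(list(D.labels), assignments, len(remap), Z)


def choose_k(D: DistanceMatrix, k_range: tuple[int, int] = (2, 8)) -> int:
    """Pick k by maximum mean silhouette width over a range of cuts.

    Ties go to the smaller k.  The matrix must have at least k+1 points for
    a silhouette to be defined at k.
    """
    n = len(D.labels)
    best_k, best_s = None, -np.inf
    for k in range(k_range[0], min(k_range[1], n - 1) + 1):
        model = complete_linkage_cluster(D, k)
        lab = np.array([model.assignments[l] for l in D.labels])
        if len(set(lab)) < 2:
            continue
        s = silhouette_score(D.values, lab, metric="precomputed")
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no valid k in range for silhouette selection")
    return best_k


# ---------------------------------------------------------------------------
# Representative selection


def _medoid(members: list[str], index: dict[str, int], values: np.ndarray) -> str:
    sums = {
        m: float(sum(values[index[m], index[o]] for o in members)) for m in members
    }
    best = min(sums.values())
    return min(m for m in members if sums[m] <= best + 1e-12)


def select_representatives(
    D: DistanceMatrix,
    model: ClusterModel,
    population_threshold: float = 0.25,
    dispersion_rule: str = "median",
    cap: int = 3,
) -> RepresentativeSet:
    """Medoid plus max-min diverse extras for every cluster.

    The first representative of a cluster is its medoid (minimum sum of
    within-cluster distances; ties to the lexicographically smallest id).
    A cluster earns one extra representative if it holds at least
    ``population_threshold`` of all structures, and one more if its mean
    within-cluster distance exceeds the across-cluster median of that
    quantity; extras are chosen greedily to maximize their minimum distance
    to already-selected representatives, capped at ``cap`` per cluster.
    """
    index = {l: i for i, l in enumerate(D.labels)}
    n_total = len(model.labels)
    dispersion: dict[int, float] = {}
    for c in model.clusters():
        members = model.members(c)
        if not members:
            raise ValueError(f"cluster {c} is empty")
        if len(members) == 1:
            dispersion[c] = 0.0
        else:
            vals = [
                D.values[index[a], index[b]]
                for i, a in enumerate(members)
                for b in members[i + 1:]
            ]
            dispersion[c] = float(np.mean(vals))
    median_disp = float(np.median(list(dispersion.values())))

    per_cluster: dict[int, list[Representative]] = {}
    for c in model.clusters():
        members = model.members(c)
        want = 1
        if len(members) >= population_threshold * n_total:
            want += 1
        if dispersion[c] > median_disp:
            want += 1
        want = min(want, cap, len(members))
        chosen = [_medoid(members, index, D.values)]
        while len(chosen) < want:
            remaining = [m for m in members if m not in chosen]
            # max-min distance to current picks; ties to smallest id
            def min_dist(m: str) -> float:
                return min(D.values[index[m], index[s]] for s in chosen)
            best = max(min_dist(m) for m in remaining)
            chosen.append(min(m for m in remaining if min_dist(m) >= best - 1e-12))
        per_cluster[c] = [
            Representative(s, MEDOID if i == 0 else MAXMIN)
            for i, s in enumerate(chosen)
        ]
    return RepresentativeSet(
        per_cluster,
        parameters={
            "population_threshold": population_threshold,
            "dispersion_rule": dispersion_rule,
            "median_dispersion": median_disp,
            "cap": cap,
        },
    )


def apply_lbi_filter(
    reps: RepresentativeSet,
    lbi: dict[str, LbiRecord],
    D: DistanceMatrix,
    model: ClusterModel,
) -> RepresentativeSet:
    """Replace representatives with poor re-docking fidelity.

    A failing representative is swapped for the nearest same-cluster
    structure (by the site-RMSD matrix) that passes and is not already
    selected; if the whole cluster fails, the original is kept and flagged.
    """
    index = {l: i for i, l in enumerate(D.labels)}
    out: dict[int, list[Representative]] = {}
    for c, cluster_reps in reps.per_cluster.items():
        selected = [r.structure_id for r in cluster_reps]
        new_reps: list[Representative] = []
        for r in cluster_reps:
            rec = lbi.get(r.structure_id)
            if rec is None:
                raise ValueError(f"no docking-fidelity record for {r.structure_id}")
            if rec.passes:
                new_reps.append(Representative(r.structure_id, r.annotation))
                continue
            candidates = [
                m
                for m in model.members(c)
                if m not in selected
                and m in lbi
                and lbi[m].passes
            ]
            if not candidates:
                logger.warning(
                    "cluster %s: every member fails docking fidelity; keeping %s",
                    c, r.structure_id,
                )
                new_reps.append(Representative(r.structure_id, r.annotation, flagged=True))
                continue
            d = {m: D.values[index[r.structure_id], index[m]] for m in candidates}
            best = min(d.values())
            chosen = min(m for m in candidates if d[m] <= best + 1e-12)
            selected[selected.index(r.structure_id)] = chosen
            new_reps.append(Representative(chosen, LBI_REPLACEMENT))
        out[c] = new_reps
    params = dict(reps.parameters)
    params["lbi_threshold"] = next(iter(lbi.values())).threshold if lbi else None
    return RepresentativeSet(out, params)


# ---------------------------------------------------------------------------
# Classical MDS


def mds_project(D: DistanceMatrix, dims: int = 3) -> pd.DataFrame:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the
    top ``dims`` coordinates ordered by eigenvalue.  If fewer than ``dims``
    positive eigenvalues exist the remaining coordinates are zero-padded
    with a warning.
    """
    n = len(D.labels)
    if not 1 <= dims <= n - 1:
        raise ValueError(f"dims must be in [1, {n - 1}]")
    d2 = D.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, dims))
    n_pos = int(np.sum(evals > 1e-10))
    use = min(dims, n_pos)
    if use < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding {dims - use} "
            "MDS coordinates with zeros",
            stacklevel=2,
        )
    coords[:, :use] = evecs[:, :use] * np.sqrt(evals[:use])
    return pd.DataFrame(
        coords, index=pd.Index(D.labels, name="structure_id"),
        columns=[f"mds{i + 1}" for i in range(dims)],
    )
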