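"""Activity classification and virtual-screening performance metrics.

Ligands are labelled from assay data: active at pChEMBL > 7 or a standard
value ≤ 100 nM, inactive at pChEMBL ≤ 5.5 or ≥ 10 µM, unknown in between
(the curated pChEMBL wins when the two sources disagree).  Per receptor
conformation and score component the module computes global discrimination
(ROC AUC, midrank tie convention), early-recognition metrics (exponential
ROC enrichment and enrichment factors), and confusion-matrix statistics at
top-ranked cutoffs; conformers are then prioritized by a combined
AUC + early-enrichment rule.  Lower scores are better throughout, the
docking convention.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

ACTIVE = "active"
INACTIVE = "inactive"
UNKNOWN = "unknown"

#: top-ranked cutoff fractions evaluated by default (0.2% … 10%)
DEFAULT_FRACTIONS = (0.002, 0.005, 0.01, 0.02, 0.05, 0.10)

ACTIVE_PCHEMBL_GT = 7.0
ACTIVE_NM_LE = 100.0
INACTIVE_PCHEMBL_LE = 5.5
INACTIVE_NM_GE = 10_000.0


def classify_activity(
    pchembl: float | None = None, standard_value_nm: float | None = None
) -> str:
    """Label a ligand active/inactive/unknown from pChEMBL and/or nM value.

    Active: pChEMBL > 7 or standard value ≤ 100 nM.  Inactive: pChEMBL
    ≤ 5.5 or standard value ≥ 10 µM.  When the two sources give opposite
    decisive labels, the curated pChEMBL value wins and the conflict is
    logged.
    """
    if pchembl is None and standard_value_nm is None:
        raise ValueError("at least one of pchembl or standard_value_nm is required")

    def from_pchembl(p: float) -> str:
        if p > ACTIVE_PCHEMBL_GT:
            return ACTIVE
        if p <= INACTIVE_PCHEMBL_LE:
            return INACTIVE
        return UNKNOWN

    def from_value(v: float) -> str:
        if v <= ACTIVE_NM_LE:
            return ACTIVE
        if v >= INACTIVE_NM_GE:
            return INACTIVE
        return UNKNOWN

    lp = from_pchembl(pchembl) if pchembl is not None else None
    lv = from_value(standard_value_nm) if standard_value_nm is not None else None
    if lp is not None and lv is not None and UNKNOWN not in (lp, lv) and lp != lv:
        logger.warning(
            "conflicting activity labels (pChEMBL=%s -> %s, value=%s nM -> %s); "
            "pChEMBL takes precedence", pchembl, lp, standard_value_nm, lv,
        )
        return lp
    for lab in (lp, lv):
        if lab in (ACTIVE, INACTIVE):
            return lab
    return UNKNOWN


def classify_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``label`` column to an activity table.

    Expects columns ``ligand_id`` and at least one of ``pchembl`` /
    ``standard_value_nM``.
    """
    out = df.copy()
    labels = []
    for row in out.itertuples():
        p = getattr(row, "pchembl", None)
        v = getattr(row, "standard_value_nM", None)
        p = None if p is None or (isinstance(p, float) and math.isnan(p)) else float(p)
        v = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        labels.append(classify_activity(p, v))
    out["label"] = labels
    return out


# ---------------------------------------------------------------------------
# Score tables


def best_poses(scores: pd.DataFrame) -> pd.DataFrame:
    """Reduce a multi-pose score table to one best pose per (ligand, conformer, kinase).

    The best pose is the one with the minimum ``total`` score; all component
    columns of that same pose are kept (pose selection is by total, never
    per-component).
    """
    required = {"ligand_id", "conformer_id", "kinase_id", "total"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    idx = scores.groupby(
        ["ligand_id", "conformer_id", "kinase_id"], sort=False
    )["total"].idxmin()
    return scores.loc[idx].reset_index(drop=True)


def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    is_active = labels == ACTIVE
    is_inactive = labels == INACTIVE
    if not is_active.any() or not is_inactive.any():
        raise ValueError("need at least one active and one inactive ligand")
    return is_active, is_inactive


# ---------------------------------------------------------------------------
# Metrics


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC for a lower-is-better score vector.

    Equals the probability that a randomly chosen active outranks a
    randomly chosen inactive, with ties counting one half (midrank /
    Mann–Whitney convention).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    act, inact = _check_classes(labels)
    ranks = rankdata(scores)  # ascending: best (lowest) score gets rank 1
    n_a, n_i = int(act.sum()), int(inact.sum())
    # pairs where the active scores worse than the inactive (+ half-ties)
    u_worse = ranks[act].sum() - n_a * (n_a + 1) / 2.0
    return float((n_a * n_i - u_worse) / (n_a * n_i))


def eroce(scores: np.ndarray, labels: np.ndarray, alpha: float = 20.0) -> float:
    """Exponential ROC enrichment: mean over actives of exp(−α·FPR).

    FPR of an active is the fraction of inactives ranked strictly ahead of
    it, ties counting one half.  Actives retrieved early (low FPR) dominate
    the average, so the metric emphasizes the top of the ranked list; the
    default α = 20 weighs the first few percent of the list most, comparable
    in emphasis to BEDROC at the same α.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    act, inact = _check_classes(labels)
    s_act = scores[act]
    s_inact = scores[inact]
    n_i = len(s_inact)
    ahead = (s_inact[None, :] < s_act[:, None]).sum(axis=1)
    tied = (s_inact[None, :] == s_act[:, None]).sum(axis=1)
    fpr = (ahead + 0.5 * tied) / n_i
    return float(np.mean(np.exp(-alpha * fpr)))


def _top_mask(scores: np.ndarray, n_top: int) -> np.ndarray:
    """Boolean mask of the ``n_top`` best (lowest) scores, stable tie-break."""
    order = np.argsort(scores, kind="stable")
    mask = np.zeros(len(scores), dtype=bool)
    mask[order[:n_top]] = True
    return mask


def enrichment_factor(
    scores: np.ndarray, labels: np.ndarray, fraction: float
) -> float:
    """Enrichment factor at a top fraction of the ranked list.

    EF(f) = (actives in the top ceil(f·N) / ceil(f·N)) ÷ (total actives / N).
    Ties at the boundary are resolved by stable input order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    act, _ = _check_classes(labels)
    n = len(scores)
    n_top = math.ceil(fraction * n)
    top = _top_mask(scores, n_top)
    hit = int((top & act).sum())
    return (hit / n_top) / (int(act.sum()) / n)


@dataclass
class CutoffMetrics:
    fraction: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {
            "fraction": self.fraction, "tp": self.tp, "fp": self.fp,
            "fn": self.fn, "tn": self.tn, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
        }


def cutoff_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
) -> dict[float, CutoffMetrics]:
    """Confusion counts at each top-ranked cutoff fraction.

    "Predicted positive" is membership in the top ceil(f·N) of the ranked
    list; unknown-labelled ligands must be excluded beforehand.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    act, inact = _check_classes(labels)
    n = len(scores)
    out = {}
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError("fraction must be in (0, 1]")
        n_top = math.ceil(f * n)
        top = _top_mask(scores, n_top)
        tp = int((top & act).sum())
        fp = int((top & inact).sum())
        fn = int((~top & act).sum())
        tn = int((~top & inact).sum())
        out[f] = CutoffMetrics(f, tp, fp, fn, tn)
    return out


@dataclass
class MetricsReport:
    """Screening metrics for one (conformer, score component) pair."""

    conformer_id: str
    component: str
    auc: float
    eroce: float
    ef: dict[float, float]
    cutoffs: dict[float, CutoffMetrics]
    alpha: float = 20.0
    n_ligands: int = 0
    n_actives: int = 0

    def as_dict(self) -> dict:
        return {
            "conformer_id": self.conformer_id,
            "component": self.component,
            "auc": self.auc,
            "eroce": self.eroce,
            "alpha": self.alpha,
            "n_ligands": self.n_ligands,
            "n_actives": self.n_actives,
            "ef": {str(k): v for k, v in self.ef.items()},
            "cutoffs": {str(k): c.as_dict() for k, c in self.cutoffs.items()},
        }


def evaluate_conformer(
    scores: np.ndarray,
    labels: np.ndarray,
    conformer_id: str = "",
    component: str = "total",
    alpha: float = 20.0,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    ef_fractions: tuple[float, ...] = (0.01,),
) -> MetricsReport:
    """Full metrics report for one conformer and score component."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    act, _ = _check_classes(labels)
    return MetricsReport(
        conformer_id=conformer_id,
        component=component,
        auc=roc_auc(scores, labels),
        eroce=eroce(scores, labels, alpha),
        ef={f: enrichment_factor(scores, labels, f) for f in ef_fractions},
        cutoffs=cutoff_metrics(scores, labels, fractions),
        alpha=alpha,
        n_ligands=len(scores),
        n_actives=int(act.sum()),
    )


def evaluate_screen(
    table: pd.DataFrame,
    components: tuple[str, ...] = ("total",),
    alpha: float = 20.0,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    ef_fractions: tuple[float, ...] = (0.01,),
) -> list[MetricsReport]:
    """Per-conformer, per-component metrics for one kinase's score table.

    ``table`` holds one best-pose row per (ligand, conformer) with a
    ``label`` column; unknown-labelled ligands are dropped.
    """
    df = table[table["label"].isin([ACTIVE, INACTIVE])]
    reports = []
    for conf, grp in df.groupby("conformer_id", sort=True):
        for comp in components:
            reports.append(
                evaluate_conformer(
                    grp[comp].to_numpy(), grp["label"].to_numpy(),
                    conformer_id=str(conf), component=comp, alpha=alpha,
                    fractions=fractions, ef_fractions=ef_fractions,
                )
            )
    return reports


def aggregate_conformers(reports: list[MetricsReport]) -> dict:
    """Pool confusion counts across conformers and recompute P/R/F1.

    All reports must share the same cutoff grid.  Returns the pooled
    per-cutoff statistics together with the per-conformer metric table.
    """
    if not reports:
        raise ValueError("need at least one report")
    grids = {tuple(sorted(r.cutoffs)) for r in reports}
    if len(grids) > 1:
        raise ValueError("reports have mixed cutoff grids; cannot aggregate")
    pooled = {}
    for f in sorted(next(iter(grids))):
        tp = sum(r.cutoffs[f].tp for r in reports)
        fp = sum(r.cutoffs[f].fp for r in reports)
        fn = sum(r.cutoffs[f].fn for r in reports)
        tn = sum(r.cutoffs[f].tn for r in reports)
        pooled[f] = CutoffMetrics(f, tp, fp, fn, tn)
    per_conformer = pd.DataFrame(
        [
            {
                "conformer_id": r.conformer_id, "component": r.component,
                "auc": r.auc, "eroce": r.eroce,
                **{f"ef_{f}": v for f, v in r.ef.items()},
            }
            for r in reports
        ]
    )
    return {"pooled_cutoffs": pooled, "per_conformer": per_conformer}


def select_conformers(
    reports: list[MetricsReport],
    auc_min: float = 0.70,
    ef_fraction: float = 0.01,
) -> list[str]:
    """Prioritize conformers by combined global and early-recognition rule.

    A conformer is retained when its AUC is at least ``auc_min`` and it
    shows strong early enrichment, operationalized as both eROCE and
    EF(``ef_fraction``) at or above the ensemble median of the respective
    metric.  Returns sorted conformer ids.
    """
    if not reports:
        raise ValueError("need at least one report")
    med_eroce = float(np.median([r.eroce for r in reports]))
    med_ef = float(np.median([r.ef[ef_fraction] for r in reports]))
    keep = [
        r.conformer_id
        for r in reports
        if r.auc >= auc_min and r.eroce >= med_eroce and r.ef[ef_fraction] >= med_ef
    ]
    return sorted(set(keep))


def write_reports(reports: list[MetricsReport], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.as_dict() for r in reports], indent=2) + "\n"
    )


def read_reports(path: str | Path) -> list[MetricsReport]:
    data = json.loads(Path(path).read_text())
    reports = []
    for d in data:
        cutoffs = {
            float(f): CutoffMetrics(float(f), c["tp"], c["fp"], c["fn"], c["tn"])
            for f, c in d["cutoffs"].items()
        }
        reports.append(
            MetricsReport(
                conformer_id=d["conformer_id"], component=d["component"],
                auc=d["auc"], eroce=d["eroce"],
                ef={float(f): v for f, v in d["ef"].items()},
                cutoffs=cutoffs, alpha=d["alpha"],
                n_ligands=d["n_ligands"], n_actives=d["n_actives"],
            )
        )
    return reports


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """TPR/FPR points of the ROC curve for external plotting."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    act, inact = _check_classes(labels)
    order = np.argsort(scores, kind="stable")
    tp = np.cumsum(act[order])
    fp = np.cumsum(inact[order])
    return pd.DataFrame(
        {
            "threshold": scores[order],
            "tpr": tp / act.sum(),
            "fpr": fp / inact.sum(),
        }
    )
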