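"""Relative-rank selectivity scoring between two kinase isoforms.

For each kinase, per-ligand consensus docking scores over the selected
receptor conformations are converted to normalized ranks in (0, 1]
(raw rank position divided by the number of ligands, midranks for ties,
rank 1 = best score).  The relative rank of a ligand is

    RR = R_A − R_B,

the difference of its normalized ranks against kinase A and kinase B;
negative RR means the ligand ranks preferentially for kinase A.  The
module also quantifies cross-kinase rank concordance (Spearman ρ,
tie-corrected Kendall τ-b, and the distribution of percentile
differences), runs paired Wilcoxon tests on score components with a
Bonferroni-adjusted α, filters an externally screened library down to
kinase-A-enriched hits, and evaluates Lipinski/Veber/Ghose drug-likeness
rules on supplied descriptors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

MEAN_RANK = "mean-rank"
BEST_RANK = "best-rank"


# ---------------------------------------------------------------------------
# Rank normalization and RR


def normalize_ranks(
    table: pd.DataFrame,
    conformers: list[str] | None = None,
    consensus: str = MEAN_RANK,
    component: str = "total",
) -> pd.Series:
    """Per-ligand normalized consensus rank for one kinase.

    ``table`` holds one best-pose row per (ligand, conformer).  Scores are
    ranked within each conformer (midranks, lower score = rank 1) and
    normalized by the ligand count; the consensus across conformers is the
    mean of those per-conformer normalized ranks (default) or the best
    (minimum) one.  The consensus values are then re-ranked so the result
    is itself a normalized rank in (0, 1].
    """
    if conformers is not None:
        if not conformers:
            raise ValueError("empty conformer selection")
        table = table[table["conformer_id"].isin(conformers)]
        if table.empty:
            raise ValueError("no rows left after conformer selection")
    per_conf = []
    for _, grp in table.groupby("conformer_id", sort=True):
        r = pd.Series(
            rankdata(grp[component].to_numpy()) / len(grp),
            index=grp["ligand_id"].to_numpy(),
        )
        per_conf.append(r)
    wide = pd.concat(per_conf, axis=1)
    if consensus == MEAN_RANK:
        cons = wide.mean(axis=1)
    elif consensus == BEST_RANK:
        cons = wide.min(axis=1)
    else:
        raise ValueError(f"unknown consensus rule: {consensus}")
    cons = cons.sort_index()
    final = pd.Series(
        rankdata(cons.to_numpy()) / len(cons), index=cons.index, name="normalized_rank"
    )
    final.index.name = "ligand_id"
    return final


def relative_rank(r_a: float, r_b: float) -> float:
    """RR = R_A − R_B for one ligand; negative favours kinase A."""
    for v in (r_a, r_b):
        if not 0 < v <= 1:
            raise ValueError(f"normalized ranks must be in (0, 1], got {v}")
    return r_a - r_b


def selectivity_table(rank_a: pd.Series, rank_b: pd.Series) -> pd.DataFrame:
    """Per-ligand RR over the ligands shared by the two rank tables."""
    shared = rank_a.index.intersection(rank_b.index).sort_values()
    df = pd.DataFrame(
        {
            "ligand_id": shared,
            "R_A": rank_a.loc[shared].to_numpy(),
            "R_B": rank_b.loc[shared].to_numpy(),
        }
    )
    df["rr"] = df["R_A"] - df["R_B"]
    return df


# ---------------------------------------------------------------------------
# Concordance


@dataclass
class ConcordanceReport:
    spearman_rho: float
    spearman_p: float
    kendall_tau: float
    kendall_p: float
    n: int
    delta_mean: float
    delta_sd: float
    delta_skew: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def concordance(rank_a: pd.Series, rank_b: pd.Series) -> ConcordanceReport:
    """Cross-kinase rank agreement on shared ligands.

    Spearman ρ and tie-corrected Kendall τ-b with large-sample p-values,
    plus summary statistics of the percentile-difference distribution
    Δ = R_B − R_A.
    """
    shared = rank_a.index.intersection(rank_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared ligands for concordance")
    a = rank_a.loc[shared].to_numpy()
    b = rank_b.loc[shared].to_numpy()
    rho, rho_p = stats.spearmanr(a, b)
    tau, tau_p = stats.kendalltau(a, b, variant="b")
    delta = b - a
    return ConcordanceReport(
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        kendall_tau=float(tau),
        kendall_p=float(tau_p),
        n=len(shared),
        delta_mean=float(np.mean(delta)),
        delta_sd=float(np.std(delta, ddof=1)),
        delta_skew=float(stats.skew(delta, bias=False)) if len(shared) > 2 else 0.0,
    )


# ---------------------------------------------------------------------------
# Paired component test


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    adjusted_alpha: float
    significant: bool
    n_pairs: int
    method: str


def paired_component_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    m_comparisons: int = 2,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired score components with Bonferroni.

    Zero differences are dropped (Wilcoxon's original convention) and at
    least 5 informative pairs are required.  The exact null distribution is
    used for n ≤ 25, otherwise the normal approximation with continuity
    correction.  Significance is judged against the Bonferroni-adjusted
    level α/m.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = a - b
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        raise ValueError("degenerate pairs: all differences are zero")
    if len(diffs) < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    method = "exact" if len(diffs) <= 25 else "approx"
    res = stats.wilcoxon(
        diffs, alternative=alternative, method=method, correction=(method == "approx")
    )
    adjusted = alpha / m_comparisons
    return PairedTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        adjusted_alpha=adjusted,
        significant=bool(res.pvalue < adjusted),
        n_pairs=len(diffs),
        method=method,
    )


# ---------------------------------------------------------------------------
# Hit prioritization


def prioritize_hits(
    rank_a: pd.Series,
    rank_b: pd.Series,
    top_fraction: float = 0.05,
    rr_cutoff: float = 0.0,
    separation_margin: float = 0.05,
    descriptors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Filter a screened library down to kinase-A-enriched candidates.

    Both kinases must be scored on the same library.  The kinase-A top
    ``top_fraction`` of the library is retained (ceil(f·N) ligands), then
    ligands with RR above ``rr_cutoff`` are dropped (they do not rank
    preferentially for kinase A), then ligands with |RR| below
    ``separation_margin`` are dropped as lacking substantial rank
    separation.  Hits are ordered by RR ascending, then kinase-A rank, then
    ligand id; filter provenance is attached as DataFrame attrs.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if set(rank_a.index) != set(rank_b.index):
        raise ValueError("kinase A and kinase B were scored on different libraries")
    n = len(rank_a)
    n_top = math.ceil(top_fraction * n)
    df = selectivity_table(rank_a, rank_b)
    df = df.sort_values(["R_A", "ligand_id"], kind="stable").head(n_top)
    df = df[df["rr"] <= rr_cutoff]
    df = df[df["rr"].abs() >= separation_margin]
    df = df.sort_values(["rr", "R_A", "ligand_id"], kind="stable").reset_index(drop=True)
    if descriptors is not None:
        flags = drug_likeness_flags(descriptors.set_index("ligand_id"))
        df = df.merge(flags, left_on="ligand_id", right_index=True, how="left")
    df.attrs["provenance"] = {
        "top_fraction": top_fraction,
        "n_library": n,
        "n_top": n_top,
        "rr_cutoff": rr_cutoff,
        "separation_margin": separation_margin,
    }
    return df


# ---------------------------------------------------------------------------
# Drug-likeness rules


def _lipinski(row: pd.Series):
    needed = ["MW", "logP", "HBD", "HBA"]
    if row[needed].isna().any():
        return pd.NA, pd.NA
    violations = sum(
        int(v)
        for v in (row["MW"] > 500, row["logP"] > 5, row["HBD"] > 5, row["HBA"] > 10)
    )
    return violations, violations <= 1


def _veber(row: pd.Series):
    if row[["RotB", "TPSA"]].isna().any():
        return pd.NA
    return bool(row["RotB"] <= 10 and row["TPSA"] <= 140)


def _ghose(row: pd.Series):
    needed = ["MW", "logP", "MR", "heavy_atoms"]
    if row[needed].isna().any():
        return pd.NA
    return bool(
        160 <= row["MW"] <= 480
        and -0.4 <= row["logP"] <= 5.6
        and 40 <= row["MR"] <= 130
        and 20 <= row["heavy_atoms"] <= 70
    )


def drug_likeness_flags(descriptors: pd.DataFrame) -> pd.DataFrame:
    """Lipinski / Veber / Ghose rule flags from supplied descriptor columns.

    Expected columns: MW, logP, HBD, HBA, RotB, TPSA, MR, heavy_atoms.
    A missing descriptor makes the affected flag indeterminate (NA), never
    a failure.  Descriptors are inputs, not computed from structures.
    """
    cols = ["MW", "logP", "HBD", "HBA", "RotB", "TPSA", "MR", "heavy_atoms"]
    df = descriptors.reindex(columns=cols)
    out = pd.DataFrame(index=df.index)
    lip = df.apply(_lipinski, axis=1, result_type="expand")
    out["lipinski_violations"] = lip[0]
    out["lipinski_pass"] = lip[1]
    out["veber_pass"] = df.apply(_veber, axis=1)
    out["ghose_pass"] = df.apply(_ghose, axis=1)
    return out
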