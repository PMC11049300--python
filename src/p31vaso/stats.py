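"""Group statistics for voxel-wise Mg/pH biomarkers.

Quality-passing voxel measurements are aggregated to one value per
patient and marker in three anatomical scopes — *cumulative* (all
voxels), *affected side* (only the hemisphere of the ruptured
aneurysm) and *affected territory* (only the arterial territory it
supplies) — and the vasospasm and non-vasospasm groups are compared
with nonparametric tests:

* two independent groups: exact Mann-Whitney rank-sum when the sample
  is small and tie-free, otherwise the tie-corrected normal
  approximation;
* more than two groups (e.g. Hunt & Hess strata): Kruskal-Wallis with
  Dunn's post-hoc pairwise z-tests, Holm-adjusted by default;
* discriminative value: ROC analysis with the cutoff at the greatest
  Youden J, with the positive direction fixed a priori per marker
  (vasospasm is hypothesised to show *lower* Mg and *higher* pH).

The default comparison unit is the patient mean, not the pooled voxel,
to avoid pseudo-replication across the many voxels of one brain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PatientRecord",
    "AggregateScope",
    "StatsConfig",
    "RankSumResult",
    "KruskalDunnResult",
    "RocResult",
    "aggregate",
    "rank_sum_test",
    "kruskal_dunn",
    "roc_youden",
    "run_analysis",
]

GROUPS = ("vasospasm", "control")
LOCATIONS = ("ICA", "MCA", "AComm", "ACA", "PComm")
TREATMENTS = ("clipping", "coiling")
SIDES = ("left", "right", "midline")
SCOPES = ("cumulative", "affected_side", "affected_territory")

#: marker name -> (measurement column, ROC positive direction)
MARKERS = {
    "Mg": ("mg_mM", "lower_is_positive"),
    "pH": ("ph", "higher_is_positive"),
}


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates of one patient."""

    patient_id: str
    group: str
    aneurysm_location: str
    hunt_hess: int
    treatment: str
    affected_side: str
    affected_territory: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.aneurysm_location not in LOCATIONS:
            raise ValueError(f"aneurysm_location must be one of {LOCATIONS}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        if self.affected_side not in SIDES:
            raise ValueError(f"affected_side must be one of {SIDES}")
        if not (isinstance(self.hunt_hess, (int, np.integer)) and 1 <= self.hunt_hess <= 5):
            raise ValueError("hunt_hess must be an integer in [1, 5]")


@dataclass(frozen=True)
class AggregateScope:
    """Which voxels enter a patient's summary value."""

    scope: str = "cumulative"
    unit: str = "patient_mean"  # or "voxel_pool"

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")
        if self.unit not in ("patient_mean", "voxel_pool"):
            raise ValueError("unit must be 'patient_mean' or 'voxel_pool'")


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    adjustment: str = "holm"  # dunn post-hoc: none | holm | bonferroni
    aggregation_unit: str = "patient_mean"
    scopes: tuple[str, ...] = SCOPES
    location_subgroup: tuple[str, ...] = ("AComm", "ACA")
    min_voxels_per_hemisphere: int = 4


# -- aggregation ------------------------------------------------------------

_VALUE_COLS = ("mg_mM", "ph", "pmg")


def aggregate(
    measurements: pd.DataFrame,
    manifest: pd.DataFrame,
    scope: AggregateScope | str = "cumulative",
    min_voxels_per_hemisphere: int = 4,
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-patient marker table for one anatomical scope.

    Only quality-passing voxels enter.  Returns ``(table, exclusions)``
    where ``table`` has one row per patient (or per voxel in
    ``voxel_pool`` mode) with the clinical covariates and the mean
    marker values, and ``exclusions`` records every patient dropped
    (empty voxel selection, or no lateralised side in the
    affected-side scope) with the reason.  Patients retained with fewer
    than ``min_voxels_per_hemisphere`` passing voxels in a required
    hemisphere are flagged ``insufficient_voxels``, never silently
    imputed.
    """
    if isinstance(scope, str):
        scope = AggregateScope(scope)
    patient_cols = [
        "patient_id", "group", "aneurysm_location", "hunt_hess",
        "treatment", "affected_side", "affected_territory",
    ]
    meas_cols = ["voxel_id", "quality_pass", *(c for c in _VALUE_COLS if c in measurements)]
    merged = manifest.merge(measurements[meas_cols], on="voxel_id", validate="1:1")
    merged = merged[merged.quality_pass.astype(bool)]

    exclusions: list[dict] = []
    rows: list[dict] = []
    pooled: list[pd.DataFrame] = []
    for patient_id, sub in merged.groupby("patient_id", sort=True):
        meta = sub.iloc[0]
        if scope.scope == "affected_side":
            if meta.affected_side == "midline":
                exclusions.append(
                    {"patient_id": patient_id, "reason": "affected side is midline"}
                )
                continue
            sel = sub[sub.hemisphere == meta.affected_side]
            required_hemis = (meta.affected_side,)
        elif scope.scope == "affected_territory":
            # the territory of a lateral artery is one-sided: restrict to
            # the affected hemisphere unless the aneurysm is midline
            sel = sub[sub.territory == meta.affected_territory]
            if meta.affected_side in ("left", "right"):
                sel = sel[sel.hemisphere == meta.affected_side]
                required_hemis = (meta.affected_side,)
            else:
                required_hemis = ("left", "right")
        else:
            sel = sub
            required_hemis = ("left", "right")
        if sel.empty:
            exclusions.append(
                {"patient_id": patient_id, "reason": f"no passing voxels in scope {scope.scope}"}
            )
            continue
        counts = sel.hemisphere.value_counts()
        insufficient = any(
            counts.get(h, 0) < min_voxels_per_hemisphere for h in required_hemis
        )
        if scope.unit == "voxel_pool":
            keep = sel[patient_cols + ["voxel_id", *(c for c in _VALUE_COLS if c in sel)]].copy()
            keep["insufficient_voxels"] = insufficient
            pooled.append(keep)
            continue
        row = {c: meta[c] for c in patient_cols}
        row["n_voxels"] = int(len(sel))
        row["insufficient_voxels"] = insufficient
        for c in _VALUE_COLS:
            if c in sel:
                row[c] = float(sel[c].mean())
        rows.append(row)

    table = pd.concat(pooled, ignore_index=True) if scope.unit == "voxel_pool" else pd.DataFrame(rows)
    return table, exclusions


# -- two-group rank test ----------------------------------------------------


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    method: str
    note: str = ""


def rank_sum_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two-sided",
) -> RankSumResult:
    """Mann-Whitney rank-sum comparison of two independent samples.

    Exact permutation null when the combined sample has at most 20
    tie-free observations, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0.0:
        return RankSumResult(
            statistic=a.size * b.size / 2.0,
            p_value=1.0,
            method="degenerate",
            note="all values identical across both groups",
        )
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue), method)


# -- Kruskal-Wallis + Dunn --------------------------------------------------


@dataclass(frozen=True)
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj
    note: str = ""


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]],
    adjustment: str = "holm",
) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test with Dunn's pairwise post-hoc z-tests.

    The omnibus H is tie-corrected; Dunn z-statistics compare mean
    pooled ranks with the usual tie-corrected variance.  Pairwise
    p-values are multiplicity-adjusted per ``adjustment`` (``none``,
    ``holm`` or ``bonferroni``).
    """
    if adjustment not in ("none", "holm", "bonferroni"):
        raise ValueError("adjustment must be none, holm or bonferroni")
    empty = [name for name, vals in groups.items() if len(vals) == 0]
    if empty:
        raise ValueError(f"empty groups: {empty}")
    if len(groups) < 3:
        raise ValueError("the omnibus test requires at least 3 groups")

    names = list(groups)
    samples = [np.asarray(groups[name], float) for name in names]
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0.0:
        return KruskalDunnResult(0.0, 1.0, _degenerate_dunn_frame(names),
                                 note="all values identical")

    h, p = sps.kruskal(*samples)

    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    sizes = [s.size for s in samples]
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start : start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    records = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var) if var > 0 else 0.0
            p_raw = 2.0 * sps.norm.sf(abs(z))
            records.append((names[i], names[j], z, min(p_raw, 1.0)))
    pairwise = pd.DataFrame(records, columns=["group_a", "group_b", "z", "p_raw"])
    if adjustment == "none":
        pairwise["p_adj"] = pairwise.p_raw
    else:
        pairwise["p_adj"] = multipletests(pairwise.p_raw, method=adjustment)[1]
    return KruskalDunnResult(float(h), float(p), pairwise)


def _degenerate_dunn_frame(names):
    records = [
        (names[i], names[j], 0.0, 1.0, 1.0)
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
    return pd.DataFrame(records, columns=["group_a", "group_b", "z", "p_raw", "p_adj"])


# -- ROC / Youden -----------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    auc: float
    youden_cutoff: float
    sensitivity: float
    specificity: float
    j: float
    direction: str
    thresholds: tuple[float, ...]
    curve_sensitivity: tuple[float, ...]
    curve_specificity: tuple[float, ...]


def roc_youden(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: str = "higher_is_positive",
) -> RocResult:
    """ROC analysis with the optimal cutoff at the greatest Youden J.

    ``direction`` fixes which tail of the score is called positive
    (it is *not* auto-flipped to force AUC >= 0.5: the hypothesis
    direction is set a priori per marker).  The AUC is the concordant-
    pair proportion with half credit for ties, i.e. the Mann-Whitney
    U identity; the cutoff maximizes J = sensitivity + specificity - 1
    over all observed score thresholds, ties broken toward the lowest
    threshold on the original score scale.
    """
    if direction not in ("higher_is_positive", "lower_is_positive"):
        raise ValueError("direction must be higher_is_positive or lower_is_positive")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    oriented = scores if direction == "higher_is_positive" else -scores
    ranks = sps.rankdata(oriented)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.unique(oriented)
    sens = np.array([(oriented[labels] >= t).mean() for t in thresholds])
    spec = np.array([(oriented[~labels] < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    original = thresholds if direction == "higher_is_positive" else -thresholds
    best = candidates[np.argmin(original[candidates])]
    return RocResult(
        auc=float(auc),
        youden_cutoff=float(original[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        j=float(j[best]),
        direction=direction,
        thresholds=tuple(float(v) for v in original),
        curve_sensitivity=tuple(float(v) for v in sens),
        curve_specificity=tuple(float(v) for v in spec),
    )


# -- full analysis ----------------------------------------------------------


def _summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75]) if values.size else (math.nan,) * 3
    return {
        "n": int(values.size),
        "median": float(med),
        "iqr": [float(q1), float(q3)],
    }


def _two_group_block(table: pd.DataFrame, column: str, by: str, level_a: str, level_b: str) -> dict:
    if len(table) == 0 or by not in table.columns:
        return {"note": "no patients in scope"}
    a = table.loc[table[by] == level_a, column].to_numpy(float)
    b = table.loc[table[by] == level_b, column].to_numpy(float)
    if a.size == 0 or b.size == 0:
        return {"note": f"degenerate: one of {level_a!r}/{level_b!r} is empty"}
    res = rank_sum_test(a, b)
    return {
        "test": "rank-sum",
        "method": res.method,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "note": res.note,
        level_a: _summary(a),
        level_b: _summary(b),
    }


def run_analysis(
    measurements: pd.DataFrame,
    manifest: pd.DataFrame,
    config: StatsConfig = StatsConfig(),
) -> dict:
    """The full cohort comparison report as a JSON-serialisable dict.

    Per marker (Mg, pH) and scope: the vasospasm-vs-control rank-sum
    comparison with group summaries, and the ROC/Youden analysis.  In
    the cumulative scope additionally: the aneurysm-location subgroup
    contrasts (AComm/ACA patients vs others, and vasospasm-vs-control
    within AComm/ACA), the Hunt & Hess strata Kruskal-Wallis + Dunn
    analysis, and the treatment-arm comparison.  Every block carries n
    and the excluded patients with reasons.
    """
    report: dict = {
        "config": {
            "alpha": config.alpha,
            "adjustment": config.adjustment,
            "aggregation_unit": config.aggregation_unit,
            "roc_direction": {m: MARKERS[m][1] for m in MARKERS},
        },
        "scopes": {},
    }

    for scope_name in config.scopes:
        scope = AggregateScope(scope_name, config.aggregation_unit)
        table, exclusions = aggregate(
            measurements, manifest, scope, config.min_voxels_per_hemisphere
        )
        block: dict = {
            "n_patients": int(table.patient_id.nunique()) if len(table) else 0,
            "excluded": exclusions,
            "flagged_insufficient_voxels": sorted(
                table.loc[table.insufficient_voxels, "patient_id"].unique().tolist()
            )
            if len(table)
            else [],
            "markers": {},
        }
        for marker, (column, direction) in MARKERS.items():
            mblock = _two_group_block(table, column, "group", "vasospasm", "control")
            if "p_value" in mblock:
                roc = roc_youden(
                    table[column].to_numpy(float),
                    (table.group == "vasospasm").to_numpy(),
                    direction,
                )
                mblock["roc"] = {
                    "auc": roc.auc,
                    "youden_cutoff": roc.youden_cutoff,
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                    "j": roc.j,
                    "direction": roc.direction,
                }
            block["markers"][marker] = mblock
        report["scopes"][scope_name] = block

    # cumulative-scope clinical subgroup analyses
    table, _ = aggregate(
        measurements, manifest, AggregateScope("cumulative", config.aggregation_unit),
        config.min_voxels_per_hemisphere,
    )
    if len(table) == 0:
        report["location_and_clinical_subgroups"] = {"note": "no patients in cumulative scope"}
        return report
    sub: dict = {}
    in_subgroup = table.aneurysm_location.isin(config.location_subgroup)
    table = table.assign(_loc=np.where(in_subgroup, "subgroup", "others"))
    for marker, (column, _) in MARKERS.items():
        entry = {
            "location_subgroup_vs_others": _two_group_block(
                table, column, "_loc", "subgroup", "others"
            ),
            "location_within_subgroup_by_group": _two_group_block(
                table[in_subgroup], column, "group", "vasospasm", "control"
            ),
            "treatment": _two_group_block(table, column, "treatment", "clipping", "coiling"),
        }
        strata = {
            str(g): vals[column].to_numpy(float)
            for g, vals in table.groupby("hunt_hess")
        }
        if len(strata) >= 3:
            kd = kruskal_dunn(strata, config.adjustment)
            entry["hunt_hess"] = {
                "test": "kruskal-wallis",
                "h": kd.h_statistic,
                "p_value": kd.p_value,
                "note": kd.note,
                "dunn": kd.pairwise.to_dict(orient="records"),
                "strata_n": {k: int(v.size) for k, v in strata.items()},
            }
        else:
            entry["hunt_hess"] = {
                "note": f"only {len(strata)} nonempty strata; omnibus requires >= 3"
            }
        sub[marker] = entry
    report["location_and_clinical_subgroups"] = sub
    return report
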