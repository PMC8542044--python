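"""Regulated-site calling, inhibitor-rescue classification and temporal patterns.

A phosphosite is called stimulus-regulated at a timepoint when the mean
replicate log2 ratio (stimulus / vehicle) clears ±0.485 and a two-tailed
one-sample t-test of the replicate log2 ratios against zero gives p < 0.05.
The one-sample form reflects the paired structure of SILAC quantification
(both channels are measured within the same run); a two-sample Welch mode on
log2 intensities is available for comparison.

Kinase dependence is decided by the inhibitor arm: the rescue fraction
``f = 1 - mean_log2r_TN / mean_log2r_T`` is the share of the stimulus-induced
log2 change removed by the inhibitor.  Up-regulated sites with f >= 0.5 are
"inhibited", down-regulated sites with f >= 0.5 are "rescued"; anything else
is inhibitor-independent.  Thresholds are inclusive at the boundary
(documented constants); p is strictly < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phospho_io import PhosphoSiteRecord, SiteQuant

# t statistic assigned when replicate ratios have zero variance but a
# nonzero mean (p would otherwise be NaN); large enough to always pass the
# p gate, finite so downstream arithmetic stays defined
T_STAT_CAP = 1e6

DIRECTIONS = ("up", "down", "ns")
DEPENDENCE = ("inhibited", "rescued", "independent", "not_applicable")
PATTERNS = (
    "early_only",
    "late_only",
    "sustained",
    "late_dependent",
    "mixed",
    "none",
    "insufficient",
)


@dataclass
class RegulationThresholds:
    min_abs_log2ratio: float = 0.485
    max_p: float = 0.05
    rescue_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.min_abs_log2ratio <= 0:
            raise ValueError("min_abs_log2ratio must be > 0")
        if not 0.0 < self.max_p < 1.0:
            raise ValueError("max_p must be in (0, 1)")
        if not 0.0 < self.rescue_threshold <= 1.0:
            raise ValueError("rescue_threshold must be in (0, 1]")


@dataclass
class RegulationCall:
    site_id: str
    timepoint: str
    direction: str = "ns"
    p_value: float = float("nan")
    mean_log2r_T: float = float("nan")
    mean_log2r_TN: float = float("nan")
    rescue_fraction_f: float | None = None
    dependence: str = "not_applicable"
    reason: str = ""


@dataclass
class TemporalPattern:
    site_id: str
    vector: dict[str, tuple[str, str]]  # timepoint -> (direction, dependence)
    label: str


def test_regulation(
    quant: SiteQuant,
    timepoint: str,
    thresholds: RegulationThresholds | None = None,
) -> RegulationCall:
    """Direction and p-value for one site at one timepoint.

    p comes from a two-tailed one-sample t-test of the replicate log2
    ratios against 0.  Fewer than 2 replicates yields ``ns`` with a logged
    reason rather than an error.
    """
    thresholds = thresholds or RegulationThresholds()
    ratios = quant.replicate_log2r_T(timepoint)
    call = RegulationCall(site_id=quant.site_id, timepoint=timepoint)
    if len(ratios) < 2:
        call.reason = "insufficient replicates"
        return call
    mean = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1))
    df = len(ratios) - 1
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else math.copysign(T_STAT_CAP, mean)
        p = 1.0 if mean == 0.0 else 2.0 * stats.t.sf(abs(t), df)
    else:
        t = mean / (sd / math.sqrt(len(ratios)))
        p = 2.0 * stats.t.sf(abs(t), df)
    call.p_value = float(p)
    call.mean_log2r_T = mean
    rtn = quant.replicate_log2r_TN(timepoint)
    call.mean_log2r_TN = float(np.mean(rtn)) if len(rtn) else float("nan")
    if p < thresholds.max_p and mean >= thresholds.min_abs_log2ratio:
        call.direction = "up"
    elif p < thresholds.max_p and mean <= -thresholds.min_abs_log2ratio:
        call.direction = "down"
    else:
        call.direction = "ns"
    return call


def test_regulation_two_sample(
    stimulus_log2: np.ndarray,
    vehicle_log2: np.ndarray,
) -> float:
    """Welch two-sample alternative on log2 intensities; returns the p-value."""
    return float(stats.ttest_ind(stimulus_log2, vehicle_log2, equal_var=False).pvalue)


def rescue_fraction(mean_log2r_T: float, mean_log2r_TN: float) -> float:
    """Fraction of the stimulus-induced log2 change removed by the inhibitor.

    Sign-symmetric: a down-regulated site whose inhibitor-arm ratio moves
    back toward zero gets the same positive f as the mirrored up site.  f
    may exceed 1 (over-rescue) or go negative (amplification).
    """
    if mean_log2r_T == 0.0:
        raise ValueError("rescue fraction undefined when the stimulus ratio is 0")
    return 1.0 - mean_log2r_TN / mean_log2r_T


def classify_dependence(
    call: RegulationCall, thresholds: RegulationThresholds | None = None
) -> RegulationCall:
    """Fill in the inhibitor-dependence class of a regulated call (in place).

    Calling this on a non-significant call is a contract error.
    """
    thresholds = thresholds or RegulationThresholds()
    if call.direction == "ns":
        raise ValueError("classify_dependence requires a regulated (non-ns) call")
    if math.isnan(call.mean_log2r_TN):
        call.dependence = "independent"
        call.reason = "no inhibitor-arm quantification"
        return call
    f = rescue_fraction(call.mean_log2r_T, call.mean_log2r_TN)
    call.rescue_fraction_f = f
    if f >= thresholds.rescue_threshold:
        call.dependence = "inhibited" if call.direction == "up" else "rescued"
    else:
        call.dependence = "independent"
    return call


def call_sites(
    quants: Sequence[SiteQuant],
    timepoints: Sequence[str],
    thresholds: RegulationThresholds | None = None,
) -> list[RegulationCall]:
    """Regulation + dependence calls for every site at every timepoint."""
    thresholds = thresholds or RegulationThresholds()
    calls = []
    for quant in quants:
        for tp in timepoints:
            call = test_regulation(quant, tp, thresholds)
            if call.direction != "ns":
                classify_dependence(call, thresholds)
            calls.append(call)
    return calls


def assign_temporal_pattern(
    calls: Sequence[RegulationCall],
    timepoints: Sequence[str],
) -> TemporalPattern:
    """Deterministic temporal label from a site's per-timepoint calls.

    "Early" are the first half of the timepoints, "late" the second half.
    Decision table, first match wins:

    1. fewer than 2 timepoints with calls -> ``insufficient``
    2. no regulated timepoint -> ``none``
    3. dependent (inhibited/rescued) at >= 1 late timepoint and at no early
       timepoint -> ``late_dependent``
    4. regulated early and late -> ``sustained``
    5. regulated early only -> ``early_only``
    6. regulated late only -> ``late_only``
    7. otherwise -> ``mixed``
    """
    by_tp = {c.timepoint: c for c in calls}
    site_id = calls[0].site_id if calls else ""
    vector = {
        tp: (by_tp[tp].direction, by_tp[tp].dependence)
        for tp in timepoints
        if tp in by_tp
    }
    if len(vector) < 2:
        return TemporalPattern(site_id, vector, "insufficient")
    half = len(timepoints) // 2
    early, late = set(timepoints[:half]), set(timepoints[half:])
    reg = {tp for tp, (d, _) in vector.items() if d != "ns"}
    dep = {tp for tp, (_, dp) in vector.items() if dp in ("inhibited", "rescued")}
    if not reg:
        label = "none"
    elif (dep & late) and not (dep & early):
        label = "late_dependent"
    elif (reg & early) and (reg & late):
        label = "sustained"
    elif reg & early:
        label = "early_only"
    elif reg & late:
        label = "late_only"
    else:
        label = "mixed"
    return TemporalPattern(site_id, vector, label)


def pca_profiles(matrix: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Top-2 principal-component coordinates of a samples x sites matrix.

    The matrix is column mean-centred; missing values are imputed to 0 on
    the log2 scale ("no change") beforehand by the caller or here for NaN.
    Component signs are fixed by making the largest-magnitude loading of
    each component positive, so the embedding is deterministic.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA requires at least 3 samples")
    X = np.nan_to_num(X, nan=0.0)
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("degenerate input: no variance across samples")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(min(2, Vt.shape[0])):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    coords = U[:, :2] * S[:2]
    explained = (S**2) / np.sum(S**2)
    return coords, explained[:2]


def export_calls(
    calls: Sequence[RegulationCall],
    patterns: Mapping[str, TemporalPattern] | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """One row per site x timepoint, volcano-ready; optionally written as TSV."""
    rows = []
    for c in calls:
        rows.append(
            {
                "site_id": c.site_id,
                "timepoint": c.timepoint,
                "direction": c.direction,
                "p_value": c.p_value,
                "mean_log2r_T": c.mean_log2r_T,
                "mean_log2r_TN": c.mean_log2r_TN,
                "rescue_fraction": (
                    float("nan") if c.rescue_fraction_f is None else c.rescue_fraction_f
                ),
                "dependence": c.dependence,
                "pattern": (
                    patterns[c.site_id].label
                    if patterns and c.site_id in patterns
                    else ""
                ),
                "reason": c.reason,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "timepoint",
            "direction",
            "p_value",
            "mean_log2r_T",
            "mean_log2r_TN",
            "rescue_fraction",
            "dependence",
            "pattern",
            "reason",
        ],
    )
    # BH-adjusted column emitted for transparency; gating uses raw p
    if len(df):
        from statsmodels.stats.multitest import multipletests

        finite = df["p_value"].notna()
        adj = np.full(len(df), np.nan)
        if finite.any():
            adj[finite.to_numpy()] = multipletests(
                df.loc[finite, "p_value"], method="fdr_bh"
            )[1]
        df["p_adjusted"] = adj
    else:
        df["p_adjusted"] = []
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
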