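"""RNA-seq gene-filtering cascade, normalization, simple DE and ΔΔCT qPCR.

The cascade reproduces the five-stage filter that links a phosphomimetic
reconstitution panel (TRIM28 KO; WT-, S473A- and S473D-reconstituted KO) to
stimulus-induced transcription:

* stage 1: genes up (or down) regulated by the stimulus in WT-reconstituted
  cells — p < 0.05 and |log2 fold change| > 2;
* stage 2: of the up genes, those further up in KO vs WT under stimulus
  (log2 ratio > 0);
* stage 3: additionally up in the phosphomimetic S473D vs WT (> 0);
* stage 4: additionally up in S473D vs the non-phosphorylatable S473A (> 0);
* stage 5: the same contrast above 0.26.

All ratio gates are strict inequalities as printed in the filter scheme; the
p gate is strict <.  Counts are normalized by DESeq2-style median-of-ratios
size factors; the internal differential test (for synthetic data) is a Welch
t-test on log2 normalized counts with BH adjustment — real-data runs consume
an externally produced DE table instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.5


class NormalizationError(ValueError):
    """No gene has nonzero counts in every sample."""


@dataclass
class DeTable:
    """Per-gene differential-expression results for one contrast."""

    table: pd.DataFrame  # index: gene; columns: log2fc, p, p_adjusted
    contrast: str = ""

    def __post_init__(self) -> None:
        required = {"log2fc", "p", "p_adjusted"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DeTable missing columns {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate genes in DeTable")


@dataclass
class CascadeThresholds:
    stage1_max_p: float = 0.05
    stage1_min_abs_log2fc: float = 2.0
    stage2_min_log2ratio: float = 0.0
    stage3_min_log2ratio: float = 0.0
    stage4_min_log2ratio: float = 0.0
    stage5_min_log2ratio: float = 0.26
    use_adjusted_p: bool = False  # Methods variant: BH-adjusted p at stage 1

    def __post_init__(self) -> None:
        if not 0.0 < self.stage1_max_p < 1.0:
            raise ValueError("stage1_max_p must be in (0, 1)")
        if self.stage1_min_abs_log2fc < 0:
            raise ValueError("stage1_min_abs_log2fc must be >= 0")


@dataclass
class CascadeResult:
    s1_up: frozenset
    s1_down: frozenset
    s2: frozenset
    s3: frozenset
    s4: frozenset
    s5: frozenset
    dropped_missing: dict[str, int] = field(default_factory=dict)
    contrasts: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "s1_up": len(self.s1_up),
            "s1_down": len(self.s1_down),
            "s2": len(self.s2),
            "s3": len(self.s3),
            "s4": len(self.s4),
            "s5": len(self.s5),
        }


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq2-style size factors: per sample, the median over
    all-samples-nonzero genes of count / geometric-mean-across-samples."""
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise NormalizationError("no gene has nonzero counts in every sample")
    ref = np.exp(np.mean(np.log(mat[nonzero]), axis=1))
    factors = np.median(mat[nonzero] / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / median_of_ratios_size_factors(counts)


def simple_de(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    contrast: str = "",
) -> DeTable:
    """Welch t-test differential expression of group A vs group B.

    log2fc is the log2 ratio of normalized group means with a 0.5
    pseudocount (positive = higher in A); p from a two-sided Welch test on
    log2(normalized + 0.5); BH adjustment across genes.  Genes with zero
    variance in both groups and equal means get p = 1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    norm = normalize_counts(counts[list(group_a) + list(group_b)])
    a = norm[list(group_a)].to_numpy(dtype=float)
    b = norm[list(group_b)].to_numpy(dtype=float)
    log2fc = np.log2(a.mean(axis=1) + PSEUDOCOUNT) - np.log2(b.mean(axis=1) + PSEUDOCOUNT)
    la, lb = np.log2(a + PSEUDOCOUNT), np.log2(b + PSEUDOCOUNT)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "p_adjusted": p_adj}, index=counts.index
    )
    return DeTable(table, contrast=contrast)


def log2_expression_ratio(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    genotype_a: str,
    genotype_b: str,
    treatment: str,
    size_factors: pd.Series | None = None,
) -> pd.Series:
    """Per-gene log2 ratio of normalized mean expression, genotype A vs B
    under the given treatment, with a 0.5 pseudocount."""
    if size_factors is None:
        size_factors = median_of_ratios_size_factors(counts)
    norm = counts / size_factors

    def _samples(genotype: str) -> list[str]:
        mask = (sample_sheet["genotype"] == genotype) & (
            sample_sheet["treatment"] == treatment
        )
        samples = list(sample_sheet.index[mask])
        if not samples:
            raise ValueError(f"no samples for ({genotype}, {treatment})")
        return samples

    mean_a = norm[_samples(genotype_a)].mean(axis=1)
    mean_b = norm[_samples(genotype_b)].mean(axis=1)
    return np.log2(mean_a + PSEUDOCOUNT) - np.log2(mean_b + PSEUDOCOUNT)


def run_cascade(
    de_stimulus: DeTable,
    r_ko_vs_wt: Mapping[str, float],
    r_d_vs_wt: Mapping[str, float],
    r_d_vs_a: Mapping[str, float],
    thresholds: CascadeThresholds | None = None,
) -> CascadeResult:
    """Apply the five-stage filter; enforces the nesting invariant
    S5 ⊆ S4 ⊆ S3 ⊆ S2 ⊆ S1_up by construction.  Genes absent from a ratio
    map are excluded at that stage and counted in ``dropped_missing``."""
    thresholds = thresholds or CascadeThresholds()
    table = de_stimulus.table
    if len(table) and not (
        set(table.index) & (set(r_ko_vs_wt) | set(r_d_vs_wt) | set(r_d_vs_a))
    ):
        if r_ko_vs_wt or r_d_vs_wt or r_d_vs_a:
            raise ValueError("DE table and ratio maps share no genes")
    p_col = "p_adjusted" if thresholds.use_adjusted_p else "p"
    sig = table[p_col] < thresholds.stage1_max_p
    s1_up = frozenset(table.index[sig & (table["log2fc"] > thresholds.stage1_min_abs_log2fc)])
    s1_down = frozenset(
        table.index[sig & (table["log2fc"] < -thresholds.stage1_min_abs_log2fc)]
    )
    dropped = {}

    def _gate(genes: frozenset, ratios: Mapping[str, float], cutoff: float, stage: str):
        present = {g for g in genes if g in ratios}
        dropped[stage] = len(genes) - len(present)
        return frozenset(g for g in present if ratios[g] > cutoff)

    s2 = _gate(s1_up, r_ko_vs_wt, thresholds.stage2_min_log2ratio, "s2")
    s3 = _gate(s2, r_d_vs_wt, thresholds.stage3_min_log2ratio, "s3")
    s4 = _gate(s3, r_d_vs_a, thresholds.stage4_min_log2ratio, "s4")
    s5 = _gate(s4, r_d_vs_a, thresholds.stage5_min_log2ratio, "s5")
    return CascadeResult(
        s1_up=s1_up,
        s1_down=s1_down,
        s2=s2,
        s3=s3,
        s4=s4,
        s5=s5,
        dropped_missing=dropped,
        contrasts={"stage1": de_stimulus.contrast},
    )


def ddct(
    ct_table: pd.DataFrame,
    control_condition: str = "control",
) -> pd.DataFrame:
    """Relative qPCR quantification by the 2^-ΔΔCT method.

    Input rows: (gene, condition, replicate, ct_target, ct_reference).
    ΔCT = Ct_target - Ct_reference per replicate; ΔΔCT subtracts the mean
    control ΔCT of the same gene; fold = 2^-ΔΔCT.  The control-condition
    mean fold is 1 by construction (on the ΔΔCT scale), and results are
    invariant to adding a constant to every Ct.
    """
    required = {"gene", "condition", "replicate", "ct_target", "ct_reference"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct table missing columns {sorted(missing)}")
    if ct_table["ct_reference"].isna().any():
        raise ValueError("missing reference Ct")
    df = ct_table.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    out_rows = []
    for gene, sub in df.groupby("gene", sort=True):
        control = sub[sub["condition"] == control_condition]
        if control.empty:
            raise ValueError(f"gene {gene}: no {control_condition!r} condition")
        control_mean = control["delta_ct"].mean()
        for _, row in sub.iterrows():
            ddct_val = row["delta_ct"] - control_mean
            out_rows.append(
                {
                    "gene": gene,
                    "condition": row["condition"],
                    "replicate": row["replicate"],
                    "delta_ct": row["delta_ct"],
                    "delta_delta_ct": ddct_val,
                    "fold": 2.0 ** (-ddct_val),
                }
            )
    return pd.DataFrame(out_rows)


def ddct_summary(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Mean fold change per gene x condition from :func:`ddct` output."""
    return (
        per_replicate.groupby(["gene", "condition"])["fold"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "fold_mean", "sem": "fold_sem", "count": "n"})
    )


def read_de_table(path, contrast: str = "") -> DeTable:
    """TSV with columns gene, log2fc, p, p_adjusted (external DE results)."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError("DE table must have a 'gene' column")
    return DeTable(df.set_index("gene"), contrast=contrast)
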