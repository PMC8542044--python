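"""Hand-built 12-gene cascade fixture and its exhaustive brute-force oracle."""

import pandas as pd

from phosphorescue.rnaseq_cascade import CascadeThresholds, DeTable

TOY_GENES = [f"g{i}" for i in range(12)]
# gene -> (log2fc, p, r_ko_vs_wt, r_d_vs_wt, r_d_vs_a)
TOY_TABLE = {
    "g0": (3.0, 0.001, 1.0, 1.0, 1.0),   # survives to S5
    "g1": (2.5, 0.010, 0.5, 0.2, 0.26),  # fails S5 (0.26 not > 0.26)
    "g2": (2.1, 0.040, 0.1, 0.3, 0.10),  # S4 only
    "g3": (4.0, 0.001, 0.9, -0.1, 2.0),  # fails S3
    "g4": (2.2, 0.020, -0.5, 1.0, 1.0),  # fails S2
    "g5": (1.9, 0.001, 1.0, 1.0, 1.0),   # fails S1 (fc not > 2)
    "g6": (2.8, 0.060, 1.0, 1.0, 1.0),   # fails S1 (p)
    "g7": (-2.5, 0.010, 1.0, 1.0, 1.0),  # S1 down
    "g8": (-3.0, 0.002, 1.0, 1.0, 1.0),  # S1 down
    "g9": (0.0, 0.900, 0.0, 0.0, 0.0),   # null
    "g10": (2.0, 0.010, 1.0, 1.0, 1.0),  # fails S1 (fc == 2, strict)
    "g11": (5.0, 0.049, 0.0, 1.0, 1.0),  # fails S2 (0 not > 0)
}


def toy_inputs():
    de = DeTable(
        pd.DataFrame(
            {
                "log2fc": [TOY_TABLE[g][0] for g in TOY_GENES],
                "p": [TOY_TABLE[g][1] for g in TOY_GENES],
                "p_adjusted": [TOY_TABLE[g][1] for g in TOY_GENES],
            },
            index=TOY_GENES,
        )
    )
    maps = tuple({g: TOY_TABLE[g][j] for g in TOY_GENES} for j in (2, 3, 4))
    return de, maps


def brute_force_cascade(thresholds=None):
    """Exhaustive set computation over the 12 toy genes."""
    th = thresholds or CascadeThresholds()
    s1_up = {
        g
        for g in TOY_GENES
        if TOY_TABLE[g][1] < th.stage1_max_p
        and TOY_TABLE[g][0] > th.stage1_min_abs_log2fc
    }
    s1_down = {
        g
        for g in TOY_GENES
        if TOY_TABLE[g][1] < th.stage1_max_p
        and TOY_TABLE[g][0] < -th.stage1_min_abs_log2fc
    }
    s2 = {g for g in s1_up if TOY_TABLE[g][2] > th.stage2_min_log2ratio}
    s3 = {g for g in s2 if TOY_TABLE[g][3] > th.stage3_min_log2ratio}
    s4 = {g for g in s3 if TOY_TABLE[g][4] > th.stage4_min_log2ratio}
    s5 = {g for g in s4 if TOY_TABLE[g][4] > th.stage5_min_log2ratio}
    return s1_up, s1_down, s2, s3, s4, s5
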