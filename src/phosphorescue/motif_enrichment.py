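"""Iterative consensus-motif discovery over aligned phosphosite windows.

The algorithm is the classical greedy motif-x scheme on 15-mer windows
centred on the phosphoresidue.  At each step every unfixed (offset, residue)
pair is scored with the binomial tail probability of seeing at least the
observed number of foreground matches given the background residue frequency
at that offset; the most significant pair is fixed if it clears the step
p-value threshold and minimum support, the foreground and background are
restricted to matching sequences, and the search repeats.  When a motif is
complete its matching foreground sequences are removed and the whole process
recurses on the remainder, so motif supports are disjoint.

Positions padded with ``_`` (protein termini) are excluded from counting.
A 0.5 pseudocount on background counts guards against zero frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .phospho_io import CENTER_INDEX, WINDOW_LENGTH

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
OFFSETS = tuple(o for o in range(-CENTER_INDEX, WINDOW_LENGTH - CENTER_INDEX) if o != 0)
BACKGROUND_PSEUDOCOUNT = 0.5


@dataclass
class MotifConfig:
    p_threshold: float = 1e-6
    min_occurrences: int = 20
    max_fixed_positions: int = 4
    central: str = "ST"  # analyse S and T jointly; "Y" separately

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_occurrences < 1:
            raise ValueError("min_occurrences must be >= 1")
        if not set(self.central) <= set("STY"):
            raise ValueError("central must be drawn from S/T/Y")


@dataclass
class MotifSpec:
    """A fixed-position consensus motif with its enrichment statistics."""

    fixed_positions: dict[int, str]
    central: str
    support: int
    foreground_size: int
    fold_enrichment: float
    p_binomial: float  # final fixing step's binomial tail
    step_p_values: list[float] = field(default_factory=list)

    @property
    def display(self) -> str:
        lo = min(min(self.fixed_positions, default=0), 0)
        hi = max(max(self.fixed_positions, default=0), 0)
        out = []
        for off in range(lo, hi + 1):
            if off == 0:
                out.append("p" + ("S" if self.central == "ST" else self.central))
            elif off in self.fixed_positions:
                out.append(self.fixed_positions[off])
            else:
                out.append("x")
        return "".join(out)


def extract_windows(
    windows: Iterable[str],
) -> list[str]:
    """Deduplicate and upper-case aligned windows (one biological site, one vote)."""
    seen: list[str] = []
    have = set()
    for w in windows:
        w = w.upper()
        if len(w) != WINDOW_LENGTH:
            raise ValueError(f"window {w!r} is not a {WINDOW_LENGTH}-mer")
        if w not in have:
            have.add(w)
            seen.append(w)
    return seen


def select_windows(
    records,
    calls,
    timepoint: str | None = None,
    direction: str = "up",
    dependence: Sequence[str] = ("inhibited",),
) -> list[str]:
    """Foreground windows for sites matching a direction/dependence filter."""
    wanted = {
        c.site_id
        for c in calls
        if (timepoint is None or c.timepoint == timepoint)
        and c.direction == direction
        and c.dependence in dependence
    }
    return extract_windows(r.window for r in records if r.site_id in wanted)


def score_window(window: str, motif: MotifSpec) -> bool:
    """True iff all of the motif's fixed positions (and centre class) match."""
    if len(window) != WINDOW_LENGTH:
        raise ValueError(f"window {window!r} is not a {WINDOW_LENGTH}-mer")
    if window[CENTER_INDEX] not in motif.central:
        return False
    return all(
        window[CENTER_INDEX + off] == res for off, res in motif.fixed_positions.items()
    )


def _filter_central(windows: Sequence[str], central: str) -> list[str]:
    return [w for w in windows if w[CENTER_INDEX] in central]


def _count_matches(windows: Sequence[str], offset: int, residue: str) -> tuple[int, int]:
    """(matches, counted) at an offset; '_' padding positions are not counted."""
    idx = CENTER_INDEX + offset
    k = n = 0
    for w in windows:
        ch = w[idx]
        if ch == "_":
            continue
        n += 1
        if ch == residue:
            k += 1
    return k, n


def binomial_step_p(k: int, n: int, p: float) -> float:
    """Exact upper binomial tail P(X >= k | n, p)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def find_motifs(
    foreground: Sequence[str],
    background: Sequence[str],
    config: MotifConfig | None = None,
) -> list[MotifSpec]:
    """Greedy motif-x search; returns motifs in discovery order.

    Ties between candidate (offset, residue) pairs at the same p are broken
    lexicographically by (p, offset, residue), so results are deterministic.
    """
    config = config or MotifConfig()
    fg = _filter_central(extract_windows(foreground), config.central)
    bg = _filter_central([w.upper() for w in background], config.central)
    motifs: list[MotifSpec] = []
    fg_size_initial = len(fg)
    while True:
        motif = _grow_motif(fg, bg, config)
        if motif is None:
            return motifs
        matched = [w for w in fg if score_window(w, motif)]
        motif.support = len(matched)
        motif.foreground_size = fg_size_initial
        # overall fold: foreground vs background match rate for the full motif
        bg_matched = sum(1 for w in bg if score_window(w, motif))
        fg_rate = len(matched) / len(fg) if fg else 0.0
        bg_rate = (bg_matched + BACKGROUND_PSEUDOCOUNT) / (
            len(bg) + BACKGROUND_PSEUDOCOUNT
        )
        motif.fold_enrichment = fg_rate / bg_rate
        motifs.append(motif)
        fg = [w for w in fg if w not in set(matched)]
        bg = [w for w in bg if not score_window(w, motif)]
        if not fg or not bg:
            return motifs


def _grow_motif(
    fg: Sequence[str], bg: Sequence[str], config: MotifConfig
) -> MotifSpec | None:
    fixed: dict[int, str] = {}
    steps: list[float] = []
    fg_cur, bg_cur = list(fg), list(bg)
    while len(fixed) < config.max_fixed_positions:
        best: tuple[float, int, str] | None = None
        best_k = 0
        for offset in OFFSETS:
            if offset in fixed:
                continue
            for residue in AMINO_ACIDS:
                k, n = _count_matches(fg_cur, offset, residue)
                if k < config.min_occurrences or n == 0:
                    continue
                bk, bn = _count_matches(bg_cur, offset, residue)
                p_bg = (bk + BACKGROUND_PSEUDOCOUNT) / (
                    bn + BACKGROUND_PSEUDOCOUNT * len(AMINO_ACIDS)
                )
                p = binomial_step_p(k, n, p_bg)
                cand = (p, offset, residue)
                if best is None or cand < best:
                    best = cand
                    best_k = k
        if best is None or best[0] >= config.p_threshold:
            break
        p, offset, residue = best
        fixed[offset] = residue
        steps.append(p)
        idx = CENTER_INDEX + offset
        fg_cur = [w for w in fg_cur if w[idx] == residue]
        bg_cur = [w for w in bg_cur if w[idx] == residue]
    if not fixed:
        return None
    return MotifSpec(
        fixed_positions=fixed,
        central=config.central,
        support=len(fg_cur),
        foreground_size=len(fg),
        fold_enrichment=0.0,  # filled by caller over the full motif
        p_binomial=steps[-1],
        step_p_values=steps,
    )


def motifs_to_table(motifs: Sequence[MotifSpec]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "display": m.display,
                "fixed_positions": ";".join(
                    f"{off:+d}{res}" for off, res in sorted(m.fixed_positions.items())
                ),
                "support": m.support,
                "foreground_size": m.foreground_size,
                "fold_enrichment": m.fold_enrichment,
                "p_binomial": m.p_binomial,
            }
            for m in motifs
        ],
        columns=[
            "display",
            "fixed_positions",
            "support",
            "foreground_size",
            "fold_enrichment",
            "p_binomial",
        ],
    )
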