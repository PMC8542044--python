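"""Reading, validation and QC of quantified phosphosite tables.

A quantified phosphosite table has one row per site (times multiplicity for
MaxQuant input) and per-replicate intensity columns for the three SILAC
channels: ``vehicle`` (light, DMSO), ``stimulus`` (medium, TNFα) and
``stimulus_inhibitor`` (heavy, TNFα + Nec-1s).  Ratios are always formed
within a replicate against the vehicle channel, so quantification is paired
by construction.

Two input dialects are supported:

``generic_tsv``
    The package's own schema.  Measurement columns are named
    ``<channel>__<timepoint>__r<replicate>``, e.g. ``stimulus__0.5h__r3``.

``maxquant_sty``
    A MaxQuant ``Phospho (STY)Sites``-style table with ``Localization prob``,
    ``Sequence window``, ``Position``, ``Amino acid``, ``Protein``,
    ``Gene names`` and per-experiment ``Intensity L/M/H <timepoint>_r<rep>``
    columns, with ``___k`` multiplicity suffixes.  Light/medium/heavy map to
    vehicle / stimulus / stimulus+inhibitor respectively.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CHANNELS = ("vehicle", "stimulus", "stimulus_inhibitor")
DEFAULT_TIMEPOINTS = ("15min", "0.5h", "2h", "4h")
WINDOW_LENGTH = 15
CENTER_INDEX = 7  # 0-based; the phosphorylatable residue sits at position 8 (1-based)

_MEAS_RE = re.compile(r"^(vehicle|stimulus|stimulus_inhibitor)__(.+)__r(\d+)$")
_MQ_INTENSITY_RE = re.compile(r"^Intensity ([LMH]) (.+)_r(\d+)(?:___(\d))?$")
_MQ_CHANNEL = {"L": "vehicle", "M": "stimulus", "H": "stimulus_inhibitor"}


class SchemaError(ValueError):
    """A mandatory column is missing or the dialect is unknown."""


class RowParseError(ValueError):
    """A row holds a value that cannot be parsed; carries the line number."""


@dataclass
class PhosphoSiteRecord:
    """One quantified phosphosite (one multiplicity slice for MaxQuant input).

    ``measurements`` maps ``(channel, timepoint, replicate)`` to a raw
    intensity.  Missing measurements are simply absent from the mapping;
    zero intensities are converted to missing at read time when the QC
    policy says so (SILAC zero means "not detected", not "ratio zero").
    """

    site_id: str
    protein_id: str
    gene: str
    position: int
    residue: str
    window: str
    localization_probability: float
    multiplicity: int = 1
    measurements: dict[tuple[str, str, int], float] = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.window) != WINDOW_LENGTH:
            raise ValueError(
                f"site {self.site_id}: window must be {WINDOW_LENGTH}-mer, "
                f"got {len(self.window)}"
            )
        if self.window[CENTER_INDEX] not in "STY":
            raise ValueError(
                f"site {self.site_id}: central residue {self.window[CENTER_INDEX]!r} "
                "is not phosphorylatable (S/T/Y)"
            )
        if not 0.0 <= self.localization_probability <= 1.0:
            raise ValueError(
                f"site {self.site_id}: localization probability "
                f"{self.localization_probability} outside [0, 1]"
            )
        if self.position < 1:
            raise ValueError(f"site {self.site_id}: position {self.position} < 1")

    def timepoints(self) -> list[str]:
        seen: list[str] = []
        for (_, tp, _) in self.measurements:
            if tp not in seen:
                seen.append(tp)
        return seen

    def replicates_quantified(self, timepoint: str) -> list[int]:
        """Replicates where both the stimulus and vehicle channel are present."""
        reps = set()
        for (channel, tp, rep) in self.measurements:
            if tp == timepoint and channel == "stimulus":
                if ("vehicle", tp, rep) in self.measurements:
                    reps.add(rep)
        return sorted(reps)


@dataclass
class SiteQuant:
    """Per-site log2 ratios and replicate statistics.

    ``log2r_T`` is log2(stimulus / vehicle), ``log2r_TN`` is
    log2(stimulus+inhibitor / vehicle), both per (timepoint, replicate).
    CVs are linear-scale coefficients of variation of the replicate ratios.
    """

    site_id: str
    log2r_T: dict[tuple[str, int], float] = field(default_factory=dict)
    log2r_TN: dict[tuple[str, int], float] = field(default_factory=dict)
    n_replicates: dict[str, int] = field(default_factory=dict)
    mean_log2r_T: dict[str, float] = field(default_factory=dict)
    mean_log2r_TN: dict[str, float] = field(default_factory=dict)
    cv_T: dict[str, float] = field(default_factory=dict)
    cv_TN: dict[str, float] = field(default_factory=dict)

    def replicate_log2r_T(self, timepoint: str) -> np.ndarray:
        return np.array(
            [v for (tp, _), v in sorted(self.log2r_T.items()) if tp == timepoint]
        )

    def replicate_log2r_TN(self, timepoint: str) -> np.ndarray:
        return np.array(
            [v for (tp, _), v in sorted(self.log2r_TN.items()) if tp == timepoint]
        )


@dataclass
class QcPolicy:
    """QC thresholds mirroring the study's filters.

    Sites are kept when the phosphogroup localization probability is at
    least ``min_localization_probability`` (inclusive boundary, a documented
    choice for "over 75%") and the site is quantified — both ratio channels
    present in a replicate — in at least ``min_replicates`` replicates.
    ``replicate_scope`` decides whether that coverage is required at every
    timepoint or at one or more.  The CV rule only annotates by default.
    """

    min_localization_probability: float = 0.75
    min_replicates: int = 2
    max_cv: float | None = 0.25
    drop_high_cv: bool = False
    replicate_scope: str = "all_timepoints"  # or "any_timepoint"
    treat_zero_intensity_as_missing: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_localization_probability <= 1.0:
            raise ValueError("min_localization_probability outside [0, 1]")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")
        if self.max_cv is not None and self.max_cv <= 0:
            raise ValueError("max_cv must be positive or None")
        if self.replicate_scope not in ("all_timepoints", "any_timepoint"):
            raise ValueError(f"unknown replicate_scope {self.replicate_scope!r}")


@dataclass
class QcReport:
    n_input: int = 0
    n_kept: int = 0
    removed_low_localization: int = 0
    removed_low_replicates: int = 0
    removed_high_cv: int = 0
    flagged_high_cv: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _parse_measurement_columns(columns: Iterable[str]) -> dict[str, tuple[str, str, int]]:
    out = {}
    for col in columns:
        m = _MEAS_RE.match(col)
        if m:
            out[col] = (m.group(1), m.group(2), int(m.group(3)))
    return out


MANDATORY_GENERIC = (
    "site_id",
    "protein_id",
    "gene",
    "position",
    "residue",
    "window",
    "localization_prob",
)


def read_sites_table(
    path: str | Path,
    dialect: str = "generic_tsv",
    treat_zero_intensity_as_missing: bool = True,
) -> list[PhosphoSiteRecord]:
    """Read a quantified phosphosite table.

    No filtering happens here: records below the localization threshold are
    retained (QC is a separate, reported step).  Malformed numeric fields
    raise :class:`RowParseError` with the 1-based data line number.
    """
    path = Path(path)
    if dialect == "generic_tsv":
        return _read_generic(path, treat_zero_intensity_as_missing)
    if dialect == "maxquant_sty":
        return _read_maxquant(path, treat_zero_intensity_as_missing)
    raise SchemaError(f"unknown dialect {dialect!r}")


def _read_generic(path: Path, zero_missing: bool) -> list[PhosphoSiteRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in MANDATORY_GENERIC:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r} in {path}")
    meas_cols = _parse_measurement_columns(df.columns)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rowd = dict(zip(df.columns, row))
        try:
            rec = PhosphoSiteRecord(
                site_id=rowd["site_id"],
                protein_id=rowd["protein_id"],
                gene=rowd["gene"],
                position=int(rowd["position"]),
                residue=rowd["residue"],
                window=rowd["window"].upper(),
                localization_probability=float(rowd["localization_prob"]),
                multiplicity=int(rowd.get("multiplicity", 1) or 1),
            )
            for col, key in meas_cols.items():
                raw = rowd[col]
                if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
                    continue
                val = float(raw)
                if val < 0:
                    raise ValueError(f"negative intensity {val}")
                if val == 0 and zero_missing:
                    continue
                rec.measurements[key] = val
        except (TypeError, ValueError) as exc:
            raise RowParseError(f"{path} line {i}: {exc}") from exc
        rec.validate()
        records.append(rec)
    return records


MANDATORY_MAXQUANT = (
    "Protein",
    "Position",
    "Amino acid",
    "Sequence window",
    "Localization prob",
)


def _read_maxquant(path: Path, zero_missing: bool) -> list[PhosphoSiteRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in MANDATORY_MAXQUANT:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r} in {path}")
    # group intensity columns by multiplicity slice
    slices: dict[int, dict[str, tuple[str, str, int]]] = {}
    for col in df.columns:
        m = _MQ_INTENSITY_RE.match(col)
        if not m:
            continue
        mult = int(m.group(4)) if m.group(4) else 1
        slices.setdefault(mult, {})[col] = (
            _MQ_CHANNEL[m.group(1)],
            m.group(2),
            int(m.group(3)),
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rowd = dict(zip(df.columns, row))
        window = str(rowd["Sequence window"]).upper()
        if len(window) > WINDOW_LENGTH:  # MaxQuant emits 31-mers; keep the central 15
            mid = len(window) // 2
            window = window[mid - CENTER_INDEX : mid - CENTER_INDEX + WINDOW_LENGTH]
        protein = str(rowd["Protein"])
        gene = str(rowd.get("Gene names", protein) or protein).split(";")[0]
        try:
            position = int(str(rowd["Position"]).split(";")[0])
            locprob = float(rowd["Localization prob"])
        except (TypeError, ValueError) as exc:
            raise RowParseError(f"{path} line {i}: {exc}") from exc
        for mult, cols in sorted(slices.items()):
            rec = PhosphoSiteRecord(
                site_id=f"{protein}_{rowd['Amino acid']}{position}___{mult}",
                protein_id=protein,
                gene=gene,
                position=position,
                residue=str(rowd["Amino acid"]),
                window=window,
                localization_probability=locprob,
                multiplicity=mult,
            )
            for col, key in cols.items():
                raw = rowd.get(col)
                if raw is None or raw == "" or (isinstance(raw, float) and math.isnan(raw)):
                    continue
                try:
                    val = float(raw)
                except ValueError as exc:
                    raise RowParseError(f"{path} line {i}: {exc}") from exc
                if val == 0 and zero_missing:
                    continue
                rec.measurements[key] = val
            if rec.measurements:
                rec.validate()
                records.append(rec)
    return records


def write_sites_table(
    records: Sequence[PhosphoSiteRecord],
    path: str | Path,
    timepoints: Sequence[str] | None = None,
    n_replicates: int | None = None,
) -> None:
    """Write records in the generic TSV dialect (lossless round trip)."""
    if timepoints is None:
        tps: list[str] = []
        for rec in records:
            for tp in rec.timepoints():
                if tp not in tps:
                    tps.append(tp)
        timepoints = tps
    if n_replicates is None:
        n_replicates = 0
        for rec in records:
            for (_, _, rep) in rec.measurements:
                n_replicates = max(n_replicates, rep)
    meas_cols = [
        f"{ch}__{tp}__r{rep}"
        for tp in timepoints
        for ch in CHANNELS
        for rep in range(1, n_replicates + 1)
    ]
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "site_id": rec.site_id,
            "protein_id": rec.protein_id,
            "gene": rec.gene,
            "position": rec.position,
            "residue": rec.residue,
            "window": rec.window,
            "localization_prob": repr(float(rec.localization_probability)),
            "multiplicity": rec.multiplicity,
        }
        for col in meas_cols:
            ch, tp, rep = _MEAS_RE.match(col).groups()  # type: ignore[union-attr]
            val = rec.measurements.get((ch, tp, int(rep)))
            row[col] = "" if val is None else repr(float(val))
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(MANDATORY_GENERIC) + ["multiplicity"] + meas_cols)
    df.to_csv(path, sep="\t", index=False)


def compute_site_quant(record: PhosphoSiteRecord) -> SiteQuant:
    """Compute per-replicate log2 ratios and per-timepoint summaries.

    Ratios are formed replicate-wise; a missing channel propagates a missing
    ratio.  CVs are computed on the linear-scale ratios (sd / mean), the
    statistic the replicate-quality filter is phrased in.
    """
    quant = SiteQuant(site_id=record.site_id)
    any_ratio = False
    for tp in record.timepoints():
        for rep in range(1, 1 + max((r for (_, t, r) in record.measurements if t == tp), default=0)):
            veh = record.measurements.get(("vehicle", tp, rep))
            if veh is None or veh <= 0:
                continue
            stim = record.measurements.get(("stimulus", tp, rep))
            inh = record.measurements.get(("stimulus_inhibitor", tp, rep))
            if stim is not None and stim > 0:
                quant.log2r_T[(tp, rep)] = math.log2(stim / veh)
                any_ratio = True
            if inh is not None and inh > 0:
                quant.log2r_TN[(tp, rep)] = math.log2(inh / veh)
                any_ratio = True
        rt = quant.replicate_log2r_T(tp)
        rtn = quant.replicate_log2r_TN(tp)
        quant.n_replicates[tp] = len(rt)
        if len(rt):
            quant.mean_log2r_T[tp] = float(np.mean(rt))
            quant.cv_T[tp] = _linear_cv(rt)
        if len(rtn):
            quant.mean_log2r_TN[tp] = float(np.mean(rtn))
            quant.cv_TN[tp] = _linear_cv(rtn)
    if not any_ratio:
        raise ValueError(f"site {record.site_id}: no quantifiable measurements")
    return quant


def _linear_cv(log2_ratios: np.ndarray) -> float:
    linear = np.exp2(log2_ratios)
    mean = float(np.mean(linear))
    if len(linear) < 2 or mean == 0:
        return 0.0
    return float(np.std(linear, ddof=1) / mean)


def apply_qc(
    records: Sequence[PhosphoSiteRecord], policy: QcPolicy | None = None
) -> tuple[list[PhosphoSiteRecord], QcReport]:
    """Apply localization / replicate-coverage / CV filters.

    Idempotent: QC on already-QC'd records removes nothing further.  Empty
    input yields an empty output with a zeroed report.
    """
    policy = policy or QcPolicy()
    report = QcReport(n_input=len(records))
    kept: list[PhosphoSiteRecord] = []
    for rec in records:
        if rec.localization_probability < policy.min_localization_probability:
            report.removed_low_localization += 1
            continue
        tps = rec.timepoints()
        coverage = [len(rec.replicates_quantified(tp)) >= policy.min_replicates for tp in tps]
        ok = all(coverage) if policy.replicate_scope == "all_timepoints" else any(coverage)
        if not tps or not ok:
            report.removed_low_replicates += 1
            continue
        if policy.max_cv is not None:
            try:
                quant = compute_site_quant(rec)
            except ValueError:
                report.removed_low_replicates += 1
                continue
            cvs = list(quant.cv_T.values()) + list(quant.cv_TN.values())
            if cvs and max(cvs) > policy.max_cv:
                if policy.drop_high_cv:
                    report.removed_high_cv += 1
                    continue
                report.flagged_high_cv += 1
        kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


def summarize_global(
    records: Sequence[PhosphoSiteRecord],
    quants: Sequence[SiteQuant] | None = None,
    min_replicates: int = 2,
) -> dict:
    """Dataset-level summary: site/protein counts, per-timepoint coverage,
    CV quantiles, and the count of proteins quantified in at least
    ``min_replicates`` replicates at every timepoint (the protein-level
    coverage statistic)."""
    if quants is None:
        quants = []
        for rec in records:
            try:
                quants.append(compute_site_quant(rec))
            except ValueError:
                continue
    timepoints: list[str] = []
    for rec in records:
        for tp in rec.timepoints():
            if tp not in timepoints:
                timepoints.append(tp)
    per_tp = {
        tp: sum(1 for q in quants if q.n_replicates.get(tp, 0) >= 1) for tp in timepoints
    }
    cvs = [cv for q in quants for cv in q.cv_T.values()]
    cv_quantiles = (
        {
            "q25": float(np.percentile(cvs, 25)),
            "median": float(np.percentile(cvs, 50)),
            "q75": float(np.percentile(cvs, 75)),
        }
        if cvs
        else {"q25": 0.0, "median": 0.0, "q75": 0.0}
    )
    proteins = {rec.protein_id for rec in records}
    covered = {
        rec.protein_id
        for rec in records
        if rec.timepoints()
        and all(
            len(rec.replicates_quantified(tp)) >= min_replicates for tp in rec.timepoints()
        )
    }
    return {
        "n_sites": len(records),
        "n_proteins": len(proteins),
        "n_quantified_sites": len(quants),
        "sites_per_timepoint": per_tp,
        "cv_quantiles": cv_quantiles,
        "n_proteins_covered_all_timepoints": len(covered),
        "cv_below_025_fraction": (
            float(np.mean([cv < 0.25 for cv in cvs])) if cvs else 0.0
        ),
    }


def write_qc_report(report: QcReport, path: str | Path) -> None:
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
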