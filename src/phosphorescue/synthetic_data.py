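"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline is testable offline because these
generators emit the same table dialects the readers consume, together with a
:class:`SyntheticTruth` recording what was planted:

* a triple-channel SILAC phosphosite table (6 replicates x 4 timepoints by
  default) with log-normal multiplicative noise calibrated to a target
  linear-scale CV, planted regulation classes, an inhibitor channel that
  removes a configurable fraction of the stimulus effect in the
  kinase-dependent classes, and R(-3)/P(+1) consensus motifs planted in the
  late-dependent windows;
* protein networks with planted cliques in Erdős–Rényi noise;
* negative-binomial RNA-seq counts for a four-genotype x two-treatment panel
  with genes planted to survive a known number of cascade stages;
* qPCR Ct tables consistent with a chosen fold change under the 2^-ΔΔCT model.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phospho_io import CENTER_INDEX, PhosphoSiteRecord, WINDOW_LENGTH

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# typical phosphoproteome composition of the central residue
CENTER_RESIDUE_PROBS = {"S": 0.85, "T": 0.10, "Y": 0.05}

SITE_CLASSES = (
    "null",
    "independent_up",
    "dependent_late_up",
    "dependent_late_down",
    "early_up",
)

DEFAULT_CLASS_FRACTIONS = {
    "null": 0.70,
    "independent_up": 0.10,
    "dependent_late_up": 0.10,
    "dependent_late_down": 0.05,
    "early_up": 0.05,
}

GENOTYPES = ("KO", "WT", "S473A", "S473D")
TREATMENTS = ("vehicle", "TSZ")


class ConfigurationError(ValueError):
    """A generator configuration violates its invariants."""


@dataclass
class PhosphoSimConfig:
    """Study conditions for the phosphoproteome simulation.

    ``cv_target`` is the linear-scale coefficient of variation of replicate
    intensities; the log-normal sigma is derived as sqrt(ln(1 + cv^2)) so
    the emitted CVs match the QC statistic.  ``rescue_depth`` is the fraction
    of the planted stimulus log2 change removed in the inhibitor channel of
    dependent sites; 0.8 plants sites comfortably past the 50% rescue rule.
    """

    n_sites: int = 2000
    n_replicates: int = 6
    timepoints: tuple[str, ...] = ("15min", "0.5h", "2h", "4h")
    cv_target: float = 0.15
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    effect_log2: float = 1.0
    rescue_depth: float = 0.8
    motif_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.cv_target <= 0:
            raise ConfigurationError("cv_target must be > 0")
        if not 0.0 <= self.rescue_depth <= 1.0:
            raise ConfigurationError("rescue_depth must be in [0, 1]")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_fractions sum to {total}, not 1")
        unknown = set(self.class_fractions) - set(SITE_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown site classes {sorted(unknown)}")


@dataclass
class RnaseqSimConfig:
    """Study conditions for the RNA-seq cascade simulation.

    ``stage_sizes`` are the planted numbers of genes whose deepest satisfied
    cascade gate is stage 1..5 cumulatively, i.e. stage_sizes[k] genes pass
    the gates up to stage k+1 (sizes must be non-increasing).  Planted
    between-condition log2 offsets are large (0.8 for the >0 gates, and 0.13
    — the midpoint of the (0, 0.26) corridor — for the stage-4-only genes)
    relative to the counting noise so stage membership is recoverable.
    """

    n_genes: int = 1000
    genotypes: tuple[str, ...] = GENOTYPES
    treatments: tuple[str, ...] = TREATMENTS
    n_replicates: int = 6
    nb_dispersion: float = 0.005
    library_size: int = 2_000_000
    stage_sizes: tuple[int, ...] = (50, 30, 20, 12, 7)
    n_down: int = 20
    effect_log2: float = 3.0
    offset_log2: float = 0.8
    stage4_corridor_log2: float = 0.13
    planted_base_mean: float = 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if len(self.stage_sizes) != 5:
            raise ConfigurationError("stage_sizes must have 5 entries")
        if any(b > a for a, b in zip(self.stage_sizes, self.stage_sizes[1:])):
            raise ConfigurationError("stage sizes must be non-increasing along the cascade")
        if self.stage_sizes[0] + self.n_down > self.n_genes:
            raise ConfigurationError("planted genes exceed n_genes")


@dataclass
class SyntheticTruth:
    """Ground truth for planted structure; every planted entity appears once."""

    site_class: dict[str, str] = field(default_factory=dict)
    true_log2r_T: dict[str, dict[str, float]] = field(default_factory=dict)
    true_log2r_TN: dict[str, dict[str, float]] = field(default_factory=dict)
    true_rescue: dict[str, float] = field(default_factory=dict)
    motif_flag: dict[str, bool] = field(default_factory=dict)
    gene_stage: dict[str, int] = field(default_factory=dict)
    modules: dict[str, frozenset] = field(default_factory=dict)
    library_factors: dict[str, float] = field(default_factory=dict)

    def sites_of_class(self, label: str) -> list[str]:
        return [s for s, c in self.site_class.items() if c == label]


def _lognormal_sigma(cv: float) -> float:
    # linear-scale CV of a log-normal with log-sd sigma is sqrt(exp(sigma^2)-1)
    return math.sqrt(math.log(1.0 + cv * cv))


def _random_window(rng: np.random.Generator, motif: bool) -> str:
    chars = list(rng.choice(list(AMINO_ACIDS), size=WINDOW_LENGTH))
    center = rng.choice(
        list(CENTER_RESIDUE_PROBS), p=list(CENTER_RESIDUE_PROBS.values())
    )
    chars[CENTER_INDEX] = center
    if motif:
        chars[CENTER_INDEX - 3] = "R"
        chars[CENTER_INDEX + 1] = "P"
    return "".join(chars)


def simulate_phospho_dataset(
    config: PhosphoSimConfig,
) -> tuple[list[PhosphoSiteRecord], SyntheticTruth]:
    """Generate a labelled triple-channel phosphosite dataset.

    Early/late structure: ``early_up`` sites change at the first two
    timepoints only and are insensitive to the inhibitor; the
    ``dependent_late_*`` classes change at the last two timepoints and the
    inhibitor channel removes ``rescue_depth`` of the change;
    ``independent_up`` sites change at every timepoint with no inhibitor
    sensitivity.
    """
    rng = np.random.default_rng(config.seed)
    sigma = _lognormal_sigma(config.cv_target)
    tps = config.timepoints
    early = set(tps[: len(tps) // 2])
    late = set(tps[len(tps) // 2 :])

    # deterministic class assignment by largest-remainder apportionment
    labels: list[str] = []
    fracs = {c: config.class_fractions.get(c, 0.0) for c in SITE_CLASSES}
    counts = {c: int(fracs[c] * config.n_sites) for c in SITE_CLASSES}
    remainder = config.n_sites - sum(counts.values())
    for c in sorted(SITE_CLASSES, key=lambda c: -(fracs[c] * config.n_sites % 1)):
        if remainder <= 0:
            break
        counts[c] += 1
        remainder -= 1
    for c in SITE_CLASSES:
        labels.extend([c] * counts[c])
    rng.shuffle(labels)

    truth = SyntheticTruth()
    records: list[PhosphoSiteRecord] = []
    for i, label in enumerate(labels):
        site_id = f"site{i:05d}"
        protein_id = f"P{i // 3:05d}"  # ~3 sites per protein
        sign = -1.0 if label.endswith("_down") else 1.0
        t_effect: dict[str, float] = {}
        tn_effect: dict[str, float] = {}
        for tp in tps:
            if label == "null":
                eff = 0.0
            elif label == "independent_up":
                eff = config.effect_log2
            elif label == "early_up":
                eff = config.effect_log2 if tp in early else 0.0
            else:  # dependent_late_{up,down}
                eff = sign * config.effect_log2 if tp in late else 0.0
            t_effect[tp] = eff
            if label.startswith("dependent_late") and tp in late:
                tn_effect[tp] = eff * (1.0 - config.rescue_depth)
            else:
                tn_effect[tp] = eff
        motif = bool(
            label.startswith("dependent_late")
            and rng.random() < config.motif_fraction
        )
        window = _random_window(rng, motif)
        rec = PhosphoSiteRecord(
            site_id=site_id,
            protein_id=protein_id,
            gene=f"GENE{i // 3:05d}",
            position=int(rng.integers(8, 800)),
            residue=window[CENTER_INDEX],
            window=window,
            localization_probability=float(rng.uniform(0.85, 1.0)),
        )
        base = 10.0 ** rng.uniform(6.0, 8.0)
        for tp in tps:
            for rep in range(1, config.n_replicates + 1):
                noise = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=3)
                rec.measurements[("vehicle", tp, rep)] = base * noise[0]
                rec.measurements[("stimulus", tp, rep)] = (
                    base * 2.0 ** t_effect[tp] * noise[1]
                )
                rec.measurements[("stimulus_inhibitor", tp, rep)] = (
                    base * 2.0 ** tn_effect[tp] * noise[2]
                )
        records.append(rec)
        truth.site_class[site_id] = label
        truth.true_log2r_T[site_id] = dict(t_effect)
        truth.true_log2r_TN[site_id] = dict(tn_effect)
        truth.true_rescue[site_id] = (
            config.rescue_depth if label.startswith("dependent_late") else 0.0
        )
        truth.motif_flag[site_id] = motif
    return records, truth


def simulate_network(
    n_background: int,
    planted_modules: Sequence[int],
    background_edge_prob: float,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Planted cliques on disjoint node sets embedded in Erdős–Rényi noise.

    Background edges are drawn with probability ``background_edge_prob``
    over every node pair not internal to a planted module, so the cliques
    sit inside the noise rather than as disconnected components.
    """
    if any(size < 3 for size in planted_modules):
        raise ConfigurationError("planted module sizes must be >= 3")
    if not 0.0 <= background_edge_prob < 1.0:
        raise ConfigurationError("background_edge_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    nodes: list[str] = []
    edges: set[tuple[str, str]] = set()
    for m, size in enumerate(planted_modules):
        members = [f"M{m}_{j}" for j in range(size)]
        truth.modules[f"module{m}"] = frozenset(members)
        nodes.extend(members)
        for a in range(size):
            for b in range(a + 1, size):
                edges.add((members[a], members[b]))
    planted_pairs = set(edges)
    nodes.extend(f"B{j}" for j in range(n_background))
    if background_edge_prob > 0:
        n = len(nodes)
        for a in range(n):
            for b in range(a + 1, n):
                pair = (nodes[a], nodes[b])
                if pair in planted_pairs:
                    continue
                if rng.random() < background_edge_prob:
                    edges.add(pair)
    return sorted(edges), truth


def simulate_rnaseq_dataset(
    config: RnaseqSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Negative-binomial counts for the genotype x treatment panel.

    Returns ``(counts, sample_sheet, truth)``.  ``counts`` is genes x
    samples; ``sample_sheet`` maps sample to (genotype, treatment,
    replicate).  ``truth.gene_stage`` records each planted gene's deepest
    cascade stage (1–5; stage -1 marks stimulus-downregulated genes; 0 =
    null).  Stage-k genes satisfy every gate up to stage k in expectation
    and fail the stage-(k+1) gate.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    truth = SyntheticTruth()

    stage_of: dict[str, int] = {g: 0 for g in genes}
    s1, s2, s3, s4, s5 = config.stage_sizes
    order = list(genes)
    rng.shuffle(order)
    planted_up = order[:s1]
    planted_down = order[s1 : s1 + config.n_down]
    for j, g in enumerate(planted_up):
        if j < s5:
            stage_of[g] = 5
        elif j < s4:
            stage_of[g] = 4
        elif j < s3:
            stage_of[g] = 3
        elif j < s2:
            stage_of[g] = 2
        else:
            stage_of[g] = 1
    for g in planted_down:
        stage_of[g] = -1
    truth.gene_stage = stage_of

    base = 10.0 ** rng.uniform(0.5, 3.0, size=config.n_genes)
    for j, g in enumerate(genes):
        if stage_of[g] != 0:
            base[j] = config.planted_base_mean

    # per-gene expected proportion per condition, shaped by planted offsets
    eff, off = config.effect_log2, config.offset_log2
    mean = {}
    for gt in config.genotypes:
        for tr in config.treatments:
            mu = base.copy()
            if tr == "TSZ":
                for j, g in enumerate(genes):
                    st = stage_of[g]
                    if st >= 1:
                        fc1 = eff  # passes |log2fc| > 2 against vehicle
                        d2 = off if st >= 2 else -off
                        d3 = off if st >= 3 else (-off if st == 2 else 0.0)
                        if st >= 5:
                            d4 = off
                        elif st == 4:
                            d4 = config.stage4_corridor_log2
                        elif st == 3:
                            d4 = -0.5
                        else:
                            d4 = 0.0
                        if gt == "WT":
                            mu[j] = base[j] * 2.0 ** fc1
                        elif gt == "KO":
                            mu[j] = base[j] * 2.0 ** (fc1 + d2)
                        elif gt == "S473D":
                            mu[j] = base[j] * 2.0 ** (fc1 + d3)
                        elif gt == "S473A":
                            mu[j] = base[j] * 2.0 ** (fc1 + d3 - d4)
                    elif st == -1 and gt == "WT":
                        mu[j] = base[j] * 2.0 ** (-eff)
            mean[(gt, tr)] = mu

    columns, data = [], []
    for gt in config.genotypes:
        for tr in config.treatments:
            for rep in range(1, config.n_replicates + 1):
                sample = f"{gt}_{tr}_r{rep}"
                lib_factor = float(rng.uniform(0.7, 1.3))
                truth.library_factors[sample] = lib_factor
                mu = mean[(gt, tr)]
                scale = config.library_size * lib_factor / mu.sum()
                mu_scaled = mu * scale
                # NB with mean m and dispersion a: var = m + a m^2
                a = config.nb_dispersion
                n_param = 1.0 / a
                p_param = n_param / (n_param + mu_scaled)
                counts = rng.negative_binomial(n_param, p_param)
                columns.append(sample)
                data.append(counts)
    count_df = pd.DataFrame(
        np.array(data).T, index=genes, columns=columns
    )
    count_df.index.name = "gene"
    sheet = pd.DataFrame(
        [
            {
                "sample": c,
                "genotype": c.rsplit("_", 2)[0],
                "treatment": c.rsplit("_", 2)[1],
                "replicate": int(c.rsplit("_", 2)[2][1:]),
            }
            for c in columns
        ]
    ).set_index("sample")
    return count_df, sheet, truth


def simulate_qpcr(
    fold_changes: Mapping[str, float],
    ct_reference: float = 15.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_replicates: int = 3,
    target_offset: float = 5.0,
) -> pd.DataFrame:
    """Ct table consistent with the 2^-ΔΔCT model.

    For each gene, control ΔCT is ``target_offset`` and treated ΔCT is
    ``target_offset - log2(fold_change)``, so ΔΔCT = -log2(fold) in
    expectation.  Gaussian noise of sd ``noise_sd`` is added to every Ct.
    Rows: (gene, condition, replicate, ct_target, ct_reference).
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for gene, fold in fold_changes.items():
        if fold <= 0:
            raise ConfigurationError(f"fold change for {gene} must be positive")
        for condition in ("control", "treated"):
            shift = 0.0 if condition == "control" else -math.log2(fold)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "replicate": rep,
                        "ct_target": ct_reference
                        + target_offset
                        + shift
                        + rng.normal(0.0, noise_sd),
                        "ct_reference": ct_reference + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
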