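"""Synthetic AP-MS data with known ground truth.

Three generators mirror the three experimental layers of a quantitative
co-purification screen built around a tagged bait:

* :func:`simulate_idirt` — label-swapped SILAC I-DIRT IPs: heavy/light
  peptide intensity tables for forward (heavy = tagged cells) and swapped
  orientations, a bulk-extract protein ratio table parametrizing the
  non-specific null, and per-protein truth labels.
* :func:`simulate_labelfree` — label-free IPs from a wild-type reference
  line and a panel of knockout lines, with group-wise planted log2
  fold-change effects on bait co-enrichment.
* :func:`simulate_prescreen_matrix` — a condition x protein log2-abundance
  matrix with planted condition blocks and not-detected entries, emulating
  an extractant pre-screen heatmap.

Every generator takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

FORWARD = "forward"
SWAP = "swap"
ORIENTATIONS = (FORWARD, SWAP)

CLASSES = ("specific", "intermediate", "nonspecific", "contaminant")

#: Default knockout panel: single, double and quadruple O-mannosyltransferase KOs.
DEFAULT_KO_LINES = ("TMTC2", "TMTC3", "TMTC2/3", "TMTC1-4")

#: Default planted group effects (log2 fold change of bait co-enrichment,
#: KO vs WT) for the five response groups, per KO line, in the order of
#: DEFAULT_KO_LINES.  Group 1 = strongly decreased, Group 3 = unaffected,
#: Group 5 = increased.
DEFAULT_GROUP_EFFECTS: dict[int, tuple[float, float, float, float]] = {
    1: (-3.4, -3.5, -3.7, -2.6),
    2: (-1.7, -1.8, -2.0, -1.3),
    3: (0.0, 0.0, 0.0, 0.0),
    4: (-0.2, 0.2, -0.1, 1.0),
    5: (1.4, 1.7, 1.5, 2.4),
}


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class IdirtSimConfig:
    """Parameters of the label-swapped I-DIRT simulation.

    The defaults describe a 1:1 (w:w) heavy/light cell mix IPed in
    quadruplicate per labeling orientation: mostly non-specific background
    equilibrating to the mix ratio (tagged fraction ~0.5), a minority of
    specific interactors retaining 85-100% tagged-cell signal, an
    intermediate-stability class at 60-80%, and exogenous light-only
    contaminants.
    """

    n_proteins: int = 500
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "specific": 0.10,
            "intermediate": 0.05,
            "nonspecific": 0.80,
            "contaminant": 0.05,
        }
    )
    #: (mean, min) of the per-protein unique-peptide count (Poisson floored at min).
    peptides_per_protein: tuple[float, int] = (5.0, 1)
    n_replicates: int = 4
    #: (mean, sd) of protein log2 intensity.
    base_log2_abundance: tuple[float, float] = (20.0, 2.0)
    #: coefficient of variation of multiplicative (log-normal) channel noise.
    noise_cv: float = 0.2
    #: per-class sampling law for the tagged-cell signal fraction:
    #: ("uniform", lo, hi), ("normal", mean, sd) truncated to [0, 1], or
    #: ("fixed", value).  Contaminants emit light-only signal; their entry
    #: is ignored.
    tagged_fraction_by_class: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "specific": ("uniform", 0.85, 1.0),
            "intermediate": ("uniform", 0.60, 0.80),
            "nonspecific": ("normal", 0.5, 0.05),
            "contaminant": ("fixed", 0.0),
        }
    )
    #: logistic detection model on log2 intensity; midpoint None disables
    #: censoring entirely (all emitted values kept, including exact zeros).
    detection_midpoint: float | None = 14.0
    detection_slope: float = 1.0
    #: probability that a protein carries one aberrant 1000-fold peptide.
    outlier_prob: float = 0.02
    outlier_factor: float = 1000.0
    #: SD of bulk-extract protein ratios around the 0.5 mix fraction.
    bulk_ratio_sd: float = 0.03
    n_bulk_proteins: int = 300
    conditions: Sequence[str] = ("E1",)
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_proportions.get(c, 0.0) for c in CLASSES)
        _check(abs(total - 1.0) <= 1e-9, "class_proportions must sum to 1")
        _check(
            all(0.0 <= v <= 1.0 for v in self.class_proportions.values()),
            "class_proportions entries must lie in [0, 1]",
        )
        _check(self.n_replicates >= 2, "n_replicates must be >= 2")
        _check(self.outlier_factor >= 1.0, "outlier_factor must be >= 1")
        _check(self.n_proteins >= 1, "n_proteins must be >= 1")
        _check(self.noise_cv >= 0.0, "noise_cv must be >= 0")
        _check(len(self.conditions) >= 1, "conditions must be non-empty")


def _lognormal_sigma(cv: float) -> float:
    # sigma of ln-scale noise with the requested coefficient of variation
    return float(np.sqrt(np.log1p(cv**2)))


def _draw_fraction(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=size)
    if kind == "normal":
        return np.clip(rng.normal(law[1], law[2], size=size), 0.0, 1.0)
    if kind == "fixed":
        return np.full(size, float(law[1]))
    raise ValueError(f"unknown tagged-fraction law {law!r}")


def simulate_idirt(
    config: IdirtSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate label-swapped I-DIRT peptide tables with ground truth.

    Returns
    -------
    peptides : DataFrame
        Long channel-level table, both orientations, columns
        ``protein_id, peptide_id, condition_id, orientation, replicate,
        heavy_intensity, light_intensity`` (missing = NaN).
    bulk : DataFrame
        One tagged-cell ratio per protein per orientation from the mixed
        starting material (``protein_id, orientation, ratio``).
    truth : DataFrame
        Per-protein ``class_label`` and ``true_tagged_fraction``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_proteins
    props = np.array([config.class_proportions.get(c, 0.0) for c in CLASSES])
    # deterministic composition: largest-remainder rounding of proportions
    counts = np.floor(props * n).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(props * n - counts))
    counts[order[:remainder]] += 1
    class_labels = np.repeat(CLASSES, counts)
    rng.shuffle(class_labels)

    fractions = np.empty(n)
    for cls in CLASSES:
        mask = class_labels == cls
        fractions[mask] = _draw_fraction(
            rng, config.tagged_fraction_by_class[cls], int(mask.sum())
        )

    base_mu, base_sd = config.base_log2_abundance
    base_log2 = rng.normal(base_mu, base_sd, size=n)
    pep_mean, pep_min = config.peptides_per_protein
    n_peps = np.maximum(rng.poisson(pep_mean, size=n), pep_min)

    sigma = _lognormal_sigma(config.noise_cv)
    rows: list[pd.DataFrame] = []
    prot_ids = np.array([f"P{i:04d}" for i in range(n)])
    has_outlier = rng.random(n) < config.outlier_prob

    for i in range(n):
        npep = int(n_peps[i])
        total = 2.0 ** base_log2[i]
        # peptide ionization efficiency, shared by both channels
        pep_eff = (
            np.exp(rng.normal(0.0, sigma, size=npep)) if sigma > 0 else np.ones(npep)
        )
        f = fractions[i]
        cls = class_labels[i]
        out_pep = rng.integers(npep) if has_outlier[i] else -1
        out_orient = rng.integers(2) if has_outlier[i] else -1
        out_rep = rng.integers(config.n_replicates) if has_outlier[i] else -1

        for cond in config.conditions:
            for oi, orient in enumerate(ORIENTATIONS):
                for rep in range(1, config.n_replicates + 1):
                    eps_t = (
                        np.exp(rng.normal(0.0, sigma, size=npep))
                        if sigma > 0
                        else np.ones(npep)
                    )
                    eps_w = (
                        np.exp(rng.normal(0.0, sigma, size=npep))
                        if sigma > 0
                        else np.ones(npep)
                    )
                    if cls == "contaminant":
                        light = total * pep_eff * eps_w
                        heavy = np.full(npep, np.nan)
                    else:
                        tagged = f * total * pep_eff * eps_t
                        wild = (1.0 - f) * total * pep_eff * eps_w
                        if orient == FORWARD:
                            heavy, light = tagged, wild
                        else:
                            heavy, light = wild, tagged
                    if out_pep >= 0 and oi == out_orient and rep == out_rep + 1:
                        heavy = heavy.copy()
                        light = light.copy()
                        heavy[out_pep] *= config.outlier_factor
                        light[out_pep] *= config.outlier_factor
                    rows.append(
                        pd.DataFrame(
                            {
                                "protein_id": prot_ids[i],
                                "peptide_id": [
                                    f"{prot_ids[i]}_pep{j}" for j in range(npep)
                                ],
                                "condition_id": cond,
                                "orientation": orient,
                                "replicate": rep,
                                "heavy_intensity": heavy,
                                "light_intensity": light,
                            }
                        )
                    )

    peptides = pd.concat(rows, ignore_index=True)

    if config.detection_midpoint is not None:
        for col in ("heavy_intensity", "light_intensity"):
            x = peptides[col].to_numpy(float)
            with np.errstate(divide="ignore"):
                lx = np.where(x > 0, np.log2(np.where(x > 0, x, 1.0)), -np.inf)
            p = expit(config.detection_slope * (lx - config.detection_midpoint))
            detected = rng.random(len(x)) < p
            x = np.where(detected, x, np.nan)
            peptides[col] = x

    bulk_ids = [f"B{i:04d}" for i in range(config.n_bulk_proteins)]
    bulk = pd.DataFrame(
        [
            {"protein_id": pid, "orientation": orient, "ratio": r}
            for orient in ORIENTATIONS
            for pid, r in zip(
                bulk_ids,
                np.clip(
                    rng.normal(0.5, config.bulk_ratio_sd, size=len(bulk_ids)), 0.0, 1.0
                ),
            )
        ]
    )

    truth = pd.DataFrame(
        {
            "protein_id": prot_ids,
            "class_label": class_labels,
            "true_tagged_fraction": fractions,
        }
    )
    return peptides, bulk, truth


@dataclass
class LabelFreeSimConfig:
    """Parameters of the label-free KO-panel IP simulation.

    Proteins belong to one of five response groups; each group has a
    planted log2 fold-change of bait co-enrichment per KO line (defaults
    are the study-scale group medians in :data:`DEFAULT_GROUP_EFFECTS`).
    The bait itself is planted flat across all lines.
    """

    n_per_group: int = 50
    planted_effects: Mapping[int, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    ko_lines: Sequence[str] = DEFAULT_KO_LINES
    n_conditions: int = 6
    n_replicates: int = 4
    #: residual SD per sample on the log2 scale.
    noise_sd: float = 0.3
    bait_id: str = "CDH1"
    #: between-condition SD of each protein's planted effect.
    condition_effect_sd: float = 0.1
    #: (mean, sd) of protein baseline log2 abundance.
    baseline_log2: tuple[float, float] = (18.0, 1.5)
    bait_log2: float = 22.0
    #: mean of the (2 + Poisson) unique-peptide count per protein.
    peptide_count_mean: float = 4.0
    #: proteins emitted with a single unique peptide, to exercise the
    #: evidence filter; they carry no group label.
    n_low_evidence: int = 0
    #: optional logistic dropout on log2 abundance; None = fully observed.
    dropout_midpoint: float | None = None
    dropout_slope: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_conditions >= 1, "n_conditions must be >= 1")
        _check(self.noise_sd >= 0.0, "noise_sd must be >= 0")
        _check(self.n_replicates >= 2, "n_replicates must be >= 2")
        for g, eff in self.planted_effects.items():
            _check(
                len(eff) == len(self.ko_lines),
                f"planted_effects[{g}] must have one entry per KO line",
            )


WT_LINE = "WT"


def simulate_labelfree(
    config: LabelFreeSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate label-free IP abundance tables across WT and KO lines.

    Returns ``(abundance, truth)``.  ``abundance`` is a long table with
    columns ``protein_id, cell_line, condition_id, replicate,
    log2_abundance, n_unique_peptides``; ``truth`` carries ``group_label``
    and one ``planted_<ko>`` column per KO line.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = sorted(config.planted_effects)
    ko_lines = list(config.ko_lines)
    conditions = [f"E{c+1}" for c in range(config.n_conditions)]

    records: list[dict] = []
    truth_rows: list[dict] = []

    prot_specs: list[tuple[str, int | None, np.ndarray, int]] = []
    for g in groups:
        eff = np.asarray(config.planted_effects[g], float)
        for k in range(config.n_per_group):
            pid = f"G{g}_{k:03d}"
            npep = 2 + int(rng.poisson(config.peptide_count_mean))
            prot_specs.append((pid, g, eff, npep))
    for k in range(config.n_low_evidence):
        prot_specs.append((f"LOWEV_{k:03d}", None, np.zeros(len(ko_lines)), 1))
    # the bait: planted flat, high abundance
    prot_specs.append((config.bait_id, None, np.zeros(len(ko_lines)), 30))

    for pid, g, eff, npep in prot_specs:
        base = (
            config.bait_log2
            if pid == config.bait_id
            else rng.normal(*config.baseline_log2)
        )
        # per-condition realisation of the planted effect for each KO
        cond_eff = {
            (ko, cond): eff[j]
            + (
                rng.normal(0.0, config.condition_effect_sd)
                if config.condition_effect_sd > 0
                else 0.0
            )
            for j, ko in enumerate(ko_lines)
            for cond in conditions
        }
        for line in [WT_LINE] + ko_lines:
            for cond in conditions:
                for rep in range(1, config.n_replicates + 1):
                    mu = base if line == WT_LINE else base + cond_eff[(line, cond)]
                    val = mu + (
                        rng.normal(0.0, config.noise_sd)
                        if config.noise_sd > 0
                        else 0.0
                    )
                    records.append(
                        {
                            "protein_id": pid,
                            "cell_line": line,
                            "condition_id": cond,
                            "replicate": rep,
                            "log2_abundance": val,
                            "n_unique_peptides": npep,
                        }
                    )
        row = {
            "protein_id": pid,
            "group_label": g if g is not None else pd.NA,
        }
        for j, ko in enumerate(ko_lines):
            row[f"planted_{ko}"] = eff[j] if pid != config.bait_id else 0.0
        truth_rows.append(row)

    abundance = pd.DataFrame.from_records(records)

    if config.dropout_midpoint is not None:
        x = abundance["log2_abundance"].to_numpy(float)
        keep = rng.random(len(x)) < expit(
            config.dropout_slope * (x - config.dropout_midpoint)
        )
        keep |= (abundance["protein_id"] == config.bait_id).to_numpy()
        abundance.loc[~keep, "log2_abundance"] = np.nan

    truth = pd.DataFrame(truth_rows)
    return abundance, truth


def simulate_prescreen_matrix(
    n_conditions: int,
    n_proteins: int,
    block_structure: Sequence[Sequence[int]],
    detection_prob_by_block: Sequence[float],
    seed: int = 0,
    noise_sd: float = 0.3,
    cross_detection_prob: float = 0.0,
    abundance_sd: float = 2.0,
) -> pd.DataFrame:
    """Simulate a condition x protein log2-abundance matrix with blocks.

    ``block_structure`` partitions condition indices ``0..n_conditions-1``
    into groups sharing a detection/abundance profile.  Proteins are split
    evenly across blocks; a block's proteins are detected in its own
    conditions with the block's detection probability and elsewhere with
    ``cross_detection_prob`` (cross values carry no protein signal, so
    between-block correlation is ~0).  Not-detected entries are NaN,
    distinct from any numeric abundance.
    """
    _check(len(block_structure) >= 1, "block_structure must be non-empty")
    _check(
        len(detection_prob_by_block) == len(block_structure),
        "one detection probability per block required",
    )
    flat = sorted(c for blk in block_structure for c in blk)
    _check(
        flat == list(range(n_conditions)),
        "block_structure must partition the condition indices",
    )
    _check(all(len(b) > 0 for b in block_structure), "empty block")

    rng = np.random.default_rng(seed)
    cond_names = [f"C{c+1:02d}" for c in range(n_conditions)]
    prot_names = [f"P{j:04d}" for j in range(n_proteins)]
    mat = np.full((n_conditions, n_proteins), np.nan)

    block_of_protein = np.arange(n_proteins) % len(block_structure)
    prot_mean = rng.normal(18.0, abundance_sd, size=n_proteins)
    grand = 18.0

    for b, (conds, pdet) in enumerate(zip(block_structure, detection_prob_by_block)):
        members = np.where(block_of_protein == b)[0]
        for c in range(n_conditions):
            in_block = c in conds
            prob = pdet if in_block else cross_detection_prob
            det = rng.random(len(members)) < prob
            vals = np.where(
                in_block,
                prot_mean[members] + rng.normal(0.0, noise_sd, len(members)),
                rng.normal(grand, abundance_sd, len(members)),
            )
            mat[c, members[det]] = vals[det]

    df = pd.DataFrame(mat, index=cond_names, columns=prot_names)
    # every condition must detect at least one protein
    for c in range(n_conditions):
        if np.all(np.isnan(mat[c])):
            j = int(rng.integers(n_proteins))
            df.iloc[c, j] = prot_mean[j]
    return df
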