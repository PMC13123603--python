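"""I-DIRT specificity calling for label-swapped SILAC IP-MS.

In an I-DIRT experiment, isotope-labeled tagged cells and unlabeled
wild-type cells are mixed 1:1 before lysis, so a protein's tagged-cell
signal fraction ``PEP/(PEP + pep)`` reads out where its association with
the bait formed: in-cell interactors retain ~0.8-1.0 tagged signal,
post-lysis background equilibrates to the ~0.5 mix ratio, and exogenous
contaminants are light-only.  The per-protein, per-replicate ratio is the
median over unique peptides of the per-peptide tagged fraction — medians
resist the occasional aberrantly quantified peptide that distorts
summed protein-level ratios.

A protein is called a specific interactor when (i) a default-prior Bayes
factor for "mean ratio exceeds the bulk-extract median" clears a cutoff
(default 3), and (ii) its (forward, swap) mean-ratio point lies inside a
validation ellipse centred at (1, 1) whose semi-axes are set from the
median and SD of bulk-extract protein ratios in each orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from . import quantify
from .quantify import TAGGED, WILDTYPE, ExperimentDesign, ImputationParams
from .simulate import FORWARD, SWAP, ORIENTATIONS

RATIO_KEY = ["protein_id", "condition_id", "orientation", "replicate"]


def compute_replicate_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate peptide-median tagged-cell signal fractions.

    For each protein x condition x orientation x replicate, the ratio is
    the median over unique peptides of ``tagged / (tagged + wildtype)``.
    Peptide cells where either channel is missing, or the two channels sum
    to zero, are excluded (their fraction is undefined); a replicate with
    no usable peptide emits no row.
    """
    t = table.copy()
    total = t[TAGGED] + t[WILDTYPE]
    ok = t[TAGGED].notna() & t[WILDTYPE].notna() & (total > 0)
    t = t.loc[ok]
    if t.empty:
        return pd.DataFrame(columns=RATIO_KEY + ["ratio", "n_peptides_used"])
    t = t.assign(_frac=t[TAGGED] / (t[TAGGED] + t[WILDTYPE]))
    out = (
        t.groupby(RATIO_KEY, sort=False)["_frac"]
        .agg(ratio="median", n_peptides_used="size")
        .reset_index()
    )
    return out


def protein_level_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Abundance-weighted protein-level ratio: sum(PEP) / sum(PEP + pep).

    Comparator only — a single channel-asymmetric high-abundance peptide
    dominates the sums, which is exactly why calling uses the peptide
    median instead.
    """
    t = table.copy()
    total = t[TAGGED] + t[WILDTYPE]
    ok = t[TAGGED].notna() & t[WILDTYPE].notna() & (total > 0)
    t = t.loc[ok]
    if t.empty:
        return pd.DataFrame(columns=RATIO_KEY + ["ratio", "n_peptides_used"])
    g = t.groupby(RATIO_KEY, sort=False)
    out = g.agg(
        _tag=(TAGGED, "sum"), _tot=(TAGGED, "size"), _wt=(WILDTYPE, "sum")
    ).reset_index()
    out["ratio"] = out["_tag"] / (out["_tag"] + out["_wt"])
    out["n_peptides_used"] = out["_tot"]
    return out.drop(columns=["_tag", "_wt", "_tot"])


@dataclass
class BulkMixStats:
    """Median and SD of bulk-extract protein ratios per orientation."""

    stats: dict[str, tuple[float, float, int]]  # orientation -> (m, s, n)

    def median(self, orientation: str) -> float:
        return self.stats[orientation][0]

    def sd(self, orientation: str) -> float:
        return self.stats[orientation][1]

    @property
    def pooled_null(self) -> float:
        return float(np.mean([self.stats[o][0] for o in ORIENTATIONS]))


def compute_bulk_stats(bulk: pd.DataFrame, min_proteins: int = 10) -> BulkMixStats:
    """Median/SD of the bulk-mix protein ratio distribution per orientation."""
    out: dict[str, tuple[float, float, int]] = {}
    for orient in ORIENTATIONS:
        sub = bulk.loc[bulk["orientation"] == orient, "ratio"].dropna()
        if len(sub) < min_proteins:
            raise ValueError(
                f"orientation {orient!r}: {len(sub)} bulk proteins, "
                f"need >= {min_proteins}"
            )
        out[orient] = (float(sub.median()), float(sub.std(ddof=1)), len(sub))
    return BulkMixStats(out)


class BayesFactor(NamedTuple):
    bf: float
    degenerate: str | None = None


def bayes_factor_specific(
    ratios: Sequence[float],
    null_value: float,
    prior_scale: float = 0.707,
    one_sided: bool = True,
) -> BayesFactor:
    """Default-prior one-sample Bayes factor against a point null.

    Tests H1 "the mean ratio exceeds ``null_value``" against H0 "equals
    it", placing a Cauchy prior (scale ``prior_scale``) on the
    standardized effect and integrating the noncentral-t likelihood
    numerically; with ``one_sided`` the prior is folded onto positive
    effects.  BF10 > 1 favours enrichment above the null.

    Degenerate zero-variance samples return ``bf = 0`` (at the null) or
    ``bf = inf`` (away from it), flagged in ``degenerate``.
    """
    x = np.asarray(ratios, float)
    if len(x) < 2:
        raise ValueError(f"need >= 2 replicate ratios, got {len(x)}")
    n = len(x)
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0.0:
        if math.isclose(mean, null_value, abs_tol=1e-12):
            return BayesFactor(0.0, "zero_variance_at_null")
        return BayesFactor(math.inf, "zero_variance_off_null")
    t = (mean - null_value) / (sd / math.sqrt(n))
    # beyond |t| ~ 40 the evidence is astronomically decisive and the
    # noncentral-t evaluation becomes unstable/slow; evaluate at the cap
    # (keeps BF10 monotone non-decreasing in |t|, constant past the cap)
    t = float(np.clip(t, -40.0, 40.0))
    nu = n - 1
    like0 = stats.t.pdf(t, nu)
    fold = 2.0 if one_sided else 1.0

    def integrand(delta: float) -> float:
        return (
            stats.nct.pdf(t, nu, delta * math.sqrt(n))
            * fold
            * stats.cauchy.pdf(delta, scale=prior_scale)
        )

    # the noncentral-t likelihood peaks near delta = t/sqrt(n); integrate
    # piecewise around it so quad cannot step over a sharp peak
    peak = t / math.sqrt(n)
    lo = 0.0 if one_sided else -np.inf
    cuts = sorted({c for c in (0.0, peak) if one_sided is False or c >= 0.0})
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        num = 0.0
        edges = ([lo] if not cuts or cuts[0] != lo else []) + cuts + [np.inf]
        for a, b in zip(edges[:-1], edges[1:]):
            if a == b:
                continue
            num += integrate.quad(integrand, a, b, limit=200)[0]
    return BayesFactor(float(num / like0))


@dataclass
class EllipseSpec:
    """Validation ellipse centred at (1, 1) in the forward-vs-swap plane."""

    a_forward: float
    a_swap: float
    k: float = 3.0
    center: tuple[float, float] = (1.0, 1.0)


def build_ellipse(stats_: BulkMixStats, k: float = 3.0) -> EllipseSpec:
    """Size the validation ellipse from the bulk ratio cloud.

    Each semi-axis is ``1 - (m + k*s)``: the boundary sits ``k`` bulk SDs
    above the bulk (non-specific) median in that orientation, clipped to
    at most 1.  An axis that is not positive means the bulk cloud reaches
    the (1, 1) corner; reduce ``k``.
    """
    axes = {}
    for orient in ORIENTATIONS:
        m, s = stats_.median(orient), stats_.sd(orient)
        a = 1.0 - (m + k * s)
        if a <= 0:
            raise ValueError(
                f"orientation {orient!r}: ellipse semi-axis {a:.4f} <= 0 "
                f"(bulk median {m:.3f}, SD {s:.3f}); use a smaller k"
            )
        axes[orient] = min(a, 1.0)
    return EllipseSpec(a_forward=axes[FORWARD], a_swap=axes[SWAP], k=k)


def ellipse_membership(
    mean_ratio_forward: float, mean_ratio_swap: float, ellipse: EllipseSpec
) -> bool:
    """True iff the (forward, swap) mean-ratio point lies inside the ellipse."""
    rf, rs = mean_ratio_forward, mean_ratio_swap
    if not (np.isfinite(rf) and np.isfinite(rs)):
        return False
    d = ((1.0 - rf) / ellipse.a_forward) ** 2 + ((1.0 - rs) / ellipse.a_swap) ** 2
    return bool(d <= 1.0)


def ellipse_distance(
    mean_ratio_forward: float, mean_ratio_swap: float, ellipse: EllipseSpec
) -> float:
    """Normalized squared ellipse coordinate (<= 1 means inside)."""
    rf, rs = mean_ratio_forward, mean_ratio_swap
    if not (np.isfinite(rf) and np.isfinite(rs)):
        return float("inf")
    return float(
        ((1.0 - rf) / ellipse.a_forward) ** 2 + ((1.0 - rs) / ellipse.a_swap) ** 2
    )


@dataclass
class CategoryThresholds:
    """Tagged-fraction bands for the interactor categories.

    Hardened versions of the canonical I-DIRT bands: specific interactors
    ~80-100% tagged in both orientations, intermediate-stability 60-80%,
    equilibrated background 40-60%, exogenous contaminants light-dominant
    (forward <= 0.2 with swap >= 0.8).
    """

    specific_min: float = 0.8
    intermediate_min: float = 0.6
    nonspecific_min: float = 0.4
    nonspecific_max: float = 0.6
    contaminant_forward_max: float = 0.2
    contaminant_swap_min: float = 0.8


_BAND_CENTERS = {
    "specific": (0.9, 0.9),
    "intermediate": (0.7, 0.7),
    "nonspecific": (0.5, 0.5),
    "contaminant": (0.1, 0.9),
}


def classify_category(
    mean_ratio_forward: float,
    mean_ratio_swap: float,
    thresholds: CategoryThresholds | None = None,
) -> tuple[str, str]:
    """Assign an interactor category from the two orientation mean ratios.

    Returns ``(category, nearest)``; for points outside every band the
    category is ``"unclassified"`` and ``nearest`` records the closest
    band centre.  A missing forward ratio with swap >= the contaminant
    bound is the light-only contaminant signature (such proteins have no
    tagged-channel evidence in the forward run).
    """
    th = thresholds or CategoryThresholds()
    rf, rs = mean_ratio_forward, mean_ratio_swap
    if not np.isfinite(rf):
        if np.isfinite(rs) and rs >= th.contaminant_swap_min:
            return "contaminant", "contaminant"
        return "unclassified", "contaminant"
    if rf >= th.specific_min and rs >= th.specific_min:
        return "specific", "specific"
    if (
        th.intermediate_min <= rf < th.specific_min
        and th.intermediate_min <= rs < th.specific_min
    ):
        return "intermediate", "intermediate"
    if (
        th.nonspecific_min < rf < th.nonspecific_max
        and th.nonspecific_min < rs < th.nonspecific_max
    ):
        return "nonspecific", "nonspecific"
    if rf <= th.contaminant_forward_max and rs >= th.contaminant_swap_min:
        return "contaminant", "contaminant"
    nearest = min(
        _BAND_CENTERS,
        key=lambda c: (rf - _BAND_CENTERS[c][0]) ** 2
        + (rs - _BAND_CENTERS[c][1]) ** 2,
    )
    return "unclassified", nearest


def call_specific(
    ratios: pd.DataFrame,
    bulk_stats: BulkMixStats,
    ellipse: EllipseSpec,
    bf_cutoff: float = 3.0,
    pool_orientations: bool = True,
    prior_scale: float = 0.707,
    thresholds: CategoryThresholds | None = None,
) -> pd.DataFrame:
    """Per-protein, per-condition specificity calls.

    ``is_specific`` requires both the Bayes factor (pooled forward+swap
    replicate ratios against the pooled bulk null by default, or both
    per-orientation tests when ``pool_orientations=False``) to reach
    ``bf_cutoff`` and the orientation-mean point to fall inside the
    validation ellipse.  All component quantities are retained for audit.
    """
    rows = []
    for (pid, cond), grp in ratios.groupby(["protein_id", "condition_id"], sort=True):
        fwd = grp.loc[grp["orientation"] == FORWARD, "ratio"].to_numpy(float)
        swp = grp.loc[grp["orientation"] == SWAP, "ratio"].to_numpy(float)
        mean_f = float(np.mean(fwd)) if len(fwd) else float("nan")
        mean_s = float(np.mean(swp)) if len(swp) else float("nan")

        degenerate = None
        if pool_orientations:
            pooled = np.concatenate([fwd, swp])
            if len(pooled) >= 2:
                res = bayes_factor_specific(
                    pooled, bulk_stats.pooled_null, prior_scale=prior_scale
                )
                bf, degenerate = res.bf, res.degenerate
            else:
                bf = float("nan")
            passes_bf = np.isfinite(bf) and bf >= bf_cutoff or bf == math.inf
        else:
            bfs = []
            for orient, sample in ((FORWARD, fwd), (SWAP, swp)):
                if len(sample) >= 2:
                    res = bayes_factor_specific(
                        sample, bulk_stats.median(orient), prior_scale=prior_scale
                    )
                    bfs.append(res.bf)
                    degenerate = degenerate or res.degenerate
                else:
                    bfs.append(float("nan"))
            bf = float(np.nanmin(bfs)) if bfs else float("nan")
            passes_bf = all(
                (np.isfinite(b) and b >= bf_cutoff) or b == math.inf for b in bfs
            )

        in_ell = ellipse_membership(mean_f, mean_s, ellipse)
        category, nearest = classify_category(mean_f, mean_s, thresholds)
        rows.append(
            {
                "protein_id": pid,
                "condition_id": cond,
                "mean_ratio_forward": mean_f,
                "mean_ratio_swap": mean_s,
                "n_replicates_forward": len(fwd),
                "n_replicates_swap": len(swp),
                "bayes_factor": bf,
                "bf_degenerate": degenerate,
                "passes_bf": bool(passes_bf),
                "in_ellipse": in_ell,
                "ellipse_distance": ellipse_distance(mean_f, mean_s, ellipse),
                "is_specific": bool(passes_bf and in_ell),
                "category": category,
                "nearest_category": nearest,
            }
        )
    return pd.DataFrame(rows)


def aggregate_conditions(calls: pd.DataFrame) -> pd.DataFrame:
    """Pool specific calls across extractant conditions.

    The interactome is the union of proteins specific in at least one
    condition; ``n_conditions_specific`` counts the conditions where each
    passed, sorted by that frequency (descending) then accession.
    """
    spec = calls.loc[calls["is_specific"]]
    if spec.empty:
        return pd.DataFrame(
            columns=["protein_id", "n_conditions_specific", "conditions"]
        )
    agg = (
        spec.groupby("protein_id")["condition_id"]
        .agg(n_conditions_specific="nunique", conditions=lambda s: ",".join(sorted(set(s))))
        .reset_index()
    )
    return agg.sort_values(
        ["n_conditions_specific", "protein_id"], ascending=[False, True]
    ).reset_index(drop=True)


class IdirtSpecificity:
    """Model: I-DIRT specificity calling from channel-level peptide tables.

    Parameters
    ----------
    peptides : DataFrame
        Long channel-level table (``protein_id, peptide_id, condition_id,
        orientation, replicate, heavy_intensity, light_intensity``).
    bulk : DataFrame
        Bulk-extract protein ratio table (``protein_id, orientation,
        ratio``) from the mixed starting material.
    design : ExperimentDesign, optional
        Channel-to-cell-line mapping; defaults to heavy=tagged forward.

    ``fit()`` runs orientation mapping, the tagged-evidence filter, both
    imputation passes, peptide-median ratio computation, and Bayes
    factor + ellipse calling, returning :class:`IdirtSpecificityResults`.
    """

    def __init__(
        self,
        peptides: pd.DataFrame,
        bulk: pd.DataFrame,
        design: ExperimentDesign | None = None,
        *,
        bf_cutoff: float = 3.0,
        ellipse_k: float = 3.0,
        min_tagged_replicates: int = 2,
        imputation: ImputationParams | None = None,
        pool_orientations: bool = True,
        prior_scale: float = 0.707,
        thresholds: CategoryThresholds | None = None,
    ) -> None:
        self.peptides = peptides
        self.bulk = bulk
        self.design = design or ExperimentDesign()
        self.bf_cutoff = bf_cutoff
        self.ellipse_k = ellipse_k
        self.min_tagged_replicates = min_tagged_replicates
        self.imputation = imputation or ImputationParams(deterministic_mode=True)
        self.pool_orientations = pool_orientations
        self.prior_scale = prior_scale
        self.thresholds = thresholds or CategoryThresholds()

    def fit(self) -> "IdirtSpecificityResults":
        oriented = quantify.map_channels(self.peptides, self.design)
        filtered, filter_log = quantify.filter_low_evidence(
            oriented, self.min_tagged_replicates
        )
        imputed, impute_log = quantify.impute(filtered, self.imputation)
        ratios = compute_replicate_ratios(imputed)
        bulk_stats = compute_bulk_stats(self.bulk)
        ellipse = build_ellipse(bulk_stats, self.ellipse_k)
        calls = call_specific(
            ratios,
            bulk_stats,
            ellipse,
            bf_cutoff=self.bf_cutoff,
            pool_orientations=self.pool_orientations,
            prior_scale=self.prior_scale,
            thresholds=self.thresholds,
        )
        return IdirtSpecificityResults(
            model=self,
            calls=calls,
            ratios=ratios,
            bulk_stats=bulk_stats,
            ellipse=ellipse,
            filter_log=filter_log,
            imputation_log=impute_log,
        )


@dataclass
class IdirtSpecificityResults:
    """Fitted I-DIRT specificity calls with all audit intermediates."""

    model: IdirtSpecificity
    calls: pd.DataFrame
    ratios: pd.DataFrame
    bulk_stats: BulkMixStats
    ellipse: EllipseSpec
    filter_log: pd.DataFrame
    imputation_log: pd.DataFrame
    _interactome: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def interactome(self) -> pd.DataFrame:
        """Proteins specific in >= 1 condition with identification frequency."""
        if self._interactome is None:
            self._interactome = aggregate_conditions(self.calls)
        return self._interactome

    def summary(self) -> str:
        calls = self.calls
        n_prot = calls["protein_id"].nunique()
        n_spec = int(calls["is_specific"].sum())
        lines = [
            "I-DIRT specificity calling",
            "=" * 42,
            f"proteins scored:            {n_prot}",
            f"condition calls:            {len(calls)}",
            f"specific calls:             {n_spec}",
            f"interactome size (union):   {len(self.interactome)}",
            f"Bayes factor cutoff:        {self.model.bf_cutoff}",
            f"ellipse semi-axes (f, s):   "
            f"({self.ellipse.a_forward:.3f}, {self.ellipse.a_swap:.3f})  "
            f"[k = {self.ellipse.k}]",
            "",
            "category counts (per protein x condition):",
        ]
        for cat, cnt in calls["category"].value_counts().items():
            lines.append(f"  {cat:<14} {cnt}")
        by_cond = calls.groupby("condition_id")["is_specific"].sum()
        lines.append("")
        lines.append("specific calls per condition:")
        for cond, cnt in by_cond.items():
            lines.append(f"  {cond:<10} {int(cnt)}")
        return "\n".join(lines)

    def plot_ratio_scatter(self, ax=None):
        """Forward-vs-swap mean-ratio scatter with the validation ellipse."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse as MplEllipse

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        calls = self.calls
        colors = calls["is_specific"].map({True: "crimson", False: "grey"})
        ax.scatter(
            calls["mean_ratio_forward"],
            calls["mean_ratio_swap"],
            c=colors,
            s=12,
            alpha=0.6,
        )
        ax.add_patch(
            MplEllipse(
                (1, 1),
                2 * self.ellipse.a_forward,
                2 * self.ellipse.a_swap,
                fill=False,
                edgecolor="black",
                linestyle="--",
            )
        )
        ax.set_xlabel("mean tagged fraction (forward)")
        ax.set_ylabel("mean tagged fraction (swap)")
        ax.set_xlim(-0.05, 1.05)
        ax.set_ylim(-0.05, 1.05)
        return ax
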