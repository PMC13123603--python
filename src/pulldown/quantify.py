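"""Peptide-level quantitation preprocessing for label-swapped SILAC IPs.

The raw unit is one peptide x replicate record with heavy- and
light-channel MS1 intensities.  This module (1) re-expresses channels as
tagged-cell vs wild-type-cell intensities according to the labeling
orientation, (2) applies the tagged-channel evidence filter, and
(3) imputes missing intensities with two complementary methods:

* method 3.1 — left-censored draw: a peptide whose wild-type channel is
  observed in fewer than two replicates has its missing wild-type values
  replaced by ``2**u`` with ``u ~ Uniform[mu - 3*sigma, mu - 2*sigma]``,
  where mu and sigma are the mean and SD of all observed log2 intensities
  within that replicate (each replicate uses its own mu, sigma).  This is
  the standard treatment of intensity-dependent (MNAR) dropout: a value
  missing nearly everywhere is presumed below the detection floor.
* method 4.1 — partial-missingness draw based on the spread of observed
  replicate measurements: per peptide-channel, the relative range
  ``delta = (Int_max - Int_min) / mean_over_peptides(Int_max - Int_min)``
  is computed; a new deviate ``delta_new ~ Normal(u_delta,
  2*sd_delta / mean_corr)`` is drawn per missing cell (``mean_corr`` =
  average pairwise correlation of replicate intensity columns over
  complete rows) and the cell is filled with
  ``mean(Int_other) * |1 + delta_new|``.

Method 3.1 operates on the log2 scale (its bounds are only meaningful
there); method 4.1 operates on raw intensities, exactly as its formulas
are written.  ``deterministic_mode`` replaces every random draw by its
distribution mean (3.1: ``mu - 2.5*sigma``; 4.1: ``delta_new = u_delta``)
for exactly reproducible pipelines and tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import FORWARD, SWAP

TAGGED = "tagged_intensity"
WILDTYPE = "wildtype_intensity"

#: columns identifying one peptide series across replicates
PEPTIDE_KEY = ["protein_id", "peptide_id", "condition_id", "orientation"]
#: columns identifying one MS run (replicate sample)
REPLICATE_KEY = ["condition_id", "orientation", "replicate"]


@dataclass
class ExperimentDesign:
    """Channel-to-cell-line mapping per labeling orientation."""

    #: orientation -> {"heavy": "tagged"|"wildtype", "light": ...}
    channel_map: dict[str, dict[str, str]] = field(
        default_factory=lambda: {
            FORWARD: {"heavy": "tagged", "light": "wildtype"},
            SWAP: {"heavy": "wildtype", "light": "tagged"},
        }
    )
    n_replicates: int = 4
    bait_id: str = "CDH1"
    conditions: tuple[str, ...] = ("E1",)

    def validate(self) -> None:
        for orient, m in self.channel_map.items():
            if sorted(m) != ["heavy", "light"] or sorted(m.values()) != [
                "tagged",
                "wildtype",
            ]:
                raise ValueError(
                    f"orientation {orient!r}: channel map must be a bijection "
                    "{heavy, light} -> {tagged, wildtype}"
                )


@dataclass
class ImputationParams:
    """Configuration and audit state for the two imputation methods."""

    deterministic_mode: bool = False
    seed: int | None = None
    #: scope over which method-4.1 delta statistics are pooled:
    #: "table" (default) or "condition" (per condition x orientation).
    scope: str = "table"
    #: filled in by the imputation passes for auditing; if all three
    #: method-4.1 statistics are supplied up front they are used as given
    #: instead of being estimated from the table.
    replicate_stats: pd.DataFrame | None = None
    u_delta: float | None = None
    sd_delta: float | None = None
    mean_corr: float | None = None

    @property
    def has_preset_stats(self) -> bool:
        return all(
            v is not None for v in (self.u_delta, self.sd_delta, self.mean_corr)
        )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def map_channels(table: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    """Re-express heavy/light channels as tagged/wild-type intensities.

    Forward rows map heavy -> tagged and light -> wild-type; swapped rows
    the reverse.  Missingness is preserved and row count unchanged.
    """
    design.validate()
    unknown = set(table["orientation"].unique()) - set(design.channel_map)
    if unknown:
        bad = table.index[table["orientation"].isin(unknown)][:5].tolist()
        raise ValueError(
            f"unknown orientation label(s) {sorted(unknown)} (rows {bad})"
        )
    out = table.copy()
    tagged = np.empty(len(table))
    wild = np.empty(len(table))
    for orient, cmap in design.channel_map.items():
        mask = (table["orientation"] == orient).to_numpy()
        heavy = table["heavy_intensity"].to_numpy(float)
        light = table["light_intensity"].to_numpy(float)
        t_src = heavy if cmap["heavy"] == "tagged" else light
        w_src = light if cmap["light"] == "wildtype" else heavy
        tagged[mask] = t_src[mask]
        wild[mask] = w_src[mask]
    out[TAGGED] = tagged
    out[WILDTYPE] = wild
    return out.drop(columns=["heavy_intensity", "light_intensity"])


def filter_low_evidence(
    table: pd.DataFrame, min_tagged_replicates: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop peptides observed in too few replicates of the tagged sample.

    A peptide (within protein x condition x orientation) is retained iff
    its tagged-channel intensity is present in at least
    ``min_tagged_replicates`` replicates.  Returns ``(kept, log)`` where
    ``log`` lists each removed peptide with its observed-replicate count.
    """
    if table.empty:
        return table.copy(), pd.DataFrame(
            columns=PEPTIDE_KEY + ["n_tagged_observed"]
        )
    obs = (
        table.assign(_obs=table[TAGGED].notna())
        .groupby(PEPTIDE_KEY, sort=False)["_obs"]
        .sum()
    )
    bad = obs[obs < min_tagged_replicates]
    log = bad.rename("n_tagged_observed").reset_index()
    if bad.empty:
        return table.copy(), log
    idx = table.set_index(PEPTIDE_KEY).index
    keep = ~idx.isin(bad.index)
    return table.loc[keep].copy(), log


def replicate_log2_stats(table: pd.DataFrame) -> pd.DataFrame:
    """mu and sigma of all observed log2 intensities within each replicate.

    Both channels contribute; a replicate with no observed value at all is
    an error (its censoring floor is undefined).
    """
    frames = []
    for col in (TAGGED, WILDTYPE):
        sub = table[REPLICATE_KEY + [col]].rename(columns={col: "intensity"})
        frames.append(sub)
    stacked = pd.concat(frames, ignore_index=True)
    stacked = stacked[stacked["intensity"] > 0]
    stats = (
        stacked.assign(log2=np.log2(stacked["intensity"]))
        .groupby(REPLICATE_KEY)["log2"]
        .agg(mu="mean", sigma=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    all_reps = table[REPLICATE_KEY].drop_duplicates()
    merged = all_reps.merge(stats, on=REPLICATE_KEY, how="left")
    missing = merged[merged["mu"].isna()]
    if not missing.empty:
        rep = missing.iloc[0]
        raise ValueError(
            "replicate with no observed intensities: "
            f"condition={rep['condition_id']} orientation={rep['orientation']} "
            f"replicate={rep['replicate']}"
        )
    return merged


def impute_censored(
    table: pd.DataFrame, params: ImputationParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Method 3.1: left-censored imputation of the wild-type channel.

    Targets wild-type cells of peptides whose wild-type channel is
    observed in fewer than two replicates.  Each missing cell is replaced
    by ``2**u``, ``u ~ Uniform[mu - 3*sigma, mu - 2*sigma]`` of its own
    replicate; ``deterministic_mode`` uses the interval midpoint
    ``mu - 2.5*sigma``.  Returns ``(table, audit_log)``.
    """
    out = table.copy()
    stats = replicate_log2_stats(table)
    params.replicate_stats = stats
    if out.empty:
        return out, pd.DataFrame()
    rng = params.rng()
    stat_idx = stats.set_index(REPLICATE_KEY)

    obs_count = out[WILDTYPE].notna().groupby(
        [out[c] for c in PEPTIDE_KEY], sort=False
    ).transform("sum")
    target = out[WILDTYPE].isna() & (obs_count < 2)

    log_rows = []
    wt = out[WILDTYPE].to_numpy(float)
    for i in np.where(target.to_numpy())[0]:
        row = out.iloc[i]
        mu, sigma = stat_idx.loc[
            (row["condition_id"], row["orientation"], row["replicate"]),
            ["mu", "sigma"],
        ]
        if params.deterministic_mode:
            u = mu - 2.5 * sigma
        else:
            u = rng.uniform(mu - 3.0 * sigma, mu - 2.0 * sigma)
        wt[i] = 2.0**u
        log_rows.append(
            {
                **{k: row[k] for k in PEPTIDE_KEY + ["replicate"]},
                "channel": "wildtype",
                "method": "3.1",
                "log2_imputed": u,
                "mu": mu,
                "sigma": sigma,
            }
        )
    out[WILDTYPE] = wt
    return out, pd.DataFrame(log_rows)


def _delta_stats(wide: pd.DataFrame) -> tuple[pd.Series, float, float]:
    """Relative-range statistics over peptide-channel rows with >= 2 observations."""
    arr = wide.to_numpy(float)
    counts = np.sum(~np.isnan(arr), axis=1)
    elig = counts >= 2
    ranges = np.nanmax(arr[elig], axis=1) - np.nanmin(arr[elig], axis=1)
    mean_range = ranges.mean() if len(ranges) else float("nan")
    if not np.isfinite(mean_range) or mean_range == 0:
        deltas = np.zeros(len(ranges))  # degenerate: all ranges zero
    else:
        deltas = ranges / mean_range
    u_delta = float(deltas.mean()) if len(deltas) else 0.0
    sd_delta = float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0
    return pd.Series(deltas, index=wide.index[elig]), u_delta, sd_delta


def _mean_pairwise_corr(wide: pd.DataFrame) -> float:
    """Average Pearson correlation between replicate columns over rows
    complete in both columns of each pair."""
    cols = list(wide.columns)
    vals = []
    for a, b in itertools.combinations(cols, 2):
        sub = wide[[a, b]].dropna()
        if len(sub) < 2:
            continue
        sa, sb = sub[a].std(ddof=1), sub[b].std(ddof=1)
        if sa == 0 or sb == 0:
            continue
        vals.append(float(sub[a].corr(sub[b])))
    return float(np.mean(vals)) if vals else float("nan")


def _wide_channel(table: pd.DataFrame, channel: str) -> pd.DataFrame:
    return table.set_index(PEPTIDE_KEY + ["replicate"])[channel].unstack("replicate")


def impute_partial(
    table: pd.DataFrame, params: ImputationParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Method 4.1: impute partially missing cells from the observed spread.

    Applies to any remaining missing cell (tagged or wild-type channel)
    whose peptide has at least two observed values in that channel; cells
    with fewer observations are left for method 3.1.  One ``delta_new``
    draw per missing cell.  Returns ``(table, audit_log)``.
    """
    out = table.copy()
    if out.empty:
        return out, pd.DataFrame()
    rng = params.rng()

    if params.scope == "table":
        scopes = [(None, out)]
    elif params.scope == "condition":
        scopes = list(out.groupby(["condition_id", "orientation"], sort=False))
    else:
        raise ValueError(f"unknown scope {params.scope!r}")

    preset = params.has_preset_stats
    log_rows = []
    for _, chunk in scopes:
        # pooled delta statistics over both channels within the scope
        wides = {ch: _wide_channel(chunk, ch) for ch in (TAGGED, WILDTYPE)}
        if preset:
            u_delta, sd_delta, mean_corr = (
                params.u_delta,
                params.sd_delta,
                params.mean_corr,
            )
        else:
            stacked = pd.concat(wides.values())
            _, u_delta, sd_delta = _delta_stats(stacked)
            mean_corr = _mean_pairwise_corr(stacked)
        # the correlation only scales the SD of the random draw; the
        # deterministic point-mass mode never touches it
        if (
            not params.deterministic_mode
            and sd_delta > 0
            and (not np.isfinite(mean_corr) or mean_corr <= 0)
        ):
            raise ValueError(
                f"mean replicate correlation is {mean_corr}; method-4.1 "
                "scaling is undefined for non-positive correlation"
            )
        params.u_delta, params.sd_delta, params.mean_corr = (
            u_delta,
            sd_delta,
            mean_corr,
        )
        # sd_delta == 0 is the degenerate all-ranges-zero branch: the draw
        # collapses to a point mass and the correlation scaling is moot
        sd_new = 2.0 * sd_delta / mean_corr if sd_delta > 0 else 0.0

        # wide frame of row labels, aligned with the intensity pivots
        label_wide = (
            chunk.assign(_lbl=chunk.index)
            .set_index(PEPTIDE_KEY + ["replicate"])["_lbl"]
            .unstack("replicate")
        )
        for channel, wide in wides.items():
            arr = wide.to_numpy(float)
            nobs = np.sum(~np.isnan(arr), axis=1)
            targets = (nobs >= 2) & np.isnan(arr).any(axis=1)
            target_rows = wide.index[targets]
            if len(target_rows) == 0:
                continue
            sub = wide.loc[target_rows]
            row_mean = np.nanmean(arr[targets], axis=1)
            miss = np.isnan(arr[targets])
            ridx, cidx = np.where(miss)
            if params.deterministic_mode:
                d_new = np.full(len(ridx), u_delta)
            else:
                d_new = rng.normal(u_delta, sd_new, size=len(ridx))
            vals = row_mean[ridx] * np.abs(1.0 + d_new)
            labels = (
                label_wide.reindex(target_rows)[sub.columns].to_numpy(object)[
                    ridx, cidx
                ]
            )
            out.loc[labels, channel] = vals
            for j in range(len(ridx)):
                key = target_rows[ridx[j]]
                log_rows.append(
                    {
                        **dict(zip(PEPTIDE_KEY, key)),
                        "replicate": sub.columns[cidx[j]],
                        "channel": channel,
                        "method": "4.1",
                        "delta_new": d_new[j],
                        "imputed": vals[j],
                        "u_delta": u_delta,
                        "sd_delta": sd_delta,
                        "mean_corr": mean_corr,
                    }
                )
    return out, pd.DataFrame(log_rows)


def impute(
    table: pd.DataFrame, params: ImputationParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run method 3.1 then method 4.1; returns ``(table, combined_log)``."""
    params = params or ImputationParams()
    t1, log1 = impute_censored(table, params)
    t2, log2 = impute_partial(t1, params)
    return t2, pd.concat([log1, log2], ignore_index=True)
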