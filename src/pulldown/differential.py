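"""Label-free differential co-enrichment across a knockout panel.

Proteins validated as in-cell bait interactors are profiled across IPs
from wild-type and knockout cell lines: log2 protein abundances are
filtered on unique-peptide evidence, imputed, normalized to the bait
(making each value a log2 co-enrichment ratio), contrasted KO vs WT per
extractant condition with unpaired t-tests and Benjamini-Hochberg
adjustment, then summarized per protein as the average log2 fold change
over conditions and clustered into response groups (most decreased ->
most increased).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .quantify import ImputationParams
from .simulate import WT_LINE

SAMPLE_KEY = ["cell_line", "condition_id", "replicate"]


def filter_protein_evidence(
    table: pd.DataFrame, min_unique_peptides: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows for proteins identified with too few unique peptides."""
    bad = table["n_unique_peptides"] < min_unique_peptides
    log = (
        table.loc[bad, ["protein_id", "n_unique_peptides"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    return table.loc[~bad].copy(), log


def impute_protein_level(
    table: pd.DataFrame, params: ImputationParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute missing log2 abundances with the peptide-level machinery.

    Delegates to the method-3.1 / method-4.1 implementations, operating on
    protein x replicate log2 abundances within each cell line x condition
    block (each block is its own small replicate design).  Intensities are
    handed over on the raw scale (2**log2) so both methods behave exactly
    as at peptide level.
    """
    from . import quantify

    params = params or ImputationParams(deterministic_mode=True)
    if table["log2_abundance"].notna().all():
        return table.copy(), pd.DataFrame()

    out_blocks = []
    logs = []
    for (line, cond), block in table.groupby(["cell_line", "condition_id"], sort=False):
        if block["log2_abundance"].notna().all():
            out_blocks.append(block)
            continue
        # recast the block as a one-channel peptide table; the protein
        # abundances go into the wild-type slot (the channel method 3.1
        # targets) and the unused tagged channel stays all-missing so it
        # contributes nothing to replicate statistics.
        pseudo = pd.DataFrame(
            {
                "protein_id": block["protein_id"],
                "peptide_id": block["protein_id"],
                "condition_id": cond,
                "orientation": line,  # block tag; any constant works
                "replicate": block["replicate"],
                quantify.TAGGED: np.nan,
                quantify.WILDTYPE: 2.0 ** block["log2_abundance"],
            },
            index=block.index,
        )
        t1, log1 = quantify.impute_censored(pseudo, params)
        try:
            t2, log2_ = quantify.impute_partial(t1, params)
        except ValueError:
            # degenerate tiny block (no usable correlation): keep 3.1 result
            t2, log2_ = t1, pd.DataFrame()
        filled = block.copy()
        filled["log2_abundance"] = np.log2(t2[quantify.WILDTYPE].to_numpy(float))
        out_blocks.append(filled)
        for lg in (log1, log2_):
            if not lg.empty:
                lg = lg.assign(cell_line=line, condition_id=cond)
                logs.append(lg)
    out = pd.concat(out_blocks).sort_index()
    log = pd.concat(logs, ignore_index=True) if logs else pd.DataFrame()
    return out, log


def normalize_to_bait(table: pd.DataFrame, bait_id: str) -> pd.DataFrame:
    """Express abundances relative to the bait within each sample.

    Subtracts the bait's log2 abundance sample-wise; the bait row becomes
    exactly zero everywhere.  The bait must be observed (not imputed) in
    every sample.
    """
    bait = table.loc[table["protein_id"] == bait_id]
    all_samples = table[SAMPLE_KEY].drop_duplicates()
    bait_samples = bait.loc[bait["log2_abundance"].notna(), SAMPLE_KEY]
    missing = all_samples.merge(
        bait_samples, on=SAMPLE_KEY, how="left", indicator=True
    )
    missing = missing[missing["_merge"] == "left_only"]
    if not missing.empty:
        r = missing.iloc[0]
        raise ValueError(
            f"bait {bait_id!r} missing in sample cell_line={r['cell_line']} "
            f"condition={r['condition_id']} replicate={r['replicate']}"
        )
    bait_level = bait.set_index(SAMPLE_KEY)["log2_abundance"]
    out = table.copy()
    keys = pd.MultiIndex.from_frame(out[SAMPLE_KEY])
    out["log2_abundance"] = out["log2_abundance"].to_numpy(
        float
    ) - bait_level.reindex(keys).to_numpy(float)
    return out


def contrast(
    table: pd.DataFrame,
    ko_line: str,
    condition_id: str,
    equal_var: bool = True,
    wt_line: str = WT_LINE,
) -> pd.DataFrame:
    """Per-protein KO-vs-WT contrast within one extractant condition.

    ``log2fc = mean(KO) - mean(WT)``; p from a two-sided unpaired t-test
    (pooled variance by default, Welch with ``equal_var=False``).
    Proteins with fewer than two replicates in either arm are skipped;
    zero variance in both arms gives p = 1 when the means agree and p = 0
    (flagged) when they differ.
    """
    sub = table[
        (table["condition_id"] == condition_id)
        & (table["cell_line"].isin([ko_line, wt_line]))
    ]
    rows = []
    for pid, grp in sub.groupby("protein_id", sort=True):
        ko = grp.loc[
            grp["cell_line"] == ko_line, "log2_abundance"
        ].dropna().to_numpy(float)
        wt = grp.loc[
            grp["cell_line"] == wt_line, "log2_abundance"
        ].dropna().to_numpy(float)
        if len(ko) < 2 or len(wt) < 2:
            continue
        log2fc = float(ko.mean() - wt.mean())
        degenerate = False
        if ko.std(ddof=1) == 0.0 and wt.std(ddof=1) == 0.0:
            if np.isclose(ko.mean(), wt.mean()):
                p = 1.0
            else:
                p = 0.0
                degenerate = True
        else:
            p = float(stats.ttest_ind(ko, wt, equal_var=equal_var).pvalue)
        rows.append(
            {
                "protein_id": pid,
                "ko_line": ko_line,
                "condition_id": condition_id,
                "log2fc": log2fc,
                "p_value": p,
                "degenerate": degenerate,
                "n_ko": len(ko),
                "n_wt": len(wt),
            }
        )
    return pd.DataFrame(rows)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one test family."""
    p = np.asarray(p_values, float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flag_significant(
    results: pd.DataFrame,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Flag contrasts with |log2fc| >= threshold and (adjusted) p <= alpha."""
    out = results.copy()
    pcol = "p_adj" if use_adjusted else "p_value"
    if use_adjusted and "p_adj" not in out.columns:
        raise ValueError("adjusted p-values not present; run bh_adjust first")
    out["significant"] = (out["log2fc"].abs() >= fc_threshold) & (
        out[pcol] <= alpha
    )
    return out


def run_contrasts(
    table: pd.DataFrame,
    ko_lines: Iterable[str],
    conditions: Iterable[str],
    equal_var: bool = True,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """All KO x condition contrasts with per-family BH adjustment.

    The adjustment family is the set of proteins tested within one
    ko_line x condition contrast.
    """
    frames = []
    for ko in ko_lines:
        for cond in conditions:
            res = contrast(table, ko, cond, equal_var=equal_var)
            if res.empty:
                continue
            res["p_adj"] = bh_adjust(res["p_value"].to_numpy())
            frames.append(res)
    if not frames:
        return pd.DataFrame()
    allres = pd.concat(frames, ignore_index=True)
    return flag_significant(
        allres, fc_threshold=fc_threshold, alpha=alpha, use_adjusted=use_adjusted
    )


def build_profiles(
    results: pd.DataFrame, specific_set: Iterable[str]
) -> pd.DataFrame:
    """Per-interactor response profile across the KO panel.

    Only proteins in the in-cell-validated ``specific_set`` are profiled.
    ``avg_log2fc`` is the arithmetic mean over the conditions where the
    protein was quantified (coverage recorded in ``n_conditions_covered``);
    ``n_sig_conditions`` counts significant contrasts per KO line.
    """
    spec = set(specific_set)
    sub = results[results["protein_id"].isin(spec)]
    if sub.empty:
        return pd.DataFrame(
            columns=[
                "protein_id",
                "ko_line",
                "avg_log2fc",
                "n_sig_conditions",
                "n_conditions_covered",
            ]
        )
    prof = (
        sub.groupby(["protein_id", "ko_line"], sort=True)
        .agg(
            avg_log2fc=("log2fc", "mean"),
            n_sig_conditions=("significant", "sum"),
            n_conditions_covered=("condition_id", "nunique"),
        )
        .reset_index()
    )
    prof["n_sig_conditions"] = prof["n_sig_conditions"].astype(int)
    return prof


def assign_groups(
    profiles: pd.DataFrame,
    n_groups: int = 5,
    method: str = "average",
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Hierarchically cluster interactor profiles into response groups.

    Clusters the proteins x KO-lines matrix of ``avg_log2fc``
    (agglomerative, Euclidean distance, average linkage by default; any
    missing entry is imputed as 0 and flagged), cuts the tree into
    ``n_groups`` clusters and labels them 1..n_groups in ascending order
    of the cluster median of row-mean avg_log2fc, so Group 1 is the most
    decreased and Group ``n_groups`` the most increased.  Proteins are
    processed in accession order, making the output invariant to input
    row order.
    """
    mat = profiles.pivot_table(
        index="protein_id", columns="ko_line", values="avg_log2fc", dropna=False
    ).sort_index()
    if len(mat) < n_groups:
        raise ValueError(
            f"{len(mat)} profiles cannot be cut into {n_groups} groups"
        )
    filled_flag = mat.isna().any(axis=1)
    mat = mat.fillna(0.0)
    Z = linkage(mat.to_numpy(float), method=method, metric=metric)
    raw = fcluster(Z, t=n_groups, criterion="maxclust")
    if len(np.unique(raw)) < n_groups:
        raise ValueError(
            "degenerate clustering: tree cannot be cut into "
            f"{n_groups} distinct groups (identical profiles?)"
        )
    row_mean = mat.mean(axis=1)
    med = pd.Series(row_mean.to_numpy()).groupby(raw).median()
    order = med.sort_values(kind="stable").index.to_list()
    relabel = {old: i + 1 for i, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=mat.index, name="group_label")
    out = profiles.copy()
    out["group_label"] = out["protein_id"].map(labels)
    out["profile_imputed"] = out["protein_id"].map(filled_flag)
    return out


class DifferentialInteractome:
    """Model: differential bait co-enrichment across a KO panel.

    Parameters
    ----------
    abundance : DataFrame
        Long table ``protein_id, cell_line, condition_id, replicate,
        log2_abundance, n_unique_peptides`` covering the WT reference and
        every KO line.
    specific_set : iterable of str
        Accessions validated as in-cell interactors (e.g. the I-DIRT
        interactome); only these are profiled and grouped.
    bait_id : str
        Accession of the affinity-captured bait; abundances are expressed
        relative to it.

    ``fit()`` runs evidence filtering, protein-level imputation, bait
    normalization, all KO x condition contrasts with BH adjustment, and
    response grouping, returning :class:`DifferentialInteractomeResults`.
    """

    def __init__(
        self,
        abundance: pd.DataFrame,
        specific_set: Iterable[str],
        bait_id: str = "CDH1",
        *,
        ko_lines: Sequence[str] | None = None,
        conditions: Sequence[str] | None = None,
        min_unique_peptides: int = 2,
        fc_threshold: float = 1.0,
        alpha: float = 0.05,
        use_adjusted: bool = True,
        equal_var: bool = True,
        n_groups: int = 5,
        imputation: ImputationParams | None = None,
        wt_line: str = WT_LINE,
    ) -> None:
        self.abundance = abundance
        self.specific_set = list(specific_set)
        self.bait_id = bait_id
        lines = abundance["cell_line"].unique().tolist()
        self.ko_lines = list(ko_lines) if ko_lines is not None else [
            l for l in lines if l != wt_line
        ]
        self.conditions = (
            list(conditions)
            if conditions is not None
            else sorted(abundance["condition_id"].unique())
        )
        self.min_unique_peptides = min_unique_peptides
        self.fc_threshold = fc_threshold
        self.alpha = alpha
        self.use_adjusted = use_adjusted
        self.equal_var = equal_var
        self.n_groups = n_groups
        self.imputation = imputation or ImputationParams(deterministic_mode=True)
        self.wt_line = wt_line

    def fit(self) -> "DifferentialInteractomeResults":
        filtered, filter_log = filter_protein_evidence(
            self.abundance, self.min_unique_peptides
        )
        imputed, impute_log = impute_protein_level(filtered, self.imputation)
        normalized = normalize_to_bait(imputed, self.bait_id)
        contrasts = run_contrasts(
            normalized,
            self.ko_lines,
            self.conditions,
            equal_var=self.equal_var,
            fc_threshold=self.fc_threshold,
            alpha=self.alpha,
            use_adjusted=self.use_adjusted,
        )
        profiles = build_profiles(contrasts, self.specific_set)
        grouped = None
        if not profiles.empty and profiles["protein_id"].nunique() >= self.n_groups:
            grouped = assign_groups(profiles, self.n_groups)
        return DifferentialInteractomeResults(
            model=self,
            contrasts=contrasts,
            profiles=grouped if grouped is not None else profiles,
            filter_log=filter_log,
            imputation_log=impute_log,
            normalized=normalized,
        )


@dataclass
class DifferentialInteractomeResults:
    """Fitted differential-interactome contrasts, profiles and groups."""

    model: DifferentialInteractome
    contrasts: pd.DataFrame
    profiles: pd.DataFrame
    filter_log: pd.DataFrame
    imputation_log: pd.DataFrame
    normalized: pd.DataFrame = field(repr=False, default=None)

    def group_medians(self) -> pd.DataFrame:
        """Median avg_log2fc per response group per KO line."""
        if "group_label" not in self.profiles.columns:
            return pd.DataFrame()
        return (
            self.profiles.groupby(["group_label", "ko_line"])["avg_log2fc"]
            .median()
            .unstack("ko_line")
        )

    def summary(self) -> str:
        c = self.contrasts
        lines = [
            "Differential interactome (KO vs WT, bait-normalized)",
            "=" * 54,
            f"proteins tested:        {c['protein_id'].nunique() if not c.empty else 0}",
            f"KO lines:               {', '.join(self.model.ko_lines)}",
            f"conditions:             {', '.join(self.model.conditions)}",
            f"significance rule:      |log2FC| >= {self.model.fc_threshold}, "
            f"{'BH-adjusted' if self.model.use_adjusted else 'raw'} "
            f"p <= {self.model.alpha}",
        ]
        if not c.empty:
            sig = c.groupby("ko_line")["significant"].sum()
            lines.append("")
            lines.append("significant contrasts per KO line:")
            for ko, cnt in sig.items():
                lines.append(f"  {ko:<10} {int(cnt)}")
        gm = self.group_medians()
        if not gm.empty:
            lines.append("")
            lines.append("group median avg_log2fc per KO line:")
            lines.append(gm.round(2).to_string())
        return "\n".join(lines)

    def plot_profile_matrix(self, ax=None):
        """Fig-4A-style dot matrix: color = avg log2FC, size = #sig conditions."""
        import matplotlib.pyplot as plt

        prof = self.profiles
        if ax is None:
            _, ax = plt.subplots(
                figsize=(3 + 0.4 * len(self.model.ko_lines), 0.15 * prof["protein_id"].nunique() + 2)
            )
        order = prof.sort_values(["group_label", "protein_id"])["protein_id"].unique()
        ypos = {p: i for i, p in enumerate(order)}
        xpos = {k: i for i, k in enumerate(self.model.ko_lines)}
        sc = ax.scatter(
            prof["ko_line"].map(xpos),
            prof["protein_id"].map(ypos),
            c=prof["avg_log2fc"],
            s=10 + 20 * prof["n_sig_conditions"],
            cmap="coolwarm_r",
            vmin=-4,
            vmax=4,
        )
        ax.set_xticks(range(len(xpos)), list(xpos))
        ax.set_yticks(range(len(ypos)), list(ypos), fontsize=5)
        plt.colorbar(sc, ax=ax, label="avg log2FC")
        return ax
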