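"""Relative qPCR quantification and group statistics.

Expression is quantified with the Livak 2^-ddCt method: within each
sample the target-gene Ct is referenced to the housekeeping gene
(``dCt = Ct_target - Ct_housekeeping``), condition means of dCt are then
referenced to the mean dCt of the reference condition
(``ddCt = mean dCt(condition) - mean dCt(reference)``), and the fold
change is ``2^-ddCt``.  The reference condition (the flat control here)
has fold change exactly 1 by construction.  Error bars come from the
spread of per-sample fold changes ``2^-(dCt_i - mean dCt(reference))``.

Group comparisons follow the one-way ANOVA / Scheffé post-hoc
convention: the omnibus F test across all conditions, then Scheffé's
all-contrasts procedure for pairwise comparisons, with significance
tiers at 0.05 / 0.01 / 0.001.  Scheffé's test compares the scaled
pairwise statistic ``F_pair / (k-1)`` against the F(k-1, N-k)
distribution, which controls the family-wise error over *all* possible
contrasts and is therefore conservative; for k = 2 groups it coincides
with the plain ANOVA.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REQUIRED_COLUMNS",
    "GroupStats",
    "PairwiseResult",
    "ddct",
    "anova_scheffe",
    "significance_stars",
]

REQUIRED_COLUMNS = ("sample_id", "condition", "gene", "ct")


def significance_stars(p: float) -> str:
    """Star notation at the 0.05 / 0.01 / 0.001 tiers."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _validate_table(table: pd.DataFrame, housekeeping: str, reference: str) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks required columns: {missing}")
    ct = table["ct"]
    if not np.isfinite(ct).all():
        raise ValueError("all Ct values must be finite")
    if ((ct < 10) | (ct > 40)).any():
        warnings.warn("Ct values outside the typical 10-40 cycle range", stacklevel=3)
    if housekeeping not in set(table["gene"]):
        raise ValueError(f"housekeeping gene {housekeeping!r} absent from table")
    if reference not in set(table["condition"]):
        raise ValueError(f"reference condition {reference!r} absent from table")


def ddct(
    table: pd.DataFrame,
    housekeeping: str = "GAPDH",
    reference_condition: str = "flat",
) -> pd.DataFrame:
    """Fold changes by the 2^-ddCt method, referenced to a control condition.

    Parameters
    ----------
    table : DataFrame
        Long-format Ct table with columns ``sample_id, condition, gene,
        ct`` and optionally ``cell_type`` (quantification is stratified
        by cell type when present).  Every sample measuring a target
        gene must also measure the housekeeping gene.
    housekeeping, reference_condition : str
        Normalisation gene and baseline condition.

    Returns
    -------
    DataFrame
        One row per (cell_type,) condition and target gene: replicate
        count ``n``, ``mean_dct``, ``ddct``, ``fold`` (= 2^-ddCt, exactly
        1 for the reference stratum) and ``fold_sd``, the s.d. of
        per-sample fold changes.

    Raises
    ------
    ValueError
        Listing the strata that lack housekeeping or reference data.
    """
    _validate_table(table, housekeeping, reference_condition)
    df = table.copy()
    if "cell_type" not in df.columns:
        df["cell_type"] = "all"

    hk = (
        df[df["gene"] == housekeeping]
        .groupby(["cell_type", "condition", "sample_id"])["ct"]
        .mean()
        .rename("ct_hk")
    )
    targets = df[df["gene"] != housekeeping]
    merged = targets.join(hk, on=["cell_type", "condition", "sample_id"], how="left")
    orphans = merged[merged["ct_hk"].isna()]
    if not orphans.empty:
        strata = sorted(
            set(zip(orphans["cell_type"], orphans["condition"], orphans["sample_id"]))
        )
        raise ValueError(f"samples lacking housekeeping Ct: {strata}")
    merged["dct"] = merged["ct"] - merged["ct_hk"]

    ref_mean = (
        merged[merged["condition"] == reference_condition]
        .groupby(["cell_type", "gene"])["dct"]
        .mean()
        .rename("ref_mean_dct")
    )
    merged = merged.join(ref_mean, on=["cell_type", "gene"], how="left")
    no_ref = merged[merged["ref_mean_dct"].isna()]
    if not no_ref.empty:
        strata = sorted(set(zip(no_ref["cell_type"], no_ref["gene"])))
        raise ValueError(
            f"strata lacking reference condition {reference_condition!r}: {strata}"
        )
    merged["sample_fold"] = 2.0 ** -(merged["dct"] - merged["ref_mean_dct"])

    out = (
        merged.groupby(["cell_type", "condition", "gene"])
        .agg(
            n=("dct", "size"),
            mean_dct=("dct", "mean"),
            ref_mean_dct=("ref_mean_dct", "first"),
            fold_sd=("sample_fold", "std"),
        )
        .reset_index()
    )
    out["ddct"] = out["mean_dct"] - out["ref_mean_dct"]
    out.loc[out["condition"] == reference_condition, "ddct"] = 0.0  # exact identity
    out["fold"] = 2.0 ** -out["ddct"]
    return out[
        ["cell_type", "condition", "gene", "n", "mean_dct", "ddct", "fold", "fold_sd"]
    ]


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    mean_difference: float
    scheffe_f: float
    p_value: float
    stars: str


@dataclass(frozen=True)
class GroupStats:
    """One-way ANOVA with Scheffé post-hoc over named groups."""

    groups: dict[str, np.ndarray]
    anova_f: float
    anova_p: float
    df_between: int
    df_within: int
    mse: float
    pairwise: tuple[PairwiseResult, ...]

    @property
    def summary(self) -> pd.DataFrame:
        rows = [
            {"group": g, "n": len(v), "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
            for g, v in self.groups.items()
        ]
        return pd.DataFrame(rows)


def anova_scheffe(groups: dict[str, np.ndarray]) -> GroupStats:
    """One-way ANOVA followed by Scheffé's post-hoc pairwise comparisons.

    Parameters
    ----------
    groups : dict
        Group name -> 1-D array of measurements; at least two groups of
        at least two observations each.

    Notes
    -----
    The omnibus F matches ``scipy.stats.f_oneway``.  Pairwise Scheffé
    p-values are ``sf(F_pair / (k-1); k-1, N-k)`` with ``F_pair =
    (mean_i - mean_j)^2 / (MSE (1/n_i + 1/n_j))``; they are always >=
    the unadjusted pairwise p-values and equal the ANOVA p when k = 2.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float).ravel() for g in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0 and ss_between == 0:
        raise ValueError("degenerate groups: zero variance everywhere")
    mse = ss_within / df_w
    if mse == 0:
        raise ValueError("zero within-group variance; F undefined")
    f_stat = (ss_between / df_b) / mse
    p_val = float(stats.f.sf(f_stat, df_b, df_w))

    pairwise = []
    for (na, a), (nb, b) in itertools.combinations(zip(names, arrays), 2):
        diff = float(a.mean() - b.mean())
        f_pair = diff**2 / (mse * (1.0 / a.size + 1.0 / b.size))
        scheffe = f_pair / df_b
        p = float(stats.f.sf(scheffe, df_b, df_w))
        pairwise.append(PairwiseResult(na, nb, diff, scheffe, p, significance_stars(p)))

    return GroupStats(
        groups={g: a for g, a in zip(names, arrays)},
        anova_f=float(f_stat),
        anova_p=p_val,
        df_between=df_b,
        df_within=df_w,
        mse=float(mse),
        pairwise=tuple(pairwise),
    )
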