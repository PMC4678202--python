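"""Relative qPCR quantification and cow-blocked stage ANOVA.

Expression of each target gene is quantified relative to a housekeeping
reference (RPLP0 by default) as the normalized ratio
``E ** (meanCt_ref - meanCt_target)`` per (cow, stage) cell, with
amplification efficiency ``E`` (default 2, i.e. perfect doubling) and
replicate-mean Cts.  Stage differences are tested per gene with a balanced
two-way additive ANOVA (stage + cow as a blocking term, no interaction;
df = 2 and 2(b - 1) for three stages and b cows), followed by protected
Fisher LSD pairwise comparisons — pairwise tests run only when the overall
stage F-test is significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["STAGES", "AnovaResult", "normalize", "blocked_anova", "protected_lsd"]

STAGES = ("pregnancy", "lactation", "involution")


@dataclass(frozen=True)
class AnovaResult:
    """Blocked-ANOVA summary for one gene's normalized ratios."""

    gene: str
    f_stage: float
    df_stage: int
    df_resid: int
    p_stage: float
    f_cow: float
    p_cow: float
    mse: float
    stage_means: dict
    n_blocks: int
    transform: str


def normalize(ct: pd.DataFrame, reference_gene: str = "RPLP0",
              efficiency: float = 2.0) -> pd.DataFrame:
    """Compute normalized expression ratios per (cow, stage, gene) cell.

    ``ct`` is the tidy Ct table (cow, stage, gene, replicate, ct).  The
    ratio for a target cell is ``efficiency ** (meanCt_ref - meanCt_tgt)``
    using replicate-mean Cts; a missing reference cell raises, naming the
    (cow, stage).
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    means = (ct.groupby(["cow", "stage", "gene"], sort=False)["ct"]
             .mean().reset_index())
    ref = means[means["gene"] == reference_gene]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    ref_ct = ref.set_index(["cow", "stage"])["ct"]
    tgt = means[means["gene"] != reference_gene].copy()
    keys = pd.MultiIndex.from_frame(tgt[["cow", "stage"]])
    missing = ~keys.isin(ref_ct.index)
    if missing.any():
        cow, stage = keys[missing][0]
        raise ValueError(f"no reference Ct for cow {cow!r}, stage {stage!r}")
    tgt["ratio"] = np.power(efficiency,
                            ref_ct.loc[keys].to_numpy() - tgt["ct"].to_numpy())
    return tgt[["cow", "stage", "gene", "ratio"]].reset_index(drop=True)


def blocked_anova(ratios: pd.DataFrame, gene: str,
                  transform: str = "none") -> AnovaResult:
    """Two-way additive ANOVA of one gene's ratios: stage + cow (block).

    Requires a complete balanced design (every cow x stage cell observed
    once); unbalanced input raises, naming the missing cells.  With
    ``transform="log"`` the natural log of the ratio is analyzed.  A table
    with zero residual and stage variance reports F = 0, P = 1.
    """
    sub = ratios[ratios["gene"] == gene]
    if sub.empty:
        raise KeyError(f"gene {gene!r} absent from ratio table")
    cows = sorted(sub["cow"].unique())
    cells = sub.groupby(["cow", "stage"]).size()
    expected = pd.MultiIndex.from_product([cows, list(STAGES)])
    missing = [c for c in expected if c not in cells.index]
    if missing or (cells != 1).any():
        raise ValueError(
            f"unbalanced design for {gene!r}: missing cells {missing}, "
            f"duplicated cells {list(cells[cells > 1].index)}")

    df = sub.copy()
    if transform == "log":
        df["value"] = np.log(df["ratio"])
    elif transform == "none":
        df["value"] = df["ratio"]
    else:
        raise ValueError(f"unknown transform {transform!r}")

    b = len(cows)
    if np.ptp(df["value"].to_numpy()) == 0.0:
        means = {s: float(df[df["stage"] == s]["value"].mean()) for s in STAGES}
        return AnovaResult(gene, 0.0, 2, 2 * (b - 1), 1.0, 0.0, 1.0,
                           0.0, means, b, transform)

    model = smf.ols("value ~ C(stage) + C(cow)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ms_resid = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
    f_stage = float(table.loc["C(stage)", "F"])
    p_stage = float(table.loc["C(stage)", "PR(>F)"])
    if not np.isfinite(f_stage):  # zero residual variance, perfect structure
        f_stage, p_stage = np.inf, 0.0
    means = {s: float(df[df["stage"] == s]["value"].mean()) for s in STAGES}
    return AnovaResult(
        gene=gene,
        f_stage=f_stage,
        df_stage=int(table.loc["C(stage)", "df"]),
        df_resid=int(table.loc["Residual", "df"]),
        p_stage=p_stage,
        f_cow=float(table.loc["C(cow)", "F"]),
        p_cow=float(table.loc["C(cow)", "PR(>F)"]),
        mse=float(ms_resid),
        stage_means=means,
        n_blocks=b,
        transform=transform,
    )


def protected_lsd(anova: AnovaResult, alpha: float = 0.05) -> pd.DataFrame:
    """Protected Fisher LSD comparisons between lactation stages.

    When the overall stage P exceeds ``alpha`` no pair is tested
    (``tested = False``, ``significant = None``) — the protection step.
    Otherwise ``LSD = t(1 - alpha/2, df_resid) * sqrt(2 * MSE / b)`` and a
    pair is significant iff its |mean difference| exceeds the LSD.
    """
    tested = anova.p_stage <= alpha
    lsd = np.nan
    if tested:
        tq = stats.t.ppf(1 - alpha / 2, anova.df_resid)
        lsd = float(tq * np.sqrt(2.0 * anova.mse / anova.n_blocks))
    rows = []
    pairs = [(STAGES[i], STAGES[j])
             for i in range(len(STAGES)) for j in range(i + 1, len(STAGES))]
    for a, b_ in pairs:
        diff = anova.stage_means[a] - anova.stage_means[b_]
        sig = bool(abs(diff) > lsd) if tested else None
        rows.append((anova.gene, a, b_, diff, lsd, tested, sig))
    return pd.DataFrame(rows, columns=[
        "gene", "stage_a", "stage_b", "mean_diff", "lsd", "tested", "significant"])
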