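"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive: explicit pseudo-inverse normal
equations, double loops, textbook sum-of-squares decompositions.  None of
it shares code with the package's fitting path.
"""

from __future__ import annotations

import numpy as np


def one_hot_design(encodings) -> tuple[np.ndarray, list]:
    """Dummy design (intercept first) built independently from codes."""
    encs = [e for e in encodings if e.informative]
    n = len(encs[0].codes)
    cols = [np.ones(n)]
    meta = [("(intercept)", "(intercept)")]
    for e in encs:
        for li in range(1, e.n_levels):
            cols.append((np.asarray(e.codes) == li).astype(float))
            meta.append((e.gene, e.levels[li]))
    return np.column_stack(cols), meta


def ols_pinv(y: np.ndarray, X: np.ndarray) -> dict:
    """Least squares via explicit pseudo-inverse normal equations."""
    beta = np.linalg.pinv(X.T @ X) @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    rank = int(np.linalg.matrix_rank(X))
    n = len(y)
    p = rank - 1
    r2 = 1.0 - rss / tss
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return {"beta": beta, "rss": rss, "tss": tss, "rank": rank,
            "n": n, "p": p, "r2": r2, "adj_r2": adj,
            "df2": n - rank, "s2": rss / (n - rank)}


def drop_one_f(y: np.ndarray, X: np.ndarray, meta: list, gene: str) -> tuple:
    """Marginal F for one gene by explicitly refitting without its columns."""
    keep = [j for j, (g, _) in enumerate(meta) if g != gene]
    full = ols_pinv(y, X)
    red = ols_pinv(y, X[:, keep])
    df1 = full["rank"] - red["rank"]
    df2 = full["df2"]
    if df1 == 0:
        return np.nan, 0, df2, 1.0
    F = ((red["rss"] - full["rss"]) / df1) / (full["rss"] / df2)
    from scipy import stats
    return F, df1, df2, float(stats.f.sf(F, df1, df2))


def brute_force_assignment(snp_map, regions, window: int) -> dict:
    """SNP-to-gene assignment by a plain double loop over all pairs."""
    out = {}
    for _, r in regions.iterrows():
        hits = []
        for _, s in snp_map.iterrows():
            if (s["chrom"] == r["chrom"]
                    and r["start"] - window <= s["pos"] <= r["end"] + window):
                hits.append((s["pos"], s["snp_id"]))
        out[r["gene"]] = [sid for _, sid in sorted(hits)]
    return out


def blocked_anova_ss(values: np.ndarray) -> dict:
    """Textbook two-way additive decomposition of a blocks x treatments table.

    ``values[i, j]`` is block i (cow) under treatment j (stage).
    """
    b, a = values.shape
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    ss_treat = b * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_block = a * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_resid = ss_total - ss_treat - ss_block
    df_treat, df_block = a - 1, b - 1
    df_resid = (a - 1) * (b - 1)
    ms_treat = ss_treat / df_treat
    ms_resid = ss_resid / df_resid
    from scipy import stats
    F = ms_treat / ms_resid if ms_resid > 0 else np.inf
    return {"ss_treat": ss_treat, "ss_block": ss_block, "ss_resid": ss_resid,
            "df": (df_treat, df_resid), "F": F,
            "p": float(stats.f.sf(F, df_treat, df_resid)),
            "mse": ms_resid}
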