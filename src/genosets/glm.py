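"""Joint general linear model over composite-genotype factors.

A trait is regressed on an intercept plus one categorical factor per gene
(dummy coding against each gene's reference level).  Each gene is tested
with a marginal (drop-one) F-test:

    F = ((RSS_without - RSS_with) / df1) / (RSS_with / df2)

with ``df1`` the columns the gene contributes after alias removal and
``df2 = n - p - 1`` of the full model.  Backward elimination removes the
single worst gene (largest P, strictly above the threshold) per iteration
until every retained gene is significant.  Variance explained is reported
as R^2 = 1 - RSS/TSS and adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1).

Implementation notes: fits go through the Gram matrix (X'X, X'y computed
once per elimination context; each candidate submodel is a Cholesky solve
on an index subset), and drop-one F statistics use the general linear
hypothesis identity  beta_B' [(X'X)^-1_BB]^-1 beta_B = RSS_without -
RSS_with  on the alias-pruned column set.  Aliased (linearly dependent)
columns are dropped deterministically, first-come-first-kept in column
order — so later-listed genes lose columns first — and reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import special

from .composite import FactorEncoding

__all__ = [
    "ModelFit",
    "EliminationTrace",
    "EffectSummary",
    "DegenerateInputError",
    "RankError",
    "design_matrix",
    "fit_joint_model",
    "gene_f_test",
    "backward_eliminate",
    "estimate_combination_effects",
]

_P_FLOOR = 5e-324  # keep P in (0, 1] even for a numerically perfect fit


class DegenerateInputError(ValueError):
    """Raised for inputs the model cannot be fitted on (e.g. constant trait)."""


class RankError(ValueError):
    """Raised when the design has more columns than the sample supports."""


@dataclass(frozen=True)
class ModelFit:
    """A fitted multi-gene model and its per-gene tests.

    ``p`` counts non-intercept design columns after alias removal; the
    per-level ``effects`` are contrasts against each gene's reference level
    (reference rows are exactly 0 by construction; aliased levels are NaN).
    """

    trait: str
    genes: tuple[str, ...]
    n: int
    p: int
    gene_tests: pd.DataFrame        # gene, F, df1, df2, p_value
    r2: float
    adj_r2: float
    resid_var: float
    effects: pd.DataFrame           # gene, level, estimate, se, is_reference
    aliased: tuple[str, ...]        # "gene:level" descriptors of dropped columns
    excluded_noninformative: tuple[str, ...] = ()

    @property
    def min_p(self) -> float:
        if len(self.gene_tests) == 0:
            return 1.0
        return float(self.gene_tests["p_value"].min())

    @property
    def max_p(self) -> float:
        if len(self.gene_tests) == 0:
            return 1.0
        return float(self.gene_tests["p_value"].max())


@dataclass(frozen=True)
class EliminationTrace:
    """Record of a backward elimination run: one removal per step."""

    steps: pd.DataFrame             # step, gene, p_value, F, r2_after, adj_r2_after
    final: ModelFit


@dataclass(frozen=True)
class EffectSummary:
    """Per-level effect contrasts and their sign tally for one fit."""

    trait: str
    effects: pd.DataFrame
    n_positive: int
    n_negative: int


# ---------------------------------------------------------------------------
# Workspace: Gram-matrix machinery shared across submodel fits
# ---------------------------------------------------------------------------

class _Workspace:
    """Precomputed design for one (trait, encodings) fitting context.

    The full design matrix, X'X and X'y are built once; every submodel
    visited during backward elimination reuses index subsets of the Gram
    matrix, never touching the n-sized data again.
    """

    def __init__(self, y: np.ndarray, encodings: list[FactorEncoding]):
        y = np.asarray(y, dtype=float)
        if np.isnan(y).any():
            raise DegenerateInputError("trait contains missing values")
        self.n = len(y)
        self.y = y
        self.tss = float(np.sum((y - y.mean()) ** 2))
        if self.tss <= 0:
            raise DegenerateInputError("trait has zero variance")

        self.encodings = [e for e in encodings if e.informative]
        self.noninformative = tuple(e.gene for e in encodings if not e.informative)
        meta = [("(intercept)", "(intercept)")]
        self.block: dict[str, np.ndarray] = {}
        start = 1
        for enc in self.encodings:
            if len(enc.codes) != self.n:
                raise ValueError(
                    f"encoding for {enc.gene!r} has {len(enc.codes)} animals, "
                    f"trait has {self.n}")
            meta.extend((enc.gene, enc.levels[li])
                        for li in range(1, enc.n_levels))
            self.block[enc.gene] = np.arange(start, start + enc.n_levels - 1)
            start += enc.n_levels - 1
        # the dummy design is an indicator matrix, so its Gram matrix is a
        # table of level co-occurrence counts — assembled from bincounts of
        # the level codes instead of an explicit X'X product
        p_all = start
        G = np.zeros((p_all, p_all))
        gvec = np.zeros(p_all)
        G[0, 0] = self.n
        gvec[0] = y.sum()
        for enc in self.encodings:
            blk = self.block[enc.gene]
            cnts = np.asarray(enc.counts, dtype=float)
            G[0, blk] = G[blk, 0] = cnts[1:]
            G[blk, blk] = cnts[1:]  # levels are mutually exclusive
            gvec[blk] = np.bincount(enc.codes, weights=y,
                                    minlength=enc.n_levels)[1:]
        for a in range(len(self.encodings)):
            ea = self.encodings[a]
            la, ba = ea.n_levels, self.block[ea.gene]
            for c in range(a + 1, len(self.encodings)):
                ec = self.encodings[c]
                lc, bc = ec.n_levels, self.block[ec.gene]
                joint = np.bincount(ea.codes * lc + ec.codes,
                                    minlength=la * lc).reshape(la, lc)
                G[np.ix_(ba, bc)] = joint[1:, 1:]
                G[np.ix_(bc, ba)] = joint[1:, 1:].T
        self.meta = meta
        self.G = G
        self.g = gvec
        self.yty = float(y @ y)

    # -- rank handling ------------------------------------------------------

    def _select_columns(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (kept positions within idx, Cholesky factor of kept Gram).

        Fast path: plain Cholesky of the subset (no aliasing).  On failure
        or a suspicious pivot, fall back to greedy first-come-first-kept
        column selection via incremental Cholesky.
        """
        Gs = self.G[np.ix_(idx, idx)]
        scale = np.sqrt(np.diagonal(Gs).max())
        L, info = sla.lapack.dpotrf(Gs, lower=1)
        if info == 0 and np.diagonal(L).min() > 1e-6 * scale:
            return np.arange(len(idx)), np.tril(L)
        # greedy selection, column order = input order
        k = len(idx)
        Lbuf = np.zeros((k, k))
        keep: list[int] = []
        tol = 1e-9
        for j in range(k):
            a = Gs[keep, j]
            if keep:
                w = sla.solve_triangular(Lbuf[: len(keep), : len(keep)], a,
                                         lower=True)
            else:
                w = np.empty(0)
            d = Gs[j, j] - w @ w
            if d > tol * max(Gs[j, j], 1.0):
                m = len(keep)
                Lbuf[m, :m] = w
                Lbuf[m, m] = np.sqrt(d)
                keep.append(j)
        kk = np.array(keep, dtype=int)
        return kk, Lbuf[: len(keep), : len(keep)].copy()

    # -- submodel fit -------------------------------------------------------

    def fit_subset(self, genes: tuple[str, ...]) -> dict:
        """Least-squares fit of intercept + the given genes' factors."""
        idx = np.concatenate([[0]] + [self.block[g] for g in genes]) \
            if genes else np.array([0])
        kept_local, L = self._select_columns(idx)
        kept = idx[kept_local]
        rank = len(kept)
        if self.n <= rank:
            raise RankError(
                f"n = {self.n} <= model columns = {rank}; pool rare composite "
                f"levels more aggressively (raise min_level_count)")
        gs = self.g[kept]
        # columns of L^-1 give (X'X)^-1 blocks: (G^-1)_BB = V_B' V_B with
        # V = L^-1 (the full inverse is only materialized for reporting)
        Linv, info = sla.lapack.dtrtri(L, lower=1)
        if info != 0:
            raise RankError("singular triangular factor")
        Linv = np.tril(Linv)
        beta = Linv.T @ (Linv @ gs)
        rss = max(self.yty - gs @ beta, 0.0)
        p = rank - 1
        df2 = self.n - rank
        kept_set = {c: i for i, c in enumerate(kept)}

        tests = []
        for gene in genes:
            B = [kept_set[c] for c in self.block[gene] if c in kept_set]
            if not B:
                tests.append((gene, np.nan, 0, df2, 1.0))
                continue
            bB = beta[B]
            V = Linv[:, B]
            S = V.T @ V
            delta = float(bB @ np.linalg.solve(S, bB))
            df1 = len(B)
            if df2 <= 0:
                raise RankError("no residual degrees of freedom")
            s2 = rss / df2
            if s2 <= 0:
                F, P = np.inf, _P_FLOOR
            else:
                F = (delta / df1) / s2
                P = max(float(special.fdtrc(df1, df2, F)), _P_FLOOR)
            tests.append((gene, F, df1, df2, P))

        r2 = 1.0 - rss / self.tss
        adj = 1.0 - (1.0 - r2) * (self.n - 1) / (self.n - p - 1)
        return {
            "genes": tuple(genes),
            "kept": kept,
            "beta": beta,
            "rss": rss,
            "p": p,
            "df2": df2,
            "r2": r2,
            "adj_r2": adj,
            "resid_var": rss / df2 if df2 > 0 else np.nan,
            "Linv": Linv,
            "tests": tests,
        }

    def to_model_fit(self, res: dict, trait_name: str) -> ModelFit:
        tests = pd.DataFrame(res["tests"],
                             columns=["gene", "F", "df1", "df2", "p_value"])
        kept_cols = set(res["kept"])
        s2 = res["resid_var"]
        Ginv = res["Linv"].T @ res["Linv"]
        se_kept = np.sqrt(np.maximum(np.diag(Ginv), 0.0) * max(s2, 0.0))
        beta_of = {c: (res["beta"][i], se_kept[i])
                   for i, c in enumerate(res["kept"])}
        rows = []
        aliased = []
        for gene in res["genes"]:
            enc = next(e for e in self.encodings if e.gene == gene)
            rows.append((gene, enc.reference, 0.0, 0.0, True))
            for li, col in zip(range(1, enc.n_levels), self.block[gene]):
                if col in kept_cols:
                    est, se = beta_of[col]
                    rows.append((gene, enc.levels[li], est, se, False))
                else:
                    rows.append((gene, enc.levels[li], np.nan, np.nan, False))
                    aliased.append(f"{gene}:{enc.levels[li]}")
        effects = pd.DataFrame(
            rows, columns=["gene", "level", "estimate", "se", "is_reference"])
        return ModelFit(
            trait=trait_name,
            genes=res["genes"],
            n=self.n,
            p=res["p"],
            gene_tests=tests,
            r2=res["r2"],
            adj_r2=res["adj_r2"],
            resid_var=res["resid_var"],
            effects=effects,
            aliased=tuple(aliased),
            excluded_noninformative=self.noninformative,
        )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _as_array(trait) -> tuple[np.ndarray, str]:
    if isinstance(trait, pd.Series):
        return trait.to_numpy(dtype=float), str(trait.name or "trait")
    return np.asarray(trait, dtype=float), "trait"


def fit_joint_model(trait, encodings: list[FactorEncoding],
                    trait_name: str | None = None) -> ModelFit:
    """Fit the joint model of a trait on all informative gene factors.

    ``trait`` is a Series or array aligned with the encodings' animal
    order.  Returns the full :class:`ModelFit` with per-gene marginal
    F-tests, R^2, adjusted R^2 and per-level effect contrasts.
    """
    y, name = _as_array(trait)
    ws = _Workspace(y, encodings)
    res = ws.fit_subset(tuple(e.gene for e in ws.encodings))
    return ws.to_model_fit(res, trait_name or name)


def gene_f_test(trait, encodings: list[FactorEncoding],
                gene: str) -> tuple[float, int, int, float]:
    """Marginal (drop-one) F-test of one gene within the joint model.

    Returns ``(F, df1, df2, P)``; a fully aliased gene reports
    ``df1 = 0, P = 1`` and is treated as freely removable.
    """
    y, _ = _as_array(trait)
    ws = _Workspace(y, encodings)
    genes = tuple(e.gene for e in ws.encodings)
    if gene not in genes:
        raise KeyError(f"gene {gene!r} not in the current model")
    res = ws.fit_subset(genes)
    row = next(t for t in res["tests"] if t[0] == gene)
    return row[1], row[2], row[3], row[4]


def backward_eliminate(trait, encodings: list[FactorEncoding],
                       threshold: float = 0.05,
                       trait_name: str | None = None) -> EliminationTrace:
    """Backward-eliminate genes until all retained have P <= threshold.

    Per iteration the joint model is refitted and the single gene with the
    largest marginal P is removed if (strictly) ``P > threshold``; ties are
    broken by smaller F, then lexicographic gene name.  ``threshold = 1.0``
    therefore removes nothing.  The trace records each removal with the P
    at removal and the model R^2 after it; the terminal :class:`ModelFit`
    carries the reported trio (per-gene P, R^2, adjusted R^2).
    """
    y, name = _as_array(trait)
    ws = _Workspace(y, encodings)
    res, steps = _eliminate(ws, threshold)
    final = ws.to_model_fit(res, trait_name or name)
    trace = pd.DataFrame(
        steps, columns=["step", "gene", "p_value", "F", "r2_after", "adj_r2_after"])
    return EliminationTrace(steps=trace, final=final)


def _eliminate(ws: _Workspace, threshold: float) -> tuple[dict, list]:
    """The elimination loop on a prepared workspace (shared with the
    permutation driver, which skips the reporting layer)."""
    current = tuple(e.gene for e in ws.encodings)
    steps = []
    res = ws.fit_subset(current) if current else None
    step = 0
    while current:
        tests = res["tests"]
        # candidate for removal: max P; ties -> smaller F -> lexicographic
        def sort_key(t):
            gene, F, df1, df2, P = t
            fkey = np.inf if np.isnan(F) else F
            return (-P, fkey, gene)
        worst = sorted(tests, key=sort_key)[0]
        if not (worst[4] > threshold):
            break
        step += 1
        current = tuple(g for g in current if g != worst[0])
        res = ws.fit_subset(current)
        steps.append((step, worst[0], worst[4], worst[1],
                      res["r2"], res["adj_r2"]))
    if res is None:
        res = ws.fit_subset(())
    return res, steps


def _share_gram(ws: _Workspace, y: np.ndarray) -> _Workspace:
    """A workspace for a new trait over the same encodings: the Gram matrix
    is reused, only the trait-side vectors are recomputed."""
    y = np.asarray(y, dtype=float)
    if len(y) != ws.n:
        raise ValueError("trait length does not match the shared design")
    if np.isnan(y).any():
        raise DegenerateInputError("trait contains missing values")
    new = _Workspace.__new__(_Workspace)
    new.n = ws.n
    new.y = y
    new.tss = float(np.sum((y - y.mean()) ** 2))
    if new.tss <= 0:
        raise DegenerateInputError("trait has zero variance")
    new.encodings = ws.encodings
    new.noninformative = ws.noninformative
    new.block = ws.block
    new.meta = ws.meta
    new.G = ws.G
    new.yty = float(y @ y)
    gvec = np.zeros(len(ws.g))
    gvec[0] = y.sum()
    for enc in ws.encodings:
        gvec[ws.block[enc.gene]] = np.bincount(
            enc.codes, weights=y, minlength=enc.n_levels)[1:]
    new.g = gvec
    return new


def estimate_combination_effects(fit: ModelFit) -> EffectSummary:
    """Summarize per-level effect contrasts and their signs for one fit.

    Counts how many estimated non-reference composite levels have positive
    versus negative effects relative to each gene's reference level.
    """
    eff = fit.effects
    est = eff.loc[~eff["is_reference"], "estimate"].dropna()
    return EffectSummary(
        trait=fit.trait,
        effects=eff.copy(),
        n_positive=int((est > 0).sum()),
        n_negative=int((est < 0).sum()),
    )


def design_matrix(encodings: list[FactorEncoding]) -> tuple[np.ndarray, list]:
    """Materialize the dummy-coded design (intercept first) with column meta.

    Provided for inspection and external cross-checks; the fitting path
    itself works from the Gram matrix.
    """
    n = len(encodings[0].codes)
    cols = [np.ones(n)]
    meta = [("(intercept)", "(intercept)")]
    for enc in encodings:
        if not enc.informative:
            continue
        for li in range(1, enc.n_levels):
            cols.append((enc.codes == li).astype(float))
            meta.append((enc.gene, enc.levels[li]))
    return np.column_stack(cols), meta
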