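"""Composite (constructed) genotypes and their categorical encoding.

Each animal's genotype over a gene's SNP set is written as the minor-allele
copy counts joined by ``"-"`` in set order — e.g. ``"0-2-1"`` for a
three-SNP set.  The resulting labels are the levels of a categorical factor
whose design-matrix form (dummy coding against the most frequent level,
rare levels pooled) feeds the general linear model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RARE_LEVEL",
    "CompositeGenotype",
    "FactorEncoding",
    "determine_minor_alleles",
    "build_composite",
    "parse_composite_label",
    "encode_factor",
    "encode_gene_sets",
]

#: Pooled level collecting composite classes rarer than ``min_level_count``.
RARE_LEVEL = "RARE"


@dataclass(frozen=True)
class CompositeGenotype:
    """Per-animal composite labels for one gene's SNP set."""

    gene: str
    snp_ids: tuple[str, ...]
    labels: pd.Series            # animal -> "0-2-1"-style label
    imputed: pd.Series           # animal -> had >= 1 missing call imputed


@dataclass(frozen=True)
class FactorEncoding:
    """Design-matrix-ready categorical form of a composite genotype.

    Levels are ordered by count descending then lexicographic; the
    reference level is the most frequent (first).  ``codes[i]`` indexes the
    animal's level.  A gene with fewer than two levels after pooling is
    non-informative and excluded from modelling.
    """

    gene: str
    levels: tuple[str, ...]
    counts: tuple[int, ...]
    codes: np.ndarray
    pooled_labels: tuple[str, ...]  # original labels merged into RARE

    @property
    def reference(self) -> str:
        return self.levels[0]

    @property
    def informative(self) -> bool:
        return len(self.levels) >= 2

    @property
    def n_levels(self) -> int:
        return len(self.levels)


# ---------------------------------------------------------------------------
# Minor-allele recoding
# ---------------------------------------------------------------------------

def determine_minor_alleles(
    genotypes: pd.DataFrame,
    snp_map: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recode genotype columns to count copies of the sample minor allele.

    The minor allele is the one with sample frequency < 0.5; columns whose
    coded allele frequency exceeds 0.5 are complemented (g -> 2 - g).  A
    frequency of exactly 0.5 keeps the coded (alt) allele as minor, so the
    operation is idempotent.  Monomorphic SNPs are flagged and retained
    with all-zero counts.

    Returns the recoded matrix and a per-SNP annotation frame
    (``snp_id, coded_freq, maf, recoded, monomorphic`` and, when ``snp_map``
    provides ref/alt labels, ``minor_allele``).
    """
    values = genotypes.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(values), axis=0)
    if (n_obs == 0).any():
        bad = genotypes.columns[n_obs == 0][0]
        raise ValueError(f"SNP {bad!r} has no non-missing calls")
    freq = np.nanmean(values, axis=0) / 2.0
    flip = freq > 0.5  # strict: freq == 0.5 keeps alt as minor
    recoded = values.copy()
    recoded[:, flip] = 2.0 - recoded[:, flip]
    maf = np.minimum(freq, 1.0 - freq)
    ann = pd.DataFrame(
        {
            "snp_id": genotypes.columns,
            "coded_freq": freq,
            "maf": maf,
            "recoded": flip,
            "monomorphic": maf == 0.0,
        }
    )
    if snp_map is not None and {"ref", "alt"}.issubset(snp_map.columns):
        lookup = snp_map.set_index("snp_id")
        ref = lookup["ref"].reindex(ann["snp_id"]).to_numpy()
        alt = lookup["alt"].reindex(ann["snp_id"]).to_numpy()
        ann["minor_allele"] = np.where(flip, ref, alt)
    out = pd.DataFrame(recoded, index=genotypes.index, columns=genotypes.columns)
    return out, ann


# ---------------------------------------------------------------------------
# Composite construction
# ---------------------------------------------------------------------------

def _impute_modal(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing calls with the column's modal count (ties -> smaller)."""
    imputed_any = np.zeros(sub.shape[0], dtype=bool)
    if not np.isnan(sub).any():
        return sub, imputed_any
    sub = sub.copy()
    for j in range(sub.shape[1]):
        col = sub[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        counts = np.bincount(col[~miss].astype(int), minlength=3)
        modal = int(np.argmax(counts))  # argmax takes the smaller on ties
        col[miss] = modal
        imputed_any |= miss
    return sub, imputed_any


def build_composite(
    genotypes: pd.DataFrame,
    gene_set,
    missing_policy: str = "impute",
) -> CompositeGenotype:
    """Concatenate minor-allele counts over a gene's SNP set per animal.

    ``missing_policy="impute"`` (default) fills missing calls with the
    SNP's modal count and flags the animal; ``"drop"`` labels such animals
    ``None`` so callers can exclude them.
    """
    if gene_set.empty:
        raise ValueError(f"gene {gene_set.gene!r} has an empty SNP set")
    missing_cols = [s for s in gene_set.snp_ids if s not in genotypes.columns]
    if missing_cols:
        raise KeyError(f"SNPs absent from genotype matrix: {missing_cols}")
    sub = genotypes[list(gene_set.snp_ids)].to_numpy(dtype=float)
    if missing_policy == "impute":
        sub, imputed = _impute_modal(sub)
        labels = ["-".join(str(int(v)) for v in row) for row in sub]
    elif missing_policy == "drop":
        imputed = np.isnan(sub).any(axis=1)
        labels = [None if bad else "-".join(str(int(v)) for v in row)
                  for row, bad in zip(sub, imputed)]
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return CompositeGenotype(
        gene=gene_set.gene,
        snp_ids=tuple(gene_set.snp_ids),
        labels=pd.Series(labels, index=genotypes.index, name=gene_set.gene),
        imputed=pd.Series(imputed, index=genotypes.index),
    )


def parse_composite_label(label: str) -> tuple[int, ...]:
    """Invert a composite label back to per-SNP minor-allele counts."""
    counts = tuple(int(tok) for tok in label.split("-"))
    if any(c not in (0, 1, 2) for c in counts):
        raise ValueError(f"invalid composite label {label!r}")
    return counts


# ---------------------------------------------------------------------------
# Factor encoding (with rare-level pooling)
# ---------------------------------------------------------------------------

def _encode(labels: np.ndarray, uniq: np.ndarray, inverse: np.ndarray,
            counts: np.ndarray, gene: str, min_level_count: int) -> FactorEncoding:
    rare = counts < min_level_count
    if rare.any() and rare.sum() >= 1:
        kept = [(str(u), int(c)) for u, c, r in zip(uniq, counts, rare) if not r]
        pooled = tuple(sorted(str(u) for u, r in zip(uniq, rare) if r))
        kept.append((RARE_LEVEL, int(counts[rare].sum())))
    else:
        kept = [(str(u), int(c)) for u, c in zip(uniq, counts)]
        pooled = ()
    # deterministic ordering: count desc, then lexicographic label
    kept.sort(key=lambda lc: (-lc[1], lc[0]))
    levels = tuple(l for l, _ in kept)
    level_counts = tuple(c for _, c in kept)
    index_of = {l: i for i, l in enumerate(levels)}
    rare_idx = index_of.get(RARE_LEVEL, -1)
    remap = np.array(
        [rare_idx if r else index_of[str(u)] for u, r in zip(uniq, rare)],
        dtype=np.int64,
    )
    codes = remap[inverse]
    return FactorEncoding(
        gene=gene,
        levels=levels,
        counts=level_counts,
        codes=codes,
        pooled_labels=pooled,
    )


def encode_factor(composite: CompositeGenotype, min_level_count: int = 5) -> FactorEncoding:
    """Turn composite labels into an ordered, rare-pooled categorical factor.

    Distinct labels become levels; levels observed fewer than
    ``min_level_count`` times merge into a pooled :data:`RARE_LEVEL`.
    The reference level is the most frequent (ties broken lexicographically).
    Animals with ``None`` labels (the ``drop`` missing policy) must be
    removed before encoding.
    """
    labels = composite.labels.to_numpy()
    if any(l is None for l in labels):
        raise ValueError(
            f"gene {composite.gene!r} has unlabelled animals; drop them first")
    uniq, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    return _encode(labels, uniq, inverse, counts, composite.gene, min_level_count)


def encode_gene_sets(
    genotypes: pd.DataFrame | np.ndarray,
    gene_sets,
    min_level_count: int = 5,
    columns=None,
) -> list[FactorEncoding]:
    """Encode many gene sets directly from the genotype matrix.

    Equivalent to ``encode_factor(build_composite(...))`` per gene but
    without materializing per-animal label strings — the hot path for
    permutation re-analysis.  ``columns`` must list the SNP order of an
    ndarray input; empty gene sets are skipped.
    """
    if isinstance(genotypes, pd.DataFrame):
        values = genotypes.to_numpy(dtype=float)
        columns = genotypes.columns
    else:
        values = genotypes
        if columns is None:
            raise ValueError("columns required with an ndarray input")
    col_of = {s: j for j, s in enumerate(columns)}
    return [
        encode_columns(values, np.array([col_of[s] for s in gs.snp_ids]),
                       gs.gene, min_level_count)
        for gs in gene_sets if not gs.empty
    ]


def encode_columns(values: np.ndarray, cols: np.ndarray, gene: str,
                   min_level_count: int = 5) -> FactorEncoding:
    """Encode one gene's factor straight from genotype matrix columns."""
    sub = values[:, cols]
    if np.isnan(sub).any():
        sub, _ = _impute_modal(sub.copy())
    k = len(cols)
    radix = (3 ** np.arange(k)[::-1]).astype(np.int64)
    codes_raw = sub.astype(np.int64) @ radix
    uniq_codes, inverse, counts = np.unique(
        codes_raw, return_inverse=True, return_counts=True)
    uniq = _labels_from_codes(uniq_codes, k)
    return _encode(None, uniq, inverse, counts, gene, min_level_count)


def _labels_from_codes(codes: np.ndarray, k: int) -> np.ndarray:
    digits = ((codes[:, None] // (3 ** np.arange(k)[::-1])) % 3).astype("U1")
    label = digits[:, 0]
    for j in range(1, k):
        label = np.char.add(np.char.add(label, "-"), digits[:, j])
    return label
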