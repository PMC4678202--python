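"""Synthetic genotype panels, trait tables and qPCR Ct tables.

The generator emulates the structure the association analysis assumes: a
panel of ~1,500 progeny-tested bulls genotyped at ~100 SNPs clustered
within 500 kb of 29 candidate gene loci (8 SOCS-family + 21 JAK-STAT
pathway genes) plus a genome-wide background of unlinked SNPs; seven
quantitative traits (breeding values) with additive effects attached to a
configurable set of causal genes; and a 5-cow x 3-stage x triplicate
cycle-threshold table for the expression module.

Animals are unrelated, SNPs are in Hardy-Weinberg equilibrium and, by
default, in linkage equilibrium; an exchangeable within-block correlation
knob (``ld_rho``) exists to probe collinearity handling downstream.  Every
output is a pure function of the integer ``seed``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "DEFAULT_GENE_NAMES",
    "SOCS_GENES",
    "JAKSTAT_GENES",
    "simulate_snp_map",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_qpcr",
    "simulate_panel",
]

#: The eight SOCS-family candidate genes (seven SOCS paralogues plus CISH).
SOCS_GENES = (
    "SOCS1", "SOCS2", "SOCS3", "SOCS4", "SOCS5", "SOCS6", "SOCS7", "CISH",
)

#: Twenty-one JAK-STAT pathway members used as the wider candidate list.
JAKSTAT_GENES = (
    "JAK1", "JAK2", "JAK3", "TYK2",
    "STAT1", "STAT2", "STAT3", "STAT4", "STAT5A", "STAT5B", "STAT6",
    "PRLR", "GHR", "EPO", "LEPR", "OSMR",
    "IL2", "IL3", "IL4R", "IL6R", "IL10",
)

DEFAULT_GENE_NAMES = SOCS_GENES + JAKSTAT_GENES

DEFAULT_TRAITS = ("APR", "ASI", "PY", "PP", "MY", "FY", "FP")

_DEFAULT_GENOME = tuple((f"chr{i}", 100_000_000) for i in range(1, 6))

_BASES = np.array(["A", "C", "G", "T"])


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


class PlacementError(RuntimeError):
    """Raised when gene neighborhoods cannot be placed on the genome."""


def _stable_hash(obj) -> int:
    """Deterministic 31-bit hash of a repr-able object (stable across runs)."""
    digest = hashlib.sha256(repr(obj).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic panel.

    Parameters
    ----------
    n_animals
        Panel size; default 1546 sires.
    n_candidate_genes
        Number of candidate gene loci (default 29 = 8 SOCS + 21 JAK-STAT).
    n_background_loci
        Genome-background SNPs outside any candidate design, available as
        anchors for the random-locus permutation null.
    snps_per_gene
        Mean SNP count per candidate neighborhood (Poisson, minimum 1);
        3.4 x 29 genes ~ 98 candidate SNPs.
    genome
        Sequence of ``(chromosome, length_bp)`` pairs.
    maf_range
        Minor-allele-frequency interval in (0, 0.5]; each SNP draws its MAF
        uniformly from this interval.
    window
        Half-width (bp) of the gene neighborhood used both for SNP
        placement and downstream assignment; default 500 kb.
    causal_genes
        Either ``{gene: variance_fraction}`` applied to every trait, or
        ``{trait: {gene: variance_fraction}}``.  Fractions per trait must be
        non-negative and sum to < 1.
    trait_names
        Trait columns to simulate; default the seven dairy traits
        (APR, ASI, PY, PP, MY, FY, FP).
    residual_sd
        Standard deviation of the non-genetic trait component.
    missing_rate
        Genotype missingness fraction in [0, 0.1].
    ld_rho
        Exchangeable genotype correlation within SNP blocks (SNPs < 1 Mb
        apart on one chromosome); 0 disables.
    seed
        Master seed; fully determines every generated table.
    """

    n_animals: int = 1546
    n_candidate_genes: int = 29
    n_background_loci: int = 2000
    snps_per_gene: float = 3.4
    genome: Sequence[tuple[str, int]] = _DEFAULT_GENOME
    maf_range: tuple[float, float] = (0.05, 0.45)
    window: int = 500_000
    causal_genes: Mapping = field(default_factory=dict)
    trait_names: Sequence[str] = DEFAULT_TRAITS
    residual_sd: float = 1.0
    missing_rate: float = 0.0
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.n_animals < 2 or self.n_candidate_genes < 1:
            raise ConfigError("need at least 2 animals and 1 candidate gene")
        if not self.genome:
            raise ConfigError("genome must be non-empty")
        if not (0.0 <= self.missing_rate <= 0.10):
            raise ConfigError("missing_rate must be in [0, 0.1]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError("ld_rho must be in [0, 1)")
        for trait, frac in self.causal_map().items():
            total = sum(frac.values())
            if any(v < 0 for v in frac.values()) or total >= 1.0:
                raise ConfigError(
                    f"variance fractions for trait {trait!r} must be >= 0 "
                    f"and sum to < 1 (got sum {total})"
                )

    def gene_names(self) -> tuple[str, ...]:
        n = self.n_candidate_genes
        names = list(DEFAULT_GENE_NAMES[:n])
        names += [f"GENE{i:02d}" for i in range(len(names) + 1, n + 1)]
        return tuple(names)

    def causal_map(self) -> dict[str, dict[str, float]]:
        """Normalize ``causal_genes`` to ``{trait: {gene: fraction}}``."""
        cg = dict(self.causal_genes)
        if cg and all(isinstance(v, Mapping) for v in cg.values()):
            per_trait = {t: dict(cg.get(t, {})) for t in self.trait_names}
        else:
            per_trait = {t: dict(cg) for t in self.trait_names}
        return per_trait

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _rng(config_seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config_seed), *stream]))


# ---------------------------------------------------------------------------
# SNP map and gene regions
# ---------------------------------------------------------------------------

def simulate_snp_map(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place gene regions and SNPs on the synthetic genome.

    Returns
    -------
    snp_map : DataFrame
        Columns ``snp_id, chrom, pos, ref, alt, is_candidate`` sorted by
        (chrom, pos); 1-based positions, unique ids.
    regions : DataFrame
        Columns ``gene, chrom, start, end`` (1-based inclusive).
    """
    rng = _rng(config.seed, 1)
    genome = list(config.genome)
    lengths = np.array([l for _, l in genome], dtype=float)
    w = config.window

    # Gene bodies 5-50 kb, placed so the +-window neighborhood fits on the
    # chromosome and does not overlap another gene's neighborhood.
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in genome}
    rows = []
    for gene in config.gene_names():
        ok = False
        last_chrom = genome[0][0]
        for _ in range(2000):
            ci = rng.choice(len(genome), p=lengths / lengths.sum())
            chrom, length = genome[ci]
            last_chrom = chrom
            glen = int(rng.integers(5_000, 50_001))
            lo, hi = w + 1, length - w - glen
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi + 1))
            end = start + glen - 1
            nb = (start - w, end + w)
            if any(not (nb[1] < a or nb[0] > b) for a, b in placed[chrom]):
                continue
            placed[chrom].append(nb)
            rows.append((gene, chrom, start, end))
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place gene {gene!r}: genome too short "
                f"(last attempt on chromosome {last_chrom!r})"
            )
    regions = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])

    # Candidate SNPs inside each neighborhood: Poisson(snps_per_gene), min 1.
    snp_rows = []
    for _, r in regions.iterrows():
        k = max(1, int(rng.poisson(config.snps_per_gene)))
        lo, hi = r.start - w, r.end + w
        pos = set()
        while len(pos) < k:
            pos.update(int(p) for p in rng.integers(lo, hi + 1, size=k - len(pos)))
        for p in sorted(pos):
            snp_rows.append((r.chrom, p, True))

    # Background SNPs anywhere outside the candidate neighborhoods (keeps
    # the candidate SNP count at its design value and leaves the random-
    # locus null free of true-candidate contamination).
    n_bg = 0
    while n_bg < config.n_background_loci:
        ci = rng.choice(len(genome), p=lengths / lengths.sum())
        chrom, length = genome[ci]
        p = int(rng.integers(1, length + 1))
        if any(a <= p <= b for a, b in placed[chrom]):
            continue
        snp_rows.append((chrom, p, False))
        n_bg += 1

    snp_map = pd.DataFrame(snp_rows, columns=["chrom", "pos", "is_candidate"])
    snp_map = (
        snp_map.drop_duplicates(["chrom", "pos"])
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    alleles = np.array([rng.choice(4, size=2, replace=False)
                        for _ in range(len(snp_map))])
    snp_map.insert(0, "snp_id", [f"snp{i + 1:05d}" for i in range(len(snp_map))])
    snp_map["ref"] = _BASES[alleles[:, 0]]
    snp_map["alt"] = _BASES[alleles[:, 1]]
    return snp_map[["snp_id", "chrom", "pos", "ref", "alt", "is_candidate"]], regions


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(snp_map: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw a minor-allele-count matrix (animals x SNPs) under HWE.

    Each SNP draws a MAF uniformly from ``config.maf_range``; genotypes are
    Binomial(2, MAF).  With ``ld_rho > 0`` the two haploid allele draws are
    correlated across SNPs of the same physical block (consecutive SNPs
    < 1 Mb apart on one chromosome) through a Gaussian copula, giving an
    exchangeable positive genotype correlation within the block.  Missing
    calls (NaN) are masked in uniformly at ``missing_rate``.
    """
    if snp_map.empty:
        raise ValueError("snp_map is empty")
    rng = _rng(config.seed, 2)
    n, m = config.n_animals, len(snp_map)
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    if config.ld_rho == 0.0:
        geno = rng.binomial(2, maf, size=(n, m)).astype(float)
    else:
        blocks = _ld_blocks(snp_map)
        thresh = norm.ppf(maf)
        geno = np.zeros((n, m))
        rho = config.ld_rho
        for _ in range(2):  # two haploid draws -> Binomial(2, maf) margins
            z = rng.standard_normal((n, m))
            for blk in blocks:
                if len(blk) > 1:
                    common = rng.standard_normal(n)
                    z[:, blk] = (np.sqrt(rho) * common[:, None]
                                 + np.sqrt(1 - rho) * z[:, blk])
            geno += (z < thresh)

    if config.missing_rate > 0:
        mask = rng.uniform(size=(n, m)) < config.missing_rate
        geno[mask] = np.nan

    animals = [f"bull{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(geno, index=pd.Index(animals, name="animal"),
                        columns=snp_map["snp_id"].to_numpy())


def _ld_blocks(snp_map: pd.DataFrame, max_gap: int = 1_000_000) -> list[np.ndarray]:
    blocks = []
    order = snp_map.reset_index(drop=True)
    for _, grp in order.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        idx = grp.index.to_numpy()
        cuts = np.where(np.diff(pos) > max_gap)[0] + 1
        blocks.extend(np.split(idx, cuts))
    return blocks


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_traits(genotypes: pd.DataFrame, gene_sets, config: SimConfig) -> pd.DataFrame:
    """Simulate breeding values with additive effects on causal gene sets.

    Each trait is the sum of per-gene additive scores (per-SNP effects drawn
    once per seed per gene, signs symmetric) plus a Gaussian residual.  The
    realized components are rescaled — and the residual residualized against
    the causal scores — so each causal gene's realized variance fraction
    matches the configured value and the residual variance is exactly
    ``residual_sd**2``; the total trait variance is therefore
    ``residual_sd**2 / (1 - sum(fractions))``.

    A trait column is a pure function of ``(seed, its causal configuration)``:
    traits configured identically are identical by construction.
    """
    by_gene = {gs.gene: gs for gs in gene_sets}
    causal = config.causal_map()
    for trait, frac in causal.items():
        for gene in frac:
            if gene not in by_gene:
                raise ConfigError(
                    f"causal gene {gene!r} for trait {trait!r} has no SNP set")

    n = len(genotypes)
    values = genotypes.to_numpy(dtype=float)
    col_of = {s: j for j, s in enumerate(genotypes.columns)}

    def gene_score(gene: str) -> np.ndarray:
        gs = by_gene[gene]
        cols = [col_of[s] for s in gs.snp_ids]
        sub = values[:, cols].copy()
        if np.isnan(sub).any():  # mean-impute for scoring only
            mu = np.nanmean(sub, axis=0)
            inds = np.where(np.isnan(sub))
            sub[inds] = np.take(mu, inds[1])
        erng = _rng(config.seed, 4, _stable_hash(gene))
        eff = erng.standard_normal(len(cols))  # symmetric +- signs
        s = sub @ eff
        return s - s.mean()

    out = {}
    for trait in config.trait_names:
        frac = causal.get(trait, {})
        sig = tuple(sorted(frac.items()))
        trng = _rng(config.seed, 3, _stable_hash(sig))
        e = trng.standard_normal(n)
        total_var = config.residual_sd**2 / (1.0 - sum(frac.values()))
        parts = []
        scores = []
        for gene in sorted(frac):
            s = gene_score(gene)
            v = s.var()
            if v <= 0:
                raise ConfigError(f"causal gene {gene!r} has zero score variance")
            parts.append(s * np.sqrt(frac[gene] * total_var / v))
            scores.append(s)
        if scores:  # make the residual orthogonal to every causal score
            Q, _ = np.linalg.qr(np.column_stack(scores))
            e = e - Q @ (Q.T @ e)
        e = e - e.mean()
        e *= config.residual_sd / e.std()
        out[trait] = np.sum(parts, axis=0) + e if parts else e
    return pd.DataFrame(out, index=genotypes.index)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

QPCR_STAGES = ("pregnancy", "lactation", "involution")


def simulate_qpcr(
    n_cows: int = 5,
    stage_means: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    *,
    cow_sd: float = 0.0,
    baseline_ct: float = 20.0,
    reference_gene: str = "RPLP0",
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a balanced cow x stage x gene x triplicate Ct table.

    ``stage_means`` maps gene -> stage -> log2 expression offset; a +1
    offset halves the target's expected Ct relative to baseline by one
    cycle, i.e. doubles its normalized ratio.  The reference gene is drawn
    around the same fixed baseline, so with all offsets zero, ``cow_sd = 0``
    and ``noise_sd = 0`` every normalized ratio is exactly 1.  Cow effects
    (sd ``cow_sd``) shift target genes only, creating the block structure
    the cow-blocked ANOVA removes.  Triplicates share the cell truth and
    differ only by measurement noise.
    """
    if n_cows < 2:
        raise ValueError("need at least 2 cows")
    stage_means = {g: dict(v) for g, v in (stage_means or {}).items()} or {
        g: {} for g in ("SOCS1", "SOCS2", "SOCS3", "SOCS4", "SOCS5")
    }
    for gene, offs in stage_means.items():
        unknown = set(offs) - set(QPCR_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)} for gene {gene!r}")

    rng = _rng(seed, 5)
    cows = [f"cow{i + 1}" for i in range(n_cows)]
    cow_eff = rng.normal(0.0, cow_sd, size=n_cows) if cow_sd > 0 else np.zeros(n_cows)
    rows = []
    for ci, cow in enumerate(cows):
        for stage in QPCR_STAGES:
            for gene, offs in stage_means.items():
                true_ct = baseline_ct - offs.get(stage, 0.0) - cow_eff[ci]
                for rep in range(1, n_replicates + 1):
                    ct = true_ct + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append((cow, stage, gene, rep, ct))
            for rep in range(1, n_replicates + 1):
                ct = baseline_ct + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((cow, stage, reference_gene, rep, ct))
    return pd.DataFrame(rows, columns=["cow", "stage", "gene", "replicate", "ct"])


# ---------------------------------------------------------------------------
# Convenience bundle
# ---------------------------------------------------------------------------

def simulate_panel(config: SimConfig) -> dict:
    """Generate the full association-ready bundle for one configuration.

    Returns a dict with keys ``snp_map, regions, genotypes, gene_sets,
    traits`` — the chain map -> genotypes -> neighborhood assignment ->
    traits, all under ``config.seed``.
    """
    from .regions import assign_snps_to_genes

    snp_map, regions = simulate_snp_map(config)
    genotypes = simulate_genotypes(snp_map, config)
    gene_sets = assign_snps_to_genes(snp_map, regions, window=config.window)
    traits = simulate_traits(genotypes, gene_sets, config)
    return {
        "snp_map": snp_map,
        "regions": regions,
        "genotypes": genotypes,
        "gene_sets": gene_sets,
        "traits": traits,
        "config": config,
    }
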