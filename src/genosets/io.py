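"""Readers, writers, run configuration and end-to-end orchestration.

All internal coordinates are 1-based inclusive; conversion to and from
0-based half-open BED happens only at the I/O boundary.  Reports are plain
TSV with a YAML sidecar capturing the configuration and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .composite import determine_minor_alleles, encode_gene_sets
from .glm import backward_eliminate, estimate_combination_effects
from .permutation import run_permutations, summarize_tail
from .regions import assign_snps_to_genes

__all__ = [
    "read_genotype_matrix", "write_genotype_matrix",
    "read_snp_map", "write_snp_map",
    "read_gene_regions", "write_gene_regions",
    "read_trait_table", "write_trait_table",
    "read_ct_table", "write_ct_table",
    "write_simulated_bundle",
    "RunConfig", "load_run_config", "run_full_analysis",
]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def write_genotype_matrix(matrix: pd.DataFrame, path) -> None:
    """Write animals x SNPs minor-allele counts as TSV (missing -> NA)."""
    out = matrix.copy()
    out.index.name = "animal"
    formatted = out.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    formatted.to_csv(path, sep="\t")


def read_genotype_matrix(path, fmt: str = "tsv"):
    """Read a genotype matrix from TSV or VCF.

    TSV returns ``(matrix, None)``; VCF returns ``(matrix, snp_map)`` with
    the map populated from the records.  Cells outside {0, 1, 2, NA} (or a
    malformed GT) raise with the offending location; duplicated SNP ids
    raise.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False)
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicated SNP id {dup!r}")
        raw = df.to_numpy(dtype=object)
        values = np.full(df.shape, np.nan)
        for tok, val in (("0", 0.0), ("1", 1.0), ("2", 2.0)):
            values[raw == tok] = val
        bad = ~np.isin(raw, ("0", "1", "2", "NA", ""))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"malformed genotype {raw[i, j]!r} at line {i + 2}, "
                f"column {df.columns[j]!r}")
        return pd.DataFrame(values, index=df.index, columns=df.columns), None
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"non-biallelic record at {v.CHROM}:{v.POS}")
        sid = v.ID or f"{v.CHROM}_{v.POS}"
        if sid in ids:
            raise ValueError(f"duplicated SNP id {sid!r}")
        counts = []
        for gt in v.genotypes:  # [a0, a1, phased]; phase is irrelevant here
            a = gt[:-1]
            if any(x < 0 for x in a):  # half-calls and no-calls -> missing
                counts.append(np.nan)
            else:
                counts.append(float(sum(1 for x in a if x == 1)))
        ids.append(sid)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(counts)
    matrix = pd.DataFrame(np.array(rows).T,
                          index=pd.Index(samples, name="animal"), columns=ids)
    snp_map = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": poss,
                            "ref": refs, "alt": alts})
    return matrix, snp_map


# ---------------------------------------------------------------------------
# SNP map, regions, traits, Ct
# ---------------------------------------------------------------------------

def write_snp_map(snp_map: pd.DataFrame, path) -> None:
    snp_map.to_csv(path, sep="\t", index=False)


def read_snp_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicated SNP id {dup!r}")
    return df


def write_gene_regions(regions: pd.DataFrame, path, fmt: str = "tsv1") -> None:
    """Write regions as 1-based TSV (``tsv1``) or 0-based half-open BED."""
    if fmt == "tsv1":
        regions[["chrom", "start", "end", "gene"]].to_csv(
            path, sep="\t", index=False, header=False)
    elif fmt == "bed":
        bed = regions.copy()
        bed["start"] = bed["start"] - 1  # 1-based inclusive -> 0-based half-open
        bed[["chrom", "start", "end", "gene"]].to_csv(
            path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown region format {fmt!r}")


def read_gene_regions(path, fmt: str = "tsv1") -> pd.DataFrame:
    """Read gene regions; BED is converted to 1-based inclusive on read."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene"])
    if df["gene"].isna().any():
        raise ValueError("region records require a name column")
    if fmt == "bed":
        df["start"] = df["start"] + 1
    elif fmt != "tsv1":
        raise ValueError(f"unknown region format {fmt!r}")
    bad = df[df["start"] > df["end"]]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"region {r['gene']!r} has start > end after conversion "
            f"({r['start']} > {r['end']})")
    return df[["gene", "chrom", "start", "end"]]


def write_trait_table(traits: pd.DataFrame, path) -> None:
    out = traits.copy()
    out.index.name = "animal"
    out.to_csv(path)


def read_trait_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicated animal ids in trait table")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("trait table contains non-finite values")
    return df


def write_ct_table(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def write_simulated_bundle(bundle: dict, outdir) -> None:
    """Write a `simulate_panel` bundle to TSV/CSV/BED files in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotype_matrix(bundle["genotypes"], outdir / "genotypes.tsv")
    write_snp_map(bundle["snp_map"], outdir / "snp_map.tsv")
    write_gene_regions(bundle["regions"], outdir / "gene_regions.tsv", "tsv1")
    write_gene_regions(bundle["regions"], outdir / "gene_regions.bed", "bed")
    write_trait_table(bundle["traits"], outdir / "traits.csv")


# ---------------------------------------------------------------------------
# Run configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and parameters for a full association run."""

    genotypes: str
    snp_map: str
    regions: str
    traits: str
    outdir: str
    window: int = 500_000
    threshold: float = 0.05
    min_level_count: int = 5
    b_permutations: int = 0
    n_loci: int | None = None
    seed: int = 0
    gene_lists: dict = field(default_factory=dict)  # name -> list of genes (None = all)
    trait_list: list | None = None

    def validate(self) -> None:
        for attr in ("genotypes", "snp_map", "regions", "traits"):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"{attr} path does not exist: {p}")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def run_full_analysis(config: RunConfig) -> dict:
    """Execute assign -> composite -> eliminate per trait and gene list.

    Emits per-trait gene-combination reports (retained combination, per-gene
    P, P-value range, R^2, adjusted R^2), an adjusted-variation matrix
    (trait x gene list), elimination traces, effect-sign summaries, and —
    when ``b_permutations > 0`` — random-locus null distributions with tail
    summaries.  All outputs are TSV plus a YAML sidecar of the
    configuration.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genotypes, _ = read_genotype_matrix(config.genotypes)
    snp_map = read_snp_map(config.snp_map)
    regions = read_gene_regions(config.regions)
    traits = read_trait_table(config.traits)
    if config.trait_list:
        traits = traits[list(config.trait_list)]

    recoded, allele_ann = determine_minor_alleles(genotypes, snp_map)
    gene_lists = dict(config.gene_lists) or {"all_genes": None}

    combo_rows, adj_matrix, effect_rows, trace_frames = [], {}, [], []
    fits = {}
    for list_name, genes in gene_lists.items():
        sub_regions = (regions if genes is None
                       else regions[regions["gene"].isin(genes)])
        gene_sets = assign_snps_to_genes(snp_map, sub_regions, config.window)
        encodings = encode_gene_sets(recoded, gene_sets, config.min_level_count)
        for trait in traits.columns:
            trace = backward_eliminate(
                traits[trait], encodings, threshold=config.threshold,
                trait_name=trait)
            fit = trace.final
            fits[(list_name, trait)] = fit
            summary = estimate_combination_effects(fit)
            combo_rows.append({
                "gene_list": list_name,
                "trait": trait,
                "combination": " + ".join(fit.genes) if fit.genes else "(none)",
                "n_retained": len(fit.genes),
                "p_min": fit.min_p if fit.genes else np.nan,
                "p_max": fit.max_p if fit.genes else np.nan,
                "r2": fit.r2,
                "adj_r2": fit.adj_r2,
                "n_positive_effects": summary.n_positive,
                "n_negative_effects": summary.n_negative,
            })
            adj_matrix.setdefault(trait, {})[list_name] = fit.adj_r2
            if len(fit.effects):
                eff = fit.effects.copy()
                eff.insert(0, "trait", trait)
                eff.insert(0, "gene_list", list_name)
                effect_rows.append(eff)
            tr = trace.steps.copy()
            tr.insert(0, "trait", trait)
            tr.insert(0, "gene_list", list_name)
            trace_frames.append(tr)

    combos = pd.DataFrame(combo_rows)
    adj_frame = pd.DataFrame(adj_matrix).T
    adj_frame.index.name = "trait"
    effects = (pd.concat(effect_rows, ignore_index=True) if effect_rows
               else pd.DataFrame(columns=["gene_list", "trait", "gene",
                                          "level", "estimate", "se",
                                          "is_reference"]))
    traces = pd.concat(trace_frames, ignore_index=True)
    combos.to_csv(outdir / "gene_combinations.tsv", sep="\t", index=False)
    (adj_frame * 100).to_csv(outdir / "adjusted_variation_pct.tsv", sep="\t")
    effects.to_csv(outdir / "effects.tsv", sep="\t", index=False)
    traces.to_csv(outdir / "elimination_trace.tsv", sep="\t", index=False)
    allele_ann.to_csv(outdir / "minor_alleles.tsv", sep="\t", index=False)

    tails = {}
    nulls = {}
    if config.b_permutations > 0:
        for list_name, genes in gene_lists.items():
            sub_regions = (regions if genes is None
                           else regions[regions["gene"].isin(genes)])
            n_loci = config.n_loci or len(sub_regions)
            nulls[list_name] = run_permutations(
                recoded, traits, snp_map, sub_regions,
                b=config.b_permutations, n_loci=n_loci,
                threshold=config.threshold, window=config.window,
                min_level_count=config.min_level_count, seed=config.seed)
            for trait, null in nulls[list_name].items():
                null.table.to_csv(
                    outdir / f"null_{list_name}_{trait}.tsv", sep="\t",
                    index=False)
                tails[(list_name, trait)] = summarize_tail(
                    fits[(list_name, trait)], null)
        tail_frame = pd.DataFrame([
            {"gene_list": ln, "trait": t,
             "observed_adj_r2": s.observed_adj_r2,
             "tail_adj_r2": s.tail_adj_r2, "tail_r2": s.tail_r2,
             "tail_min_p": s.tail_min_p}
            for (ln, t), s in tails.items()])
        tail_frame.to_csv(outdir / "tail_summaries.tsv", sep="\t", index=False)

    sidecar = {
        "window": config.window, "threshold": config.threshold,
        "min_level_count": config.min_level_count,
        "b_permutations": config.b_permutations, "seed": config.seed,
        "gene_lists": {k: (v if v is None else list(v))
                       for k, v in gene_lists.items()},
        "traits": list(traits.columns),
    }
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)

    return {"combinations": combos, "adjusted_variation": adj_frame,
            "effects": effects, "traces": traces, "fits": fits,
            "nulls": nulls, "tails": tails}
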