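"""Ensemble GWAS–TWAS candidate-gene prioritization.

Inputs are externally produced association tables: SNP-level GWAS
p-values, gene-level TWAS p-values for two tissues (growing point "GP"
and leaf three "3L"), gene intervals, and precomputed LD blocks.  The
ensemble nominates candidates by percentile rank rather than adjusted
significance:

* top 0.1% of GWAS SNPs → their LD blocks → every gene overlapping a
  block (or spanning its border) is GWAS-nominated;
* p-values of the top 10% of GWAS SNPs are assigned to their nearest
  gene and combined with each tissue's TWAS p-value by Fisher's combined
  test (−2·(ln p₁ + ln p₂) ~ χ² with 4 df);
* the top 1% of genes of each TWAS and each Fisher result are nominated;
* confidence tiers follow the combination of nominations across tests
  and tissues.

Coordinates are 1-based inclusive (GFF3 convention); BED inputs are
converted on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FisherResult",
    "ConfidenceCall",
    "TIERS",
    "validate_snp_table",
    "validate_gene_table",
    "validate_block_table",
    "top_fraction",
    "assign_top_snps_to_genes",
    "fisher_combine",
    "genes_in_blocks",
    "classify_confidence",
    "overlap_counts",
    "rank_candidates",
    "synth_assoc",
    "read_gene_table",
    "read_block_table",
]

TIERS = ("twas_both_tissues", "fisher_or_twas_both_tissues", "gwas_plus_rna_one_tissue", "none")

TESTS = ("gwas", "twas_gp", "twas_3l", "fisher_gp", "fisher_3l")


# ---------------------------------------------------------------------------
# Table validation


def validate_snp_table(snps: pd.DataFrame) -> pd.DataFrame:
    required = {"snp_id", "chrom", "pos", "p"}
    if missing := required - set(snps.columns):
        raise ValueError(f"SNP table missing columns {sorted(missing)}")
    if snps["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_ids")
    if (snps["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    if ((snps["p"] <= 0) | (snps["p"] > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    return snps


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "chrom", "start", "end"}
    if missing := required - set(genes.columns):
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_ids")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene start must not exceed end")
    if (genes["start"] < 1).any():
        raise ValueError("coordinates must be 1-based (>= 1)")
    return genes


def validate_block_table(blocks: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "start", "end"}
    if missing := required - set(blocks.columns):
        raise ValueError(f"block table missing columns {sorted(missing)}")
    if (blocks["start"] > blocks["end"]).any():
        raise ValueError("block start must not exceed end")
    for chrom, grp in blocks.groupby("chrom"):
        srt = grp.sort_values("start")
        if (srt["start"].values[1:] <= srt["end"].values[:-1]).any():
            raise ValueError(f"overlapping LD blocks on {chrom}")
    return blocks


# ---------------------------------------------------------------------------
# Selection and assignment


def top_fraction(table: pd.DataFrame, fraction: float, id_col: str, p_col: str = "p") -> set[str]:
    """Ids of the ceil(fraction·n) smallest p-values; ties at the cutoff
    resolved by id order so the selection size is exactly k."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if len(table) == 0:
        raise ValueError("empty table")
    k = math.ceil(fraction * len(table))
    ordered = table.sort_values([p_col, id_col], kind="mergesort")
    return set(ordered[id_col].head(k))


def _gene_distance(pos: np.ndarray, start: int, end: int) -> np.ndarray:
    """Distance from positions to a 1-based inclusive interval (0 inside)."""
    return np.maximum.reduce([start - pos, pos - end, np.zeros_like(pos)])


def assign_top_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, top_frac: float = 0.10
) -> pd.Series:
    """Gene-level GWAS p-values: each top-fraction SNP goes to its nearest
    same-chromosome gene; a gene keeps the minimum p over its SNPs.

    Distance is 0 inside the gene body, else base pairs to the nearer
    boundary; equidistant ties go to the smaller start, then smaller
    gene_id.  Returns a Series indexed by gene_id.
    """
    validate_snp_table(snps)
    validate_gene_table(genes)
    chosen = top_fraction(snps, top_frac, id_col="snp_id")
    top = snps[snps["snp_id"].isin(chosen)]
    out: dict[str, float] = {}
    for chrom, snp_grp in top.groupby("chrom"):
        gene_grp = genes[genes["chrom"] == chrom]
        if len(gene_grp) == 0:
            logger.warning(
                "%d top SNPs on %s have no genes on that chromosome; excluded",
                len(snp_grp), chrom,
            )
            continue
        # deterministic tie-break order: (distance, start, gene_id)
        gsort = gene_grp.sort_values(["start", "gene_id"], kind="mergesort")
        starts = gsort["start"].to_numpy()
        ends = gsort["end"].to_numpy()
        ids = gsort["gene_id"].to_numpy()
        pos = snp_grp["pos"].to_numpy()
        dists = np.stack([_gene_distance(pos, s, e) for s, e in zip(starts, ends)])  # (genes, snps)
        nearest = np.argmin(dists, axis=0)  # first minimum = smallest start then id
        for gi, p in zip(nearest, snp_grp["p"].to_numpy()):
            gid = ids[gi]
            if gid not in out or p < out[gid]:
                out[gid] = float(p)
    return pd.Series(out, name="p_gwas", dtype=float).sort_index()


# ---------------------------------------------------------------------------
# Fisher's combined test


@dataclass
class FisherResult:
    gene_id: str
    p_gwas: float
    p_twas: float
    chi2: float
    df: int
    p_combined: float


def fisher_combine(p_gwas: float, p_twas: float, gene_id: str = "") -> FisherResult:
    """Fisher's combined probability of two independent p-values.

    chi² = −2(ln p₁ + ln p₂) on 4 df; for two tests the combined p has
    the closed form p₁p₂(1 − ln(p₁p₂)).
    """
    for p in (p_gwas, p_twas):
        if not (0 < p <= 1):
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    chi2 = -2.0 * (math.log(p_gwas) + math.log(p_twas))
    p_combined = float(stats.chi2.sf(chi2, df=4))
    return FisherResult(
        gene_id=gene_id, p_gwas=float(p_gwas), p_twas=float(p_twas),
        chi2=chi2, df=4, p_combined=p_combined,
    )


def fisher_combine_tables(gene_gwas_p: pd.Series, twas: pd.DataFrame) -> pd.DataFrame:
    """Combine gene-level GWAS p with a TWAS table (gene_id, p); genes
    present in both are kept."""
    twas_p = twas.set_index("gene_id")["p"]
    common = gene_gwas_p.index.intersection(twas_p.index)
    rows = [fisher_combine(gene_gwas_p[g], twas_p[g], gene_id=g) for g in common]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "p_gwas": [r.p_gwas for r in rows],
            "p_twas": [r.p_twas for r in rows],
            "chi2": [r.chi2 for r in rows],
            "p": [r.p_combined for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# LD-block gene extraction


def genes_in_blocks(
    top_snps: set[str],
    snps: pd.DataFrame,
    blocks: pd.DataFrame,
    genes: pd.DataFrame,
) -> set[str]:
    """Genes overlapping (≥1 bp, closed intervals) any LD block that
    contains a top SNP; a top SNP inside no block contributes a degenerate
    single-position block at its own coordinate."""
    validate_snp_table(snps)
    validate_gene_table(genes)
    validate_block_table(blocks)
    top = snps[snps["snp_id"].isin(top_snps)]
    # hit blocks per chromosome
    hit: dict[str, list[tuple[int, int]]] = {}
    for chrom, snp_grp in top.groupby("chrom"):
        blk = blocks[blocks["chrom"] == chrom]
        tree = IntervalTree()
        for s, e in zip(blk["start"], blk["end"]):
            tree.addi(int(s), int(e) + 1)  # half-open for the tree
        intervals = hit.setdefault(chrom, [])
        for pos in snp_grp["pos"]:
            containing = tree[int(pos)]
            if containing:
                iv = next(iter(containing))
                intervals.append((iv.begin, iv.end - 1))
            else:
                intervals.append((int(pos), int(pos)))
    out: set[str] = set()
    for chrom, intervals in hit.items():
        gene_grp = genes[genes["chrom"] == chrom]
        gtree = IntervalTree()
        for gid, s, e in zip(gene_grp["gene_id"], gene_grp["start"], gene_grp["end"]):
            gtree.addi(int(s), int(e) + 1, gid)
        for s, e in set(intervals):
            out.update(iv.data for iv in gtree.overlap(s, e + 1))
    return out


# ---------------------------------------------------------------------------
# Confidence tiers


@dataclass
class ConfidenceCall:
    gene_id: str
    flags: dict[str, bool]
    tier: str

    @property
    def high_confidence(self) -> bool:
        return self.tier != "none"


def classify_confidence(gene_id: str, flags: dict[str, bool]) -> ConfidenceCall:
    """Confidence tier of one gene from its per-test nominations.

    Priority order: GWAS plus RNA evidence (TWAS or Fisher) in at least
    one tissue; else RNA evidence in both tissues — labeled
    ``twas_both_tissues`` when only the TWAS tests drive it, otherwise
    ``fisher_or_twas_both_tissues``; else ``none``.
    """
    f = {t: bool(flags.get(t, False)) for t in TESTS}
    rna_gp = f["twas_gp"] or f["fisher_gp"]
    rna_3l = f["twas_3l"] or f["fisher_3l"]
    if f["gwas"] and (rna_gp or rna_3l):
        tier = "gwas_plus_rna_one_tissue"
    elif rna_gp and rna_3l:
        if f["twas_gp"] and f["twas_3l"] and not (f["fisher_gp"] or f["fisher_3l"]):
            tier = "twas_both_tissues"
        else:
            tier = "fisher_or_twas_both_tissues"
    else:
        tier = "none"
    return ConfidenceCall(gene_id=gene_id, flags=f, tier=tier)


def overlap_counts(named_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise intersection matrix plus the all-set intersection/union.

    Returns a square DataFrame of pairwise |A∩B| (diagonal |A|) with
    attrs ``k_way`` (size of the intersection of all sets) and ``union``.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 named sets")
    names = list(named_sets)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            mat.loc[a, b] = len(named_sets[a] & named_sets[b])
    inter = set.intersection(*named_sets.values())
    union = set.union(*named_sets.values())
    mat.attrs["k_way"] = len(inter)
    mat.attrs["union"] = len(union)
    return mat


# ---------------------------------------------------------------------------
# The full ensemble


def rank_candidates(
    snps: pd.DataFrame,
    twas_gp: pd.DataFrame,
    twas_3l: pd.DataFrame,
    genes: pd.DataFrame,
    blocks: pd.DataFrame,
    gwas_snp_frac: float = 0.001,
    nearest_gene_snp_frac: float = 0.10,
    gene_frac: float = 0.01,
) -> pd.DataFrame:
    """Run the whole candidate-gene ensemble; one row per nominated gene
    with per-test flags, the confidence tier, and Fisher combined p's."""
    gene_gwas_p = assign_top_snps_to_genes(snps, genes, top_frac=nearest_gene_snp_frac)
    fisher_gp = fisher_combine_tables(gene_gwas_p, twas_gp)
    fisher_3l = fisher_combine_tables(gene_gwas_p, twas_3l)
    nominations = {
        "gwas": genes_in_blocks(
            top_fraction(snps, gwas_snp_frac, id_col="snp_id"), snps, blocks, genes
        ),
        "twas_gp": top_fraction(twas_gp, gene_frac, id_col="gene_id"),
        "twas_3l": top_fraction(twas_3l, gene_frac, id_col="gene_id"),
        "fisher_gp": top_fraction(fisher_gp, gene_frac, id_col="gene_id")
        if len(fisher_gp)
        else set(),
        "fisher_3l": top_fraction(fisher_3l, gene_frac, id_col="gene_id")
        if len(fisher_3l)
        else set(),
    }
    fgp = fisher_gp.set_index("gene_id")["p"] if len(fisher_gp) else pd.Series(dtype=float)
    f3l = fisher_3l.set_index("gene_id")["p"] if len(fisher_3l) else pd.Series(dtype=float)
    all_genes = sorted(set.union(*nominations.values()))
    rows = []
    for g in all_genes:
        flags = {t: g in nominations[t] for t in TESTS}
        call = classify_confidence(g, flags)
        rows.append(
            {
                "gene_id": g,
                **{t: flags[t] for t in TESTS},
                "p_fisher_gp": fgp.get(g, np.nan),
                "p_fisher_3l": f3l.get(g, np.nan),
                "tier": call.tier,
                "high_confidence": call.high_confidence,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["snp_to_gene_collapse"] = "min_p"
    out.attrs["fractions"] = {
        "gwas_snp_frac": gwas_snp_frac,
        "nearest_gene_snp_frac": nearest_gene_snp_frac,
        "gene_frac": gene_frac,
    }
    return out


# ---------------------------------------------------------------------------
# Synthetic association data


def synth_assoc(
    n_snps: int = 10000,
    n_genes: int = 500,
    n_causal: int = 10,
    signal_strength: float = 8.0,
    tissue_correlation: float = 0.3,
    gwas_log_spread: float = 2.0,
    seed: int = 0,
    n_chroms: int = 2,
):
    """Synthetic GWAS/TWAS tables with planted causal genes.

    Genes tile ``n_chroms`` chromosomes (3 kb bodies every 10 kb); LD
    blocks tile with gaps (20 kb blocks, 5 kb gaps) so some genes fall
    outside every block.  Background p-values are Uniform(0, 1].  Each
    causal gene gets one SNP moved to its midpoint with
    p = 10^(−signal_strength·(1+gwas_log_spread·u)) — GWAS hits span a
    much wider −log₁₀ p range than TWAS hits, as in real studies — and
    TWAS p-values 10^(−signal_strength·(1+u)) in both tissues,
    rank-correlated across tissues through a Gaussian copula with the
    given correlation.  Deterministic given ``seed``.

    Returns (snps, twas_gp, twas_3l, genes, blocks, causal_gene_ids).
    """
    if n_causal > n_genes:
        raise ValueError("n_causal must not exceed n_genes")
    if not (0 <= tissue_correlation <= 1):
        raise ValueError("tissue_correlation must be in [0, 1]")
    if signal_strength <= 0:
        raise ValueError("signal_strength must be positive")
    if n_snps < max(10, 2 * n_causal):
        raise ValueError("too few SNPs for the requested layout")
    rng = np.random.default_rng(seed)

    gene_pitch, gene_len = 10_000, 3_000
    per_chrom = int(np.ceil(n_genes / n_chroms))
    gene_rows = []
    for i in range(n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        j = i % per_chrom
        start = 2_000 + j * gene_pitch
        gene_rows.append((f"gene{i:04d}", chrom, start, start + gene_len - 1, "+"))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    chrom_len = {c: int(g["end"].max()) + 5_000 for c, g in genes.groupby("chrom")}

    block_rows = []
    for chrom, L in chrom_len.items():
        pos = 1
        while pos < L:
            block_rows.append((chrom, pos, min(pos + 20_000 - 1, L)))
            pos += 25_000  # 5 kb gap between blocks
    blocks = pd.DataFrame(block_rows, columns=["chrom", "start", "end"])

    chroms = sorted(chrom_len)
    snp_chrom = rng.choice(chroms, size=n_snps)
    snp_pos = np.array([int(rng.integers(1, chrom_len[c] + 1)) for c in snp_chrom])
    snp_p = 1.0 - rng.random(n_snps)  # Uniform(0, 1]
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(n_snps)],
            "chrom": snp_chrom,
            "pos": snp_pos,
            "p": snp_p,
        }
    )

    causal_ids = sorted(rng.choice(genes["gene_id"].to_numpy(), size=n_causal, replace=False))
    causal = genes.set_index("gene_id").loc[causal_ids]

    def planted_p(u: np.ndarray, spread: float = 1.0) -> np.ndarray:
        return 10.0 ** (-signal_strength * (1.0 + spread * u))

    # move one background SNP into each causal gene body and plant its p
    moved = rng.choice(n_snps, size=n_causal, replace=False)
    for k, (gid, row) in enumerate(causal.iterrows()):
        mid = int((row["start"] + row["end"]) // 2)
        snps.loc[moved[k], ["chrom", "pos", "p"]] = [
            row["chrom"], mid,
            float(planted_p(rng.random(1), spread=gwas_log_spread)[0]),
        ]
    snps["pos"] = snps["pos"].astype(int)

    # TWAS tables: background uniform; causal genes get correlated signals
    def background(n):
        return 1.0 - rng.random(n)

    twas_gp_p = background(n_genes)
    twas_3l_p = background(n_genes)
    z1 = rng.standard_normal(n_causal)
    z2 = tissue_correlation * z1 + np.sqrt(1 - tissue_correlation**2) * rng.standard_normal(
        n_causal
    )
    u1, u2 = stats.norm.cdf(z1), stats.norm.cdf(z2)
    gene_index = {g: i for i, g in enumerate(genes["gene_id"])}
    for gid, a, b in zip(causal_ids, planted_p(u1), planted_p(u2)):
        twas_gp_p[gene_index[gid]] = a
        twas_3l_p[gene_index[gid]] = b
    twas_gp = pd.DataFrame({"gene_id": genes["gene_id"], "p": twas_gp_p})
    twas_3l = pd.DataFrame({"gene_id": genes["gene_id"], "p": twas_3l_p})
    return snps, twas_gp, twas_3l, genes, blocks, list(causal_ids)


# ---------------------------------------------------------------------------
# IO: gene annotations (GFF3/BED) and LD blocks (BED)


def read_gene_table(path) -> pd.DataFrame:
    """Read gene intervals from GFF3 (1-based inclusive, kept) or BED
    (0-based half-open, converted)."""
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID", attrs.get("gene_id", f"{f[0]}:{f[3]}-{f[4]}"))
                rows.append((gid, f[0], int(f[3]), int(f[4]), f[6]))
        genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    elif path.endswith(".bed"):
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        genes = pd.DataFrame(
            {
                "gene_id": bed[3] if bed.shape[1] > 3 else bed.index.map(lambda i: f"gene{i}"),
                "chrom": bed[0],
                "start": bed[1].astype(int) + 1,  # BED 0-based half-open -> 1-based inclusive
                "end": bed[2].astype(int),
                "strand": bed[5] if bed.shape[1] > 5 else "+",
            }
        )
    else:
        raise ValueError(f"unsupported gene annotation format: {path}")
    return validate_gene_table(genes)


def read_block_table(path) -> pd.DataFrame:
    """Read LD blocks from a BED-like file (0-based half-open, converted)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    blocks = pd.DataFrame(
        {"chrom": bed[0], "start": bed[1].astype(int) + 1, "end": bed[2].astype(int)}
    )
    return validate_block_table(blocks)
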