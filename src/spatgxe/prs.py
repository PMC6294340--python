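"""Polygenic risk score construction from GWAS summary statistics.

The score is the dosage-weighted sum of per-allele log-odds effects from an
independent GWAS, over a SNP set thinned for linkage disequilibrium by
greedy p-value clumping (r2 = 0.1 within 250 kb) followed by sliding-window
pruning (r2 = 0.8, 2 kb windows advanced by 2 kb). No p-value significance
threshold is applied. LD (r2) is the squared Pearson correlation of dosages
in the analysis sample itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_summary_stats",
    "read_vcf_dosages",
    "align_alleles",
    "clump",
    "prune",
    "score",
    "build_prs",
    "ScoreResult",
]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def read_summary_stats(path) -> pd.DataFrame:
    """GWAS summary statistics TSV with columns SNP, CHR, BP, A1, A2,
    BETA (or OR, converted via log), P. Returns the normalized frame with
    columns snp_id, chrom, pos, effect_allele, other_allele, beta, pvalue."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    cols = {c.upper(): c for c in df.columns}
    need = ["SNP", "CHR", "BP", "A1", "A2", "P"]
    missing = [c for c in need if c not in cols]
    if missing:
        raise ValueError(f"summary statistics missing column(s): {missing}")
    out = pd.DataFrame(
        {
            "snp_id": df[cols["SNP"]].astype(str),
            "chrom": df[cols["CHR"]].astype(str),
            "pos": df[cols["BP"]].astype(int),
            "effect_allele": df[cols["A1"]].astype(str).str.upper(),
            "other_allele": df[cols["A2"]].astype(str).str.upper(),
            "pvalue": df[cols["P"]].astype(float),
        }
    )
    if "BETA" in cols:
        out["beta"] = df[cols["BETA"]].astype(float)
    elif "OR" in cols:
        out["beta"] = np.log(df[cols["OR"]].astype(float))
    else:
        raise ValueError("summary statistics need a BETA or OR column")
    if (out["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    if ((out["pvalue"] <= 0) | (out["pvalue"] > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    return out


def read_vcf_dosages(path, samples: list[str] | None = None):
    """Dosage matrix (subjects x SNPs, DS FORMAT field) and SNP metadata
    from a VCF. Requires cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=samples)
    meta_rows, dosages = [], []
    for var in vcf:
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is None:
            logger.warning("variant %s has no DS field; skipped", var.ID)
            continue
        meta_rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "effect_allele": var.ALT[0].upper() if var.ALT else "N",
                "other_allele": var.REF.upper(),
            }
        )
        dosages.append(np.asarray(ds, dtype=float).reshape(-1))
    meta = pd.DataFrame(meta_rows)
    D = np.column_stack(dosages) if dosages else np.empty((len(vcf.samples), 0))
    if D.size and (D.min() < 0 or D.max() > 2):
        raise ValueError("dosages must lie in [0, 2]")
    return D, meta, list(vcf.samples)


def align_alleles(stats: pd.DataFrame, dosage_meta: pd.DataFrame) -> pd.DataFrame:
    """Match summary-stat SNPs to dosage SNPs and sign-correct the betas.

    Matching is on snp_id when available on both sides, else on chrom:pos.
    Betas are flipped where effect/other alleles are swapped relative to
    the dosage coding (dosage counts the effect_allele in dosage_meta);
    strand-ambiguous (A/T, C/G) SNPs are dropped, as are SNPs whose alleles
    match in neither orientation (counted in the log).
    """
    s = stats.copy()
    m = dosage_meta.copy().reset_index().rename(columns={"index": "dosage_col"})
    if "snp_id" in s.columns and s["snp_id"].notna().all():
        merged = m.merge(
            s[["snp_id", "effect_allele", "other_allele", "beta", "pvalue"]],
            on="snp_id", suffixes=("_dos", "_gwas"),
        )
    else:
        merged = m.merge(
            s[["chrom", "pos", "effect_allele", "other_allele", "beta", "pvalue"]],
            on=["chrom", "pos"], suffixes=("_dos", "_gwas"),
        )
    ea_d = merged["effect_allele_dos"].str.upper()
    oa_d = merged["other_allele_dos"].str.upper()
    ea_g = merged["effect_allele_gwas"].str.upper()
    oa_g = merged["other_allele_gwas"].str.upper()

    ambiguous = [
        (a, b) in _AMBIGUOUS for a, b in zip(ea_g, oa_g)
    ]
    same = (ea_d == ea_g) & (oa_d == oa_g)
    swapped = (ea_d == oa_g) & (oa_d == ea_g)
    keep = (same | swapped) & ~np.asarray(ambiguous)
    n_amb = int(np.sum(ambiguous))
    n_mis = int(np.sum(~(same | swapped) & ~np.asarray(ambiguous)))
    if n_amb:
        logger.info("dropped %d strand-ambiguous SNP(s)", n_amb)
    if n_mis:
        logger.info("dropped %d SNP(s) with allele mismatch", n_mis)
    out = merged.loc[keep].copy()
    out["beta"] = np.where(swapped[keep], -out["beta"], out["beta"])
    out = out.rename(
        columns={"effect_allele_dos": "effect_allele", "other_allele_dos": "other_allele"}
    )
    return out[
        ["dosage_col", "snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "pvalue"]
    ].sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _r2_matrix(D: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns; monomorphic
    columns yield NaN rows/cols."""
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(D, rowvar=False)
    return np.atleast_2d(c) ** 2


def clump(
    snps: pd.DataFrame,
    dosages: np.ndarray,
    r2_max: float = 0.1,
    dist: int = 250_000,
) -> pd.DataFrame:
    """Greedy p-value clumping.

    Repeatedly retain the remaining SNP with the smallest p-value (ties:
    lower chrom, then pos) as an index SNP, and remove every SNP on the
    same chromosome within ``dist`` bp whose dosage r2 with the index
    exceeds ``r2_max``.  The globally smallest-p SNP is always retained.
    Monomorphic SNPs (zero dosage variance, undefined r2) are excluded
    up front with a warning.
    """
    snps = snps.reset_index(drop=True)
    var = dosages[:, snps["dosage_col"].to_numpy()].var(axis=0)
    mono = var <= 0
    if mono.any():
        logger.warning("excluded %d monomorphic SNP(s) from clumping", int(mono.sum()))
    avail = snps.loc[~mono].copy()
    order = avail.sort_values(
        ["pvalue", "chrom", "pos"], kind="stable"
    ).index.tolist()
    removed: set[int] = set()
    kept: list[int] = []
    for idx in order:
        if idx in removed:
            continue
        kept.append(idx)
        row = avail.loc[idx]
        cand = avail[
            (avail["chrom"] == row["chrom"])
            & ((avail["pos"] - row["pos"]).abs() <= dist)
            & (~avail.index.isin(removed))
            & (avail.index != idx)
        ]
        if len(cand) == 0:
            continue
        x = dosages[:, int(row["dosage_col"])]
        for j in cand.index:
            y = dosages[:, int(cand.loc[j, "dosage_col"])]
            r = np.corrcoef(x, y)[0, 1]
            if r * r > r2_max:
                removed.add(j)
    return avail.loc[sorted(kept)].reset_index(drop=True)


def prune(
    snps: pd.DataFrame,
    dosages: np.ndarray,
    r2_max: float = 0.8,
    window: int = 2_000,
    step: int = 2_000,
) -> pd.DataFrame:
    """Sliding-window LD pruning.

    Windows of ``window`` bp advance by ``step`` bp along each chromosome.
    Within a window, while any remaining pair has dosage r2 above
    ``r2_max``, the pair with the largest r2 is found (ties: leftmost pair)
    and its larger-p member dropped (ties: larger position).
    """
    snps = snps.reset_index(drop=True)
    var = dosages[:, snps["dosage_col"].to_numpy()].var(axis=0)
    mono = var <= 0
    if mono.any():
        logger.warning("excluded %d monomorphic SNP(s) from pruning", int(mono.sum()))
    alive = set(snps.index[~mono])
    for chrom in snps["chrom"].unique():
        on_chr = snps[snps["chrom"] == chrom]
        if len(on_chr) == 0:
            continue
        lo, hi = int(on_chr["pos"].min()), int(on_chr["pos"].max())
        start = lo
        while start <= hi:
            in_win = [
                i for i in on_chr.index
                if i in alive and start <= snps.at[i, "pos"] < start + window
            ]
            while len(in_win) > 1:
                best = None
                for a_i in range(len(in_win)):
                    for b_i in range(a_i + 1, len(in_win)):
                        a, b = in_win[a_i], in_win[b_i]
                        x = dosages[:, int(snps.at[a, "dosage_col"])]
                        y = dosages[:, int(snps.at[b, "dosage_col"])]
                        r2 = np.corrcoef(x, y)[0, 1] ** 2
                        if r2 > r2_max and (best is None or r2 > best[0] + 1e-15):
                            best = (r2, a, b)
                if best is None:
                    break
                _, a, b = best
                pa, pb = snps.at[a, "pvalue"], snps.at[b, "pvalue"]
                if (pa, -snps.at[a, "pos"]) > (pb, -snps.at[b, "pos"]):
                    drop = a
                else:
                    drop = b
                alive.discard(drop)
                in_win.remove(drop)
            start += step
    return snps.loc[sorted(alive)].reset_index(drop=True)


@dataclass
class ScoreResult:
    scores: np.ndarray
    standardized: bool
    n_snps: int


def score(dosages: np.ndarray, snps: pd.DataFrame) -> ScoreResult:
    """Raw PRS = sum_k beta_k * dosage_k, then zero-centered and scaled to
    unit variance over the sample. Zero-variance raw scores (e.g. all
    betas 0) cannot be standardized: the raw scores are returned flagged."""
    cols = snps["dosage_col"].to_numpy(dtype=int)
    beta = snps["beta"].to_numpy(dtype=float)
    raw = dosages[:, cols] @ beta if len(cols) else np.zeros(dosages.shape[0])
    sd = raw.std()
    if sd <= 0:
        logger.warning("raw PRS has zero variance; returning unstandardized scores")
        return ScoreResult(raw, standardized=False, n_snps=len(cols))
    return ScoreResult((raw - raw.mean()) / sd, standardized=True, n_snps=len(cols))


def build_prs(
    stats: pd.DataFrame,
    dosages: np.ndarray,
    dosage_meta: pd.DataFrame,
    clump_r2: float = 0.1,
    clump_dist: int = 250_000,
    prune_r2: float = 0.8,
    prune_window: int = 2_000,
    prune_step: int = 2_000,
) -> tuple[ScoreResult, pd.DataFrame]:
    """Full pipeline: allele alignment, clumping, pruning, scoring."""
    aligned = align_alleles(stats, dosage_meta)
    clumped = clump(aligned, dosages, clump_r2, clump_dist)
    pruned = prune(clumped, dosages, prune_r2, prune_window, prune_step)
    return score(dosages, pruned), pruned
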