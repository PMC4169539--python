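"""Ancestry-informative marker selection by Rosenberg informativeness.

For a biallelic SNP with alt-allele frequency ``p_i`` in each of K
populations, the informativeness for assignment is

    I_n = sum over alleles j of [ -pbar_j ln pbar_j + sum_i (p_ij / K) ln p_ij ]

with natural logs, ``pbar_j`` the unweighted mean frequency of allele j over
the K populations, and the convention ``0 ln 0 = 0``. I_n is zero iff every
population shares the same frequency and is bounded above by ``ln K``.

The selection pipeline (:func:`rank_aims`) filters on mean minor-allele
frequency (the alt frequency is averaged across populations first, then
folded — so a marker private to one of 13 populations at frequency 0.5 has
mean MAF ~3.8% and survives a 1% filter that a 5% filter would reject),
scores by informativeness, sorts (ties broken lexicographically by snp id)
and finally thins for linkage disequilibrium at a squared-correlation
threshold, keeping the best-scoring SNP of each correlated set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fst import FreqTable, allele_frequencies
from .io import MISSING, GenotypeDataset


@dataclass
class MarkerRanking:
    """SNP ids ordered by non-increasing score."""

    snp_ids: list[str]
    scores: np.ndarray
    method: str
    tie_rule: str = "lexicographic snp_id"

    def __post_init__(self) -> None:
        if len(self.snp_ids) != self.scores.shape[0]:
            raise ValueError("one score per snp id required")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp ids must be unique")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def top(self, n: int) -> list[str]:
        return self.snp_ids[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_ids, "score": self.scores})


def _sorted_ranking(snp_ids: Sequence[str], scores: np.ndarray, method: str) -> MarkerRanking:
    # sort by descending score, ties by ascending snp_id
    order = np.lexsort((np.asarray(snp_ids, dtype=object), -scores))
    return MarkerRanking([snp_ids[i] for i in order], scores[order], method)


def mean_maf(ft: FreqTable) -> np.ndarray:
    """Mean minor-allele frequency per SNP across populations.

    The alt-allele frequency is averaged (unweighted) over populations first
    and folded to ``min(m, 1-m)`` afterwards, so consistently-labelled rare
    alleles are not inflated by per-population folding.
    """
    m = np.nanmean(ft.freq, axis=0)
    return np.minimum(m, 1.0 - m)


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def informativeness(ft: FreqTable) -> np.ndarray:
    """Rosenberg informativeness for assignment, per SNP (nats).

    SNPs with a masked frequency in any population get NaN with a warning.
    """
    p = ft.freq
    k = p.shape[0]
    masked = np.isnan(p).any(axis=0)
    if masked.any():
        warnings.warn(f"{int(masked.sum())} SNP(s) with undefined frequencies skipped")
    out = np.full(p.shape[1], np.nan)
    ok = ~masked
    total = np.zeros(int(ok.sum()))
    for q in (p[:, ok], 1.0 - p[:, ok]):  # both alleles of the biallelic SNP
        qbar = q.mean(axis=0)
        total += -_xlogx(qbar) + _xlogx(q).sum(axis=0) / k
    out[ok] = total
    return out


def genotype_r2(ds: GenotypeDataset, col_a: int, col_b: int) -> float:
    """Squared Pearson correlation of two dosage columns, pairwise-complete."""
    a = ds.dosages[:, col_a]
    b = ds.dosages[:, col_b]
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    af, bf = a[ok].astype(float), b[ok].astype(float)
    if af.std() == 0 or bf.std() == 0:
        return 0.0
    return float(np.corrcoef(af, bf)[0, 1] ** 2)


def _pairwise_complete_r2(y: np.ndarray, block: np.ndarray) -> np.ndarray:
    """r^2 of column ``y`` against each column of ``block`` over rows where
    both are called (NaN marks missing); undefined correlations give 0."""
    my = ~np.isnan(y)
    mb = ~np.isnan(block)
    both = mb & my[:, None]
    yz = np.where(my, y, 0.0)
    bz = np.where(mb, block, 0.0)
    n = both.sum(axis=0)
    sy = yz @ both
    syy = (yz**2) @ both
    sb = (bz * both).sum(axis=0)
    sbb = (bz**2 * both).sum(axis=0)
    sby = bz.T @ yz
    num = n * sby - sb * sy
    den = (n * sbb - sb**2) * (n * syy - sy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((n >= 2) & (den > 0), num**2 / np.where(den > 0, den, 1.0), 0.0)
    return r2


def ld_thin(
    ds: GenotypeDataset,
    ranking: MarkerRanking,
    r2_threshold: float = 0.8,
    window_bp: int = 1_000_000,
) -> MarkerRanking:
    """Greedy LD thinning of a ranking in score order.

    A SNP is kept unless its dosage r^2 (Pearson over pairwise-complete
    observations) with an already-kept SNP on the same chromosome within
    ``window_bp`` exceeds the threshold; the output keeps the original score
    order over survivors.
    """
    col = {r.snp_id: j for j, r in enumerate(ds.snps)}
    meta = {r.snp_id: (r.chromosome, r.position_bp) for r in ds.snps}
    d = ds.dosages.astype(float)
    d[ds.dosages == MISSING] = np.nan
    kept_ids: list[str] = []
    kept_scores: list[float] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}  # chrom -> [(pos, col)]
    for snp_id, score in zip(ranking.snp_ids, ranking.scores):
        chrom, pos = meta[snp_id]
        near = [kc for kpos, kc in by_chrom.get(chrom, ()) if abs(kpos - pos) <= window_bp]
        if near:
            r2 = _pairwise_complete_r2(d[:, col[snp_id]], d[:, near])
            if np.any(r2 > r2_threshold):
                continue
        kept_ids.append(snp_id)
        kept_scores.append(float(score))
        by_chrom.setdefault(chrom, []).append((pos, col[snp_id]))
    return MarkerRanking(kept_ids, np.asarray(kept_scores), ranking.method, ranking.tie_rule)


def rank_aims(
    reference: GenotypeDataset,
    maf_threshold: float = 0.01,
    r2_threshold: float = 0.8,
    window_bp: int = 1_000_000,
    thin_first: bool = False,
) -> MarkerRanking:
    """AIM pipeline: frequencies -> mean-MAF filter (strict >) ->
    informativeness -> descending sort -> LD thinning.

    ``thin_first=True`` thins an id-ordered list before scoring instead (the
    order of thinning and scoring is a free choice; keeping the best of each
    correlated set retains more information, hence the default).
    A harmonized reference (equal samples per population) is expected; a
    warning is raised otherwise.
    """
    sizes = {p: len(ix) for p, ix in reference.population_indices().items()}
    if len(set(sizes.values())) > 1:
        warnings.warn(f"unequal population sizes in reference may bias scores: {sizes}")
    ft = allele_frequencies(reference)
    keep = mean_maf(ft) > maf_threshold
    if not keep.any():
        raise ValueError("no SNP survives the mean-MAF filter")
    snp_ids = [s for s, k in zip(ft.snp_ids, keep) if k]
    sub = FreqTable(ft.populations, snp_ids, ft.freq[:, keep], ft.n_called[:, keep])
    if thin_first:
        flat = MarkerRanking(sorted(snp_ids), np.zeros(len(snp_ids)), "informativeness")
        thinned = ld_thin(reference, flat, r2_threshold, window_bp)
        idx = [snp_ids.index(s) for s in thinned.snp_ids]
        sub = FreqTable(ft.populations, thinned.snp_ids, sub.freq[:, idx], sub.n_called[:, idx])
        scores = informativeness(sub)
        return _sorted_ranking(sub.snp_ids, scores, "informativeness")
    scores = informativeness(sub)
    ranking = _sorted_ranking(snp_ids, scores, "informativeness")
    return ld_thin(reference, ranking, r2_threshold, window_bp)


def lopo_stability(
    reference: GenotypeDataset,
    maf_threshold: float = 0.01,
) -> pd.DataFrame:
    """Leave-one-population-out stability of informativeness scores.

    For each population, informativeness is recomputed without it over the
    same (full-panel mean-MAF-filtered) SNP universe, without re-thinning,
    and Spearman-correlated against the full-panel scores. Returns a frame
    with columns ``population``, ``rho`` and ``note`` (NaN rho with a note
    when the correlation is undefined, e.g. K=2 leaves one population).
    """
    ft = allele_frequencies(reference)
    if len(ft.populations) < 3:
        raise ValueError("need at least 3 populations")
    keep = mean_maf(ft) > maf_threshold
    snp_ids = [s for s, k in zip(ft.snp_ids, keep) if k]
    full = FreqTable(ft.populations, snp_ids, ft.freq[:, keep], ft.n_called[:, keep])
    base = informativeness(full)
    rows = []
    for i, pop in enumerate(ft.populations):
        others = [j for j in range(len(ft.populations)) if j != i]
        sub = FreqTable(
            [ft.populations[j] for j in others], snp_ids,
            full.freq[others], full.n_called[others],
        )
        scores = informativeness(sub)
        ok = ~np.isnan(base) & ~np.isnan(scores)
        if ok.sum() < 2 or np.ptp(scores[ok]) == 0 or np.ptp(base[ok]) == 0:
            rows.append({"population": pop, "rho": np.nan, "note": "correlation undefined"})
            continue
        rho = stats.spearmanr(base[ok], scores[ok])[0]
        rows.append({"population": pop, "rho": float(rho), "note": ""})
    return pd.DataFrame(rows)
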