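"""PCAIM selection: marker ranking by principal-component loading weights.

Each SNP's contribution to a component is its absolute loading, normalized
to the component's maximum so the strongest contributor gets weight 1. The
per-component weights are scaled by the component's importance (its
eigenvalue by default) and summed across the significant components to give
one score per SNP. Because the sign of an eigenvector is arbitrary and only
relative component importance matters, the resulting ranks are invariant to
loading-sign flips and to a common rescaling of all eigenvalues.

Top-ranked PCAIMs tend to arrive in tight physical clusters (strongly
differentiated regions contribute many correlated SNPs to the same
component); :func:`prune_clusters` collapses each cluster to its single
best-scoring SNP using a positional window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aims import MarkerRanking, _sorted_ranking
from .io import SnpRecord
from .pca import PCAResult


@dataclass
class PcaimConfig:
    n_pcs: int | None = None          # default: count of TW-significant PCs
    cluster_window_bp: int = 1_000_000
    use_abs_loading: bool = True
    pc_weight: str = "eigenvalue"     # or "variance-fraction" / "none"
    tw_alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.n_pcs is not None and self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if self.pc_weight not in ("eigenvalue", "variance-fraction", "none"):
            raise ValueError(f"unknown pc_weight {self.pc_weight!r}")


def pcaim_scores(
    pca: PCAResult,
    snp_ids: list[str],
    cfg: PcaimConfig | None = None,
) -> MarkerRanking:
    """Score every SNP by its summed, importance-weighted loading weights."""
    cfg = cfg or PcaimConfig()
    if len(snp_ids) != pca.loadings.shape[0]:
        raise ValueError("need one snp id per loading row")
    if cfg.n_pcs is not None:
        n_pcs = cfg.n_pcs
    else:
        n_pcs = max(1, pca.n_significant(cfg.tw_alpha))
    if n_pcs > pca.loadings.shape[1]:
        raise ValueError(f"only {pca.loadings.shape[1]} components available, {n_pcs} requested")
    load = pca.loadings[:, :n_pcs]
    contrib = np.abs(load) if cfg.use_abs_loading else load
    peak = contrib.max(axis=0)
    if np.any(peak <= 0):
        raise ValueError("degenerate all-zero loading column")
    weights = contrib / peak[None, :]
    if cfg.pc_weight == "eigenvalue":
        scale = pca.eigenvalues[:n_pcs]
    elif cfg.pc_weight == "variance-fraction":
        scale = pca.variance_fraction[:n_pcs]
    else:
        scale = np.ones(n_pcs)
    scores = weights @ scale
    return _sorted_ranking(snp_ids, scores, "pcaim")


def prune_clusters(
    ranking: MarkerRanking,
    snps: list[SnpRecord],
    window_bp: int = 1_000_000,
) -> MarkerRanking:
    """Greedy positional pruning: drop any SNP with a higher-scored kept SNP
    on the same chromosome within ``window_bp`` (each cluster keeps only its
    top SNP; equal scores fall back to the ranking's lexicographic order)."""
    meta = {r.snp_id: (r.chromosome, r.position_bp) for r in snps}
    kept_ids: list[str] = []
    kept_scores: list[float] = []
    by_chrom: dict[str, list[int]] = {}
    for snp_id, score in zip(ranking.snp_ids, ranking.scores):
        chrom, pos = meta[snp_id]
        if any(abs(pos - kpos) <= window_bp for kpos in by_chrom.get(chrom, ())):
            continue
        kept_ids.append(snp_id)
        kept_scores.append(float(score))
        by_chrom.setdefault(chrom, []).append(pos)
    return MarkerRanking(kept_ids, np.asarray(kept_scores), ranking.method, ranking.tie_rule)


def rank_pcaims(
    pca: PCAResult,
    snps: list[SnpRecord],
    cfg: PcaimConfig | None = None,
) -> tuple[MarkerRanking, MarkerRanking]:
    """Full PCAIM pipeline: loading scores, then cluster pruning.

    Returns ``(raw_ranking, pruned_ranking)``.
    """
    cfg = cfg or PcaimConfig()
    raw = pcaim_scores(pca, [r.snp_id for r in snps], cfg)
    return raw, prune_clusters(raw, snps, cfg.cluster_window_bp)
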