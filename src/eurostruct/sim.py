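"""Synthetic multi-population genotype cohorts.

This module generates the kind of data the rest of the package analyses: a
set of closely related populations on a geographic grid, differentiated by

* **Balding-Nichols drift** — frequency deviations are Beta draws around an
  ancestral frequency, parameterized so that ``Var(p) = F * p0 * (1 - p0)``;
  ``F`` therefore has a direct Fst interpretation: the Hudson pairwise Fst
  between populations *i* and *j* has model expectation ``(F_i + F_j) / 2``
  plus any shared-cline contribution. Differentiation can be hierarchical:
  *regions* share one locus-heterogeneous deviation per SNP (a two-component
  multiplier on the region F puts a small class of loci at selection-scale
  differentiation while keeping the genome-wide mean F exact), and each
  *population* drifts diffusely on top with a constant F. Same-region pairs
  drop the region terms from the pairwise expectation.
* **Geographic clines** — one or more linear allele-frequency gradients, each
  along a fixed compass bearing. Each axis carries a sparse heavy-tailed
  per-SNP susceptibility: a fraction ``cline_sparsity`` of SNPs are clinal
  with Exponential weights scaled so the susceptibility's mean square is 2
  regardless of sparsity. Genome-average pairwise differentiation from a
  cline is therefore ``(strength * separation_km/1000)^2 * 2 / (2 E[p(1-p)])``
  however the signal is spread, while the strongest clinal loci (the
  analogue of selected regions such as the lactase and pigmentation loci)
  approach fixation differences across the map — which is what makes small
  ancestry panels work in real data.
* **LD blocks** (optional) — within a block of consecutive SNPs, genotypes
  are copies of the block's first SNP with per-haplotype allele flips at rate
  ``f``, giving a known squared correlation of ``(1 - 2 f)^2`` between the
  first SNP and every other block member.

The default configuration (:func:`default_config`) mirrors a multi-country
European-origin GWAS cohort: 13 populations with sample sizes between 39 and
475, per-population ``F`` chosen so pairwise Fst spans ~0 to ~0.014 with one
strongly drifted northeastern outlier, a dominant NNW/SSE cline plus a weaker
orthogonal one, and a small northern population held out of marker selection
entirely.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import MISSING, GenotypeDataset, GeoPanel, SnpRecord

EARTH_RADIUS_KM = 6371.0

#: Frequencies are clipped to this band to avoid degenerate fixation.
FREQ_FLOOR, FREQ_CEIL = 0.005, 0.995

#: Two-component locus-multiplier model: fraction of loci in the strongly
#: differentiated outlier class and their scale (times Exp(1)); the bulk is
#: rescaled so the multiplier's mean is exactly 1. The synthetic genome is
#: ~50x smaller than the genotyping chip it emulates; the outlier class
#: preserves the absolute strength of the strongest ancestry-informative
#: loci (selection-scale frequency differences) rather than their relative
#: share of a real genome.
LOCUS_OUTLIER_FRACTION = 0.005
LOCUS_OUTLIER_SCALE = 130.0


def equirectangular_xy(geo: GeoPanel) -> np.ndarray:
    """Local planar km offsets (x east, y north) of each population from the
    panel centroid, by equirectangular projection (adequate at continental
    scale; distance distortion <1% across Europe)."""
    lat = np.radians(geo.table["latitude_deg"].to_numpy(float))
    lon = np.radians(geo.table["longitude_deg"].to_numpy(float))
    lat0, lon0 = lat.mean(), lon.mean()
    x = EARTH_RADIUS_KM * (lon - lon0) * math.cos(lat0)
    y = EARTH_RADIUS_KM * (lat - lat0)
    return np.column_stack([x, y])


@dataclass
class SimConfig:
    """Full description of one simulated cohort (all randomness from `seed`)."""

    populations: list[str]
    samples_per_pop: list[int]
    n_snps: int
    fst_per_pop: list[float]
    geo: GeoPanel
    #: (bearing_deg from north, frequency shift per 1000 km) per cline axis;
    #: each axis gets its own per-SNP susceptibility.
    cline_axes: list[tuple[float, float]] = field(default_factory=list)
    #: Fraction of SNPs susceptible to each cline axis; the Exponential
    #: weights of susceptible SNPs are scaled by 1/sqrt(sparsity) so the
    #: susceptibility mean square (hence the genome-average cline
    #: contribution to Fst) does not depend on this knob. 1.0 = every SNP.
    cline_sparsity: float = 0.03
    #: Per-SNP multiplier model for the Balding-Nichols F. "two-component"
    #: (default): a shared Exp(1) multiplier for the bulk of loci plus a rare
    #: strongly scaled outlier class (selection/low-recombination analogue),
    #: rescaled so the multiplier's mean is exactly 1 and genome-average
    #: differentiation is unchanged. "exponential": Exp(1) only. "none":
    #: constant F at every SNP (the textbook model).
    locus_f_model: str = "two-component"
    #: Optional hierarchical structure: region label per population. All
    #: populations of a region share one region-level frequency deviation per
    #: SNP (drawn with the region's F scaled by the locus multiplier), on top
    #: of which each population drifts independently with a constant F at
    #: every locus. Region deviations therefore carry the locus-concentrated
    #: (selection-scale) signal, population drift the diffuse genome-wide
    #: signal.
    region_per_pop: list[str] | None = None
    #: Region-level F keyed by region label; required with region_per_pop.
    fst_per_region: dict[str, float] | None = None
    ld_block_size: int = 1
    ld_flip_prob: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def __post_init__(self) -> None:
        k = self.n_populations
        if k < 2:
            raise ValueError("need at least 2 populations")
        if len(self.samples_per_pop) != k or len(self.fst_per_pop) != k:
            raise ValueError("samples_per_pop and fst_per_pop must match populations")
        if any(f <= 0 or f >= 1 for f in self.fst_per_pop):
            raise ValueError("Balding-Nichols F must lie in (0, 1)")
        if self.ld_block_size < 1 or self.n_snps % self.ld_block_size:
            raise ValueError("n_snps must be divisible by ld_block_size >= 1")
        if not 0 <= self.ld_flip_prob <= 0.5:
            raise ValueError("ld_flip_prob must be in [0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 < self.cline_sparsity <= 1:
            raise ValueError("cline_sparsity must be in (0, 1]")
        if self.locus_f_model not in ("two-component", "exponential", "none"):
            raise ValueError(f"unknown locus_f_model {self.locus_f_model!r}")
        missing_geo = set(self.populations) - set(self.geo.populations)
        if missing_geo:
            raise ValueError(f"geo panel lacks populations: {sorted(missing_geo)}")
        if self.region_per_pop is not None:
            if len(self.region_per_pop) != self.n_populations:
                raise ValueError("region_per_pop must give one region per population")
            if self.fst_per_region is None:
                raise ValueError("fst_per_region is required with region_per_pop")
            missing = set(self.region_per_pop) - set(self.fst_per_region)
            if missing:
                raise ValueError(f"fst_per_region lacks regions: {sorted(missing)}")
            if any(f < 0 or f >= 1 for f in self.fst_per_region.values()):
                raise ValueError("region F must lie in [0, 1)")

    @classmethod
    def with_cline_strength(cls, cline_strength: tuple[float, float] = (0.0, 0.0), **kw) -> "SimConfig":
        """Convenience: (latitudinal, longitudinal) gradients per 1000 km as
        two independent axes due north (0 deg) and due east (90 deg)."""
        axes = []
        c_lat, c_lon = cline_strength
        if c_lat:
            axes.append((0.0, c_lat))
        if c_lon:
            axes.append((90.0, c_lon))
        return cls(cline_axes=axes, **kw)


@dataclass
class FrequencyModel:
    """Per-SNP ancestral and per-population allele frequencies."""

    ancestral_freq: np.ndarray  # (n_snps,)
    pop_freq: np.ndarray        # (n_populations, n_snps)

    def __post_init__(self) -> None:
        if self.pop_freq.ndim != 2 or self.pop_freq.shape[1] != self.ancestral_freq.shape[0]:
            raise ValueError("pop_freq must be populations x SNPs")
        if self.pop_freq.min() < FREQ_FLOOR - 1e-12 or self.pop_freq.max() > FREQ_CEIL + 1e-12:
            raise ValueError("pop_freq outside the clipped band")


def simulate_frequencies(cfg: SimConfig) -> FrequencyModel:
    """Draw the ancestral and per-population frequency model for ``cfg``.

    Ancestral frequencies are Uniform(0.05, 0.95); population frequencies are
    Balding-Nichols Beta draws shifted by the configured cline axes and
    clipped to [0.005, 0.995]. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, 101])
    p0 = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    xy = equirectangular_xy(cfg.geo.subset(cfg.populations))
    if cfg.locus_f_model == "two-component":
        pi, big = LOCUS_OUTLIER_FRACTION, LOCUS_OUTLIER_SCALE
        bulk_scale = (1.0 - pi * big) / (1.0 - pi)  # keeps E[multiplier] = 1
        locus_mult = bulk_scale * rng.exponential(1.0, size=cfg.n_snps)
        outlier = rng.random(cfg.n_snps) < pi
        locus_mult[outlier] = big * rng.exponential(1.0, size=int(outlier.sum()))
    elif cfg.locus_f_model == "exponential":
        locus_mult = rng.exponential(1.0, size=cfg.n_snps)
    else:
        locus_mult = np.ones(cfg.n_snps)
    def beta_dev(f_vec: np.ndarray) -> np.ndarray:
        f_eff = np.clip(f_vec, 1e-9, 0.5)
        a = p0 * (1.0 - f_eff) / f_eff
        b = (1.0 - p0) * (1.0 - f_eff) / f_eff
        return rng.beta(a, b) - p0

    pop_freq = np.empty((cfg.n_populations, cfg.n_snps))
    if cfg.region_per_pop is not None:
        region_dev: dict[str, np.ndarray] = {}
        for region in dict.fromkeys(cfg.region_per_pop):
            f_reg = cfg.fst_per_region[region]
            region_dev[region] = (
                beta_dev(f_reg * locus_mult) if f_reg > 0 else np.zeros(cfg.n_snps)
            )
        ones = np.ones(cfg.n_snps)
        for i, f in enumerate(cfg.fst_per_pop):
            # population drift is diffuse: constant F at every locus
            pop_freq[i] = p0 + region_dev[cfg.region_per_pop[i]] + beta_dev(f * ones)
    else:
        for i, f in enumerate(cfg.fst_per_pop):
            pop_freq[i] = p0 + beta_dev(f * locus_mult)
    for bearing_deg, strength in cfg.cline_axes:
        theta = math.radians(bearing_deg)
        proj_km = xy[:, 1] * math.cos(theta) + xy[:, 0] * math.sin(theta)
        susceptibility = np.zeros(cfg.n_snps)
        clinal = rng.random(cfg.n_snps) < cfg.cline_sparsity
        susceptibility[clinal] = rng.exponential(
            1.0 / math.sqrt(cfg.cline_sparsity), size=int(clinal.sum())
        )
        pop_freq += np.outer(strength * proj_km / 1000.0, susceptibility)
    np.clip(pop_freq, FREQ_FLOOR, FREQ_CEIL, out=pop_freq)
    return FrequencyModel(ancestral_freq=p0, pop_freq=pop_freq)


def _default_snp_map(n_snps: int, spacing_bp: int = 30_000) -> list[SnpRecord]:
    # Synthetic map: ~220 SNPs per "chromosome", 30 kb spacing, A1=A, A2=G.
    per_chrom = max(1, math.ceil(n_snps / 22)) if n_snps > 22 else n_snps
    records = []
    for j in range(n_snps):
        chrom = str(j // per_chrom + 1)
        pos = (j % per_chrom) * spacing_bp + 1
        records.append(SnpRecord(f"snp{j:06d}", chrom, pos, allele_ref="G", allele_alt="A"))
    return records


def simulate_genotypes(fm: FrequencyModel, cfg: SimConfig) -> GenotypeDataset:
    """Draw diploid dosages for every sample from the frequency model.

    Within an LD block the two haplotypes of each sample are drawn once from
    the block's first SNP and copied to the other members with independent
    per-haplotype flips at ``cfg.ld_flip_prob``; missing calls are inserted
    uniformly at ``cfg.missing_rate``. Deterministic given ``cfg.seed``.
    """
    if fm.pop_freq.shape != (cfg.n_populations, cfg.n_snps):
        raise ValueError("frequency model inconsistent with config")
    rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, 202])
    n_total = sum(cfg.samples_per_pop)
    block = cfg.ld_block_size
    n_blocks = cfg.n_snps // block
    dosages = np.empty((n_total, cfg.n_snps), dtype=np.int8)
    row = 0
    for i, n_i in enumerate(cfg.samples_per_pop):
        p_first = fm.pop_freq[i, ::block]  # (n_blocks,)
        latent = rng.random((n_i, n_blocks, 2)) < p_first[None, :, None]
        if block == 1:
            geno = latent.sum(axis=2, dtype=np.int8)
        else:
            members = np.repeat(latent, block, axis=1)  # (n_i, n_snps, 2)
            flips = rng.random((n_i, cfg.n_snps, 2)) < cfg.ld_flip_prob
            first_mask = (np.arange(cfg.n_snps) % block == 0)[None, :, None]
            flips &= ~first_mask
            geno = (members ^ flips).sum(axis=2, dtype=np.int8)
        dosages[row:row + n_i] = geno
        row += n_i
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING
    sample_ids, populations = [], []
    for pop, n_i in zip(cfg.populations, cfg.samples_per_pop):
        sample_ids.extend(f"{pop}_{j:04d}" for j in range(n_i))
        populations.extend([pop] * n_i)
    return GenotypeDataset(dosages, sample_ids, _default_snp_map(cfg.n_snps), populations)


def simulate_dataset(cfg: SimConfig) -> GenotypeDataset:
    """``simulate_genotypes(simulate_frequencies(cfg), cfg)`` in one call."""
    return simulate_genotypes(simulate_frequencies(cfg), cfg)


def simulate_mixture_cohort(
    fm: FrequencyModel,
    cfg: SimConfig,
    components: Sequence[str],
    n_samples: int,
    weights: Sequence[float] | None = None,
    mode: str = "discrete",
    label: str = "COHORT",
    seed: int = 0,
) -> GenotypeDataset:
    """Simulate an admixed cohort from existing population frequency models.

    ``mode="discrete"``: each sample descends wholly from one component
    population chosen with the given weights (emigrant-community model).
    ``mode="admixed"``: two components only; each sample gets its own mixing
    weight w ~ Uniform(0,1) and draws genotypes from ``w*p_a + (1-w)*p_b``.
    """
    if n_samples < 1:
        raise ValueError("cohort must contain at least one sample")
    idx = [cfg.populations.index(p) for p in components]
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 303])
    if mode == "discrete":
        w = None if weights is None else np.asarray(weights, float) / np.sum(weights)
        origin = rng.choice(len(idx), size=n_samples, p=w)
        freqs = fm.pop_freq[np.asarray(idx)[origin]]
    elif mode == "admixed":
        if len(idx) != 2:
            raise ValueError("admixed mode mixes exactly two components")
        w = rng.random(n_samples)
        freqs = np.outer(w, fm.pop_freq[idx[0]]) + np.outer(1 - w, fm.pop_freq[idx[1]])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    dosages = (rng.random((n_samples, cfg.n_snps)) < freqs).astype(np.int8)
    dosages += rng.random((n_samples, cfg.n_snps)) < freqs
    sample_ids = [f"{label}_{j:04d}" for j in range(n_samples)]
    return GenotypeDataset(
        dosages, sample_ids, _default_snp_map(cfg.n_snps), [label] * n_samples
    )


def make_study_design(
    ds: GenotypeDataset,
    reference_size: int = 70,
    min_test: int = 10,
    held_out_pops: Sequence[str] = (),
    seed: int = 0,
) -> tuple[GenotypeDataset, GenotypeDataset, GenotypeDataset]:
    """Split a cohort into (reference, test, heldout) sets.

    The reference is a harmonized panel of exactly ``reference_size`` samples
    per population, drawn at random; populations with fewer samples are
    excluded from the reference entirely. Leftover samples of a retained
    population form the test set only when more than ``min_test`` remain.
    Populations listed in ``held_out_pops`` go wholly to the heldout set and
    are never in the reference or test sets. The three outputs are disjoint.
    """
    if reference_size < 1:
        raise ValueError("reference_size must be >= 1")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 404])
    held = set(held_out_pops)
    ref_rows: list[int] = []
    test_rows: list[int] = []
    heldout_rows: list[int] = []
    for pop, rows in ds.population_indices().items():
        if pop in held:
            heldout_rows.extend(rows.tolist())
            continue
        if len(rows) < reference_size:
            warnings.warn(
                f"population {pop} has {len(rows)} samples < reference_size "
                f"{reference_size}; excluded from reference and test sets"
            )
            continue
        chosen = rng.choice(rows, size=reference_size, replace=False)
        chosen_set = set(chosen.tolist())
        ref_rows.extend(sorted(chosen_set))
        leftovers = [r for r in rows.tolist() if r not in chosen_set]
        if len(leftovers) > min_test:
            test_rows.extend(leftovers)
    if not ref_rows:
        raise ValueError(f"no population has {reference_size} samples; cannot build a reference")
    return ds.take_samples(ref_rows), ds.take_samples(test_rows), ds.take_samples(heldout_rows)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: Geographic centres (deg) of the 13 simulated European-like populations.
EUROPE_GEO: dict[str, tuple[float, float]] = {
    "CZ": (49.8, 15.5),
    "DE": (51.0, 10.4),
    "ES": (40.2, -3.6),
    "FI": (64.0, 26.0),
    "FR": (46.6, 2.4),
    "GR": (39.0, 22.0),
    "NIT": (45.4, 11.0),
    "NL": (52.2, 5.3),
    "NO": (61.0, 9.0),
    "PL": (52.1, 19.4),
    "SIT": (40.9, 14.3),
    "SE": (62.0, 15.0),
    "UK": (54.0, -2.0),
}

#: Per-population cohort sizes of the emulated study (range 39-475; the small
#: northern population SE is the held-out "new population").
STUDY_SIZES: dict[str, int] = {
    "CZ": 72, "DE": 475, "ES": 186, "FI": 131, "FR": 293, "GR": 70,
    "NIT": 203, "NL": 348, "NO": 82, "PL": 175, "SIT": 75, "SE": 39, "UK": 213,
}

#: Hierarchical structure of the emulated cohort: regions share the
#: locus-concentrated (selection-scale) deviations, populations drift
#: diffusely on top. Pairwise Fst between populations i, j of different
#: regions has model expectation
#: (F_reg_i + F_reg_j + F_drift_i + F_drift_j)/2 + cline term, with the
#: region terms dropped for same-region pairs. Values are set so pairwise
#: Fst spans ~0-0.014: an indistinct core (CZ/DE/NL, and NIT/SIT, below the
#: 0.001 threshold), distinct neighbours around it, a Mediterranean tier,
#: and the strongly drifted northeastern outlier FI, whose excess
#: differentiation is genome-wide (bottleneck-like) rather than
#: locus-concentrated.
STUDY_REGIONS: dict[str, str] = {
    "CZ": "CORE", "DE": "CORE", "NL": "CORE",
    "FR": "WEST", "UK": "BRIT", "PL": "EAST",
    "FI": "SCAN", "NO": "SCAN", "SE": "SCAN",
    "ES": "IBER", "NIT": "ITAL", "SIT": "ITAL", "GR": "GREC",
}

STUDY_REGION_F: dict[str, float] = {
    "CORE": 0.00025, "WEST": 0.0018, "BRIT": 0.0018, "EAST": 0.0018,
    "SCAN": 0.0012, "IBER": 0.0022, "ITAL": 0.0015, "GREC": 0.0025,
}

#: Diffuse per-population drift F (constant across loci).
STUDY_F: dict[str, float] = {
    "CZ": 0.00015, "DE": 0.00015, "ES": 0.0006, "FI": 0.0090, "FR": 0.0003,
    "GR": 0.0008, "NIT": 0.0004, "NL": 0.00015, "NO": 0.0006, "PL": 0.0003,
    "SIT": 0.0006, "SE": 0.0006, "UK": 0.0003,
}

#: Dominant NNW/SSE cline plus a weaker orthogonal (roughly E-W) one.
STUDY_CLINES: list[tuple[float, float]] = [(-11.0, 0.012), (79.0, 0.008)]

HELD_OUT_POP = "SE"
OUTLIER_POP = "FI"


def default_config(
    n_snps: int = 12_000,
    seed: int = 0,
    size_scale: float = 1.0,
    missing_rate: float = 0.002,
    ld_block_size: int = 1,
    ld_flip_prob: float = 0.0,
) -> SimConfig:
    """The package's default study conditions (optionally size-scaled)."""
    pops = sorted(EUROPE_GEO)
    return SimConfig(
        populations=pops,
        samples_per_pop=[max(10, round(STUDY_SIZES[p] * size_scale)) for p in pops],
        n_snps=n_snps,
        fst_per_pop=[STUDY_F[p] for p in pops],
        geo=GeoPanel.from_dict(EUROPE_GEO),
        cline_axes=list(STUDY_CLINES),
        region_per_pop=[STUDY_REGIONS[p] for p in pops],
        fst_per_region=dict(STUDY_REGION_F),
        ld_block_size=ld_block_size,
        ld_flip_prob=ld_flip_prob,
        missing_rate=missing_rate,
        seed=seed,
    )
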