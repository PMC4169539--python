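"""End-to-end study pipeline with caching and a run manifest.

Stages (in dependency order): simulate -> design -> pca -> geo -> fst ->
aims -> lopo -> pcaims -> assign -> substructure. Each stage writes plain
TSV/JSON outputs under the run directory; a manifest records the config
hash, per-stage outputs, seeds and wall-clock. On resume, completed stages
(outputs present, config hash unchanged) are reloaded from disk and only the
first incomplete stage onwards is recomputed. All randomness derives from
the single root seed via named substreams.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import fst as fst_mod
from . import geo as geo_mod
from .aims import MarkerRanking, lopo_stability, mean_maf, rank_aims
from .fst import allele_frequencies, indistinct_groups, pairwise_fst
from .io import (
    GenotypeDataset,
    GeoPanel,
    read_genotypes,
    read_geo_panel,
    write_genotypes,
    write_geo_panel,
)
from .knn import accuracy_curve, knn_assign
from .pca import pca_with_tw
from .pcaim import PcaimConfig, rank_pcaims
from .sim import (
    HELD_OUT_POP,
    STUDY_CLINES,
    SimConfig,
    default_config,
    make_study_design,
    simulate_frequencies,
    simulate_genotypes,
    simulate_mixture_cohort,
)
from .substructure import kmeans_subclusters, nearest_population_profile, within_population_pca

__version__ = "0.1.0"

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "n_snps": 12_000,
    "size_scale": 1.0,
    "missing_rate": 0.002,
    "ld_block_size": 1,
    "ld_flip_prob": 0.0,
    "reference_size": 70,
    "min_test": 10,
    "held_out": [HELD_OUT_POP],
    "n_pcs": 10,
    "maf_threshold": 0.01,
    "r2_threshold": 0.8,
    "window_bp": 1_000_000,
    "n_perm": 1000,
    "marker_counts": [10, 25, 50, 100, 250, 500, 1000],
    "top_n": 25,
    "admixed_cohort": True,
    "admixed_n": 200,
    "substructure_pops": [],  # empty: skip per-population scans (admixed cohort still run)
    "populations": None,      # optional override: {name: {size, fst, lat, lon}}
}

STAGES = [
    "simulate", "design", "pca", "geo", "fst",
    "aims", "lopo", "pcaims", "assign", "substructure",
]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "version": self.version, "stages": self.stages},
            indent=2,
        )


def load_config(source: dict[str, Any] | str | Path | None) -> dict[str, Any]:
    cfg = dict(DEFAULT_CONFIG)
    if source is None:
        return cfg
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    unknown = set(user) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    return cfg


def _config_hash(cfg: dict[str, Any]) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _sim_config(cfg: dict[str, Any]) -> SimConfig:
    if cfg["populations"]:
        over = cfg["populations"]
        names = sorted(over)
        return SimConfig(
            populations=names,
            samples_per_pop=[int(over[p]["size"]) for p in names],
            n_snps=int(cfg["n_snps"]),
            fst_per_pop=[float(over[p]["fst"]) for p in names],
            geo=GeoPanel.from_dict({p: (over[p]["lat"], over[p]["lon"]) for p in names}),
            cline_axes=list(STUDY_CLINES),
            ld_block_size=int(cfg["ld_block_size"]),
            ld_flip_prob=float(cfg["ld_flip_prob"]),
            missing_rate=float(cfg["missing_rate"]),
            seed=int(cfg["seed"]),
        )
    return default_config(
        n_snps=int(cfg["n_snps"]),
        seed=int(cfg["seed"]),
        size_scale=float(cfg["size_scale"]),
        missing_rate=float(cfg["missing_rate"]),
        ld_block_size=int(cfg["ld_block_size"]),
        ld_flip_prob=float(cfg["ld_flip_prob"]),
    )


def _write_ranking_tsv(path: Path, ranking: MarkerRanking, ds: GenotypeDataset) -> None:
    meta = {r.snp_id: r for r in ds.snps}
    ft = allele_frequencies(ds)
    maf = dict(zip(ft.snp_ids, mean_maf(ft)))
    rows = [
        {
            "snp_id": s,
            "chromosome": meta[s].chromosome,
            "position_bp": meta[s].position_bp,
            "score": float(sc),
            "mean_maf": float(maf[s]),
        }
        for s, sc in zip(ranking.snp_ids, ranking.scores)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _read_ranking_tsv(path: Path, method: str) -> MarkerRanking:
    t = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    return MarkerRanking(t["snp_id"].tolist(), t["score"].to_numpy(float), method)


class PipelineError(RuntimeError):
    pass


def run_pipeline(
    config: dict[str, Any] | str | Path | None,
    outdir: str | Path,
    resume: bool = True,
) -> RunManifest:
    """Run (or resume) the full study workflow under ``outdir``."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    manifest_path = outdir / "manifest.json"
    manifest = RunManifest(config_hash=chash, seed=int(cfg["seed"]))
    prior: dict[str, Any] = {}
    if resume and manifest_path.exists():
        stored = json.loads(manifest_path.read_text())
        if stored.get("config_hash") == chash:
            prior = stored.get("stages", {})

    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    state: dict[str, Any] = {"cfg": cfg, "outdir": outdir}
    stage_fns: dict[str, tuple[Callable, Callable, Callable]] = {
        name: (globals()[f"_stage_{name}"], globals()[f"_outputs_{name}"], globals()[f"_load_{name}"])
        for name in STAGES
    }

    # first stage whose outputs are missing (or not recorded) must recompute;
    # everything after it recomputes too.
    first_dirty = len(STAGES)
    for i, name in enumerate(STAGES):
        outputs = [outdir / rel for rel in stage_fns[name][1](cfg)]
        if name not in prior or not all(p.exists() for p in outputs):
            first_dirty = i
            break

    for i, name in enumerate(STAGES):
        compute, outputs_fn, load = stage_fns[name]
        outputs = [str(Path(rel)) for rel in outputs_fn(cfg)]
        t0 = time.perf_counter()
        try:
            if i < first_dirty:
                load(state)
                seconds = prior[name].get("seconds")
            else:
                compute(state)
                seconds = round(time.perf_counter() - t0, 3)
        except Exception as e:  # noqa: BLE001 - name the failing stage
            raise PipelineError(f"stage {name!r} failed: {e}") from e
        manifest.stages[name] = {"outputs": outputs, "seconds": seconds, "cached": i < first_dirty}
        manifest_path.write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations. Each _stage_X(state) computes and writes outputs;
# _load_X(state) restores the in-memory artifacts from a previous run.
# ---------------------------------------------------------------------------

def _outputs_simulate(cfg):
    return ["cohort.bed", "cohort.bim", "cohort.fam", "cohort.panel.tsv", "geo.tsv"]


def _stage_simulate(state):
    cfg = state["cfg"]
    sim_cfg = _sim_config(cfg)
    fm = simulate_frequencies(sim_cfg)
    ds = simulate_genotypes(fm, sim_cfg)
    write_genotypes(ds, state["outdir"] / "cohort", format="plink1")
    write_geo_panel(state["outdir"] / "geo.tsv", sim_cfg.geo)
    state.update(sim_cfg=sim_cfg, fm=fm, cohort=ds, geo=sim_cfg.geo)


def _load_simulate(state):
    cfg = state["cfg"]
    sim_cfg = _sim_config(cfg)
    state.update(
        sim_cfg=sim_cfg,
        fm=simulate_frequencies(sim_cfg),  # frequencies are cheap and seed-determined
        cohort=read_genotypes(state["outdir"] / "cohort", "plink1"),
        geo=read_geo_panel(state["outdir"] / "geo.tsv"),
    )


def _outputs_design(cfg):
    out = []
    for part in ("reference", "test", "heldout"):
        out += [f"{part}.bed", f"{part}.bim", f"{part}.fam", f"{part}.panel.tsv"]
    return out


def _stage_design(state):
    cfg = state["cfg"]
    ref, test, heldout = make_study_design(
        state["cohort"],
        reference_size=int(cfg["reference_size"]),
        min_test=int(cfg["min_test"]),
        held_out_pops=cfg["held_out"],
        seed=int(cfg["seed"]),
    )
    for part, ds in (("reference", ref), ("test", test), ("heldout", heldout)):
        write_genotypes(ds, state["outdir"] / part, format="plink1")
    state.update(reference=ref, test=test, heldout=heldout)


def _load_design(state):
    for part in ("reference", "test", "heldout"):
        state[part] = read_genotypes(state["outdir"] / part, "plink1")


def _outputs_pca(cfg):
    return ["pca_scores.tsv", "pca_eigen.tsv"]


def _stage_pca(state):
    cfg = state["cfg"]
    res = pca_with_tw(state["cohort"], n_pcs=int(cfg["n_pcs"]))
    scores = pd.DataFrame(
        res.scores, index=pd.Index(state["cohort"].sample_ids, name="sample_id"),
        columns=[f"PC{k+1}" for k in range(res.n_pcs)],
    )
    scores.insert(0, "population", state["cohort"].populations)
    scores.to_csv(state["outdir"] / "pca_scores.tsv", sep="\t", float_format="%.8g")
    pd.DataFrame(
        {
            "component": np.arange(1, res.n_pcs + 1),
            "eigenvalue": res.eigenvalues,
            "variance_fraction": res.variance_fraction,
            "tw_statistic": res.tw_stats,
            "tw_pvalue": res.tw_pvalues,
        }
    ).to_csv(state["outdir"] / "pca_eigen.tsv", sep="\t", index=False, float_format="%.8g")
    state["cohort_pca"] = res


def _load_pca(state):
    cfg = state["cfg"]
    state["cohort_pca"] = pca_with_tw(state["cohort"], n_pcs=int(cfg["n_pcs"]))


def _outputs_geo(cfg):
    return ["concordance.json"]


def _stage_geo(state):
    cfg = state["cfg"]
    res = state["cohort_pca"]
    cent = geo_mod.population_centroids(res, state["cohort"].populations, state["geo"], m=2)
    rep = geo_mod.concordance_report(cent, state["geo"], n_perm=int(cfg["n_perm"]), seed=int(cfg["seed"]))
    payload = {
        "spearman": {f"PC{k+1}:{axis}": [r, p] for (k, axis), (r, p) in rep.spearman.items()},
        "best_angle_deg": rep.best_angle_deg,
        "best_angle_rho": rep.best_angle_rho,
        "mantel_r": rep.mantel_r,
        "mantel_p": rep.mantel_p,
        "procrustes_t": rep.procrustes_t,
        "procrustes_p": rep.procrustes_p,
        "n_permutations": rep.n_permutations,
    }
    (state["outdir"] / "concordance.json").write_text(json.dumps(payload, indent=2))
    state["concordance"] = payload


def _load_geo(state):
    state["concordance"] = json.loads((state["outdir"] / "concordance.json").read_text())


def _outputs_fst(cfg):
    return ["fst_matrix.tsv", "fst_full.tsv", "fst_pairs.json"]


def _stage_fst(state):
    cfg = state["cfg"]
    cohort = state["cohort"]
    # large populations only, as in the printed matrix (small cohorts give
    # noisy Fst); all their cohort samples are used
    big = [p for p, ix in cohort.population_indices().items() if len(ix) >= int(cfg["reference_size"])]
    rows = np.concatenate([cohort.population_indices()[p] for p in big])
    fm = pairwise_fst(allele_frequencies(cohort.take_samples(rows)))
    fm.to_lower_triangle_frame().to_csv(state["outdir"] / "fst_matrix.tsv", sep="\t", na_rep="")
    pd.DataFrame(fm.fst, index=fm.populations, columns=fm.populations).to_csv(
        state["outdir"] / "fst_full.tsv", sep="\t", float_format="%.10g"
    )
    pairs, closure = indistinct_groups(fm)
    r2, mr, mp = fst_mod.fst_vs_distance(fm, state["geo"], n_perm=int(cfg["n_perm"]), seed=int(cfg["seed"]))
    payload = {
        "indistinct_pairs": sorted(sorted(p) for p in pairs),
        "closure": [sorted(c) for c in closure],
        "fst_vs_km": {"r_squared": r2, "mantel_r": mr, "mantel_p": mp},
    }
    (state["outdir"] / "fst_pairs.json").write_text(json.dumps(payload, indent=2))
    state.update(fst_matrix=fm, indistinct_pairs=pairs, fst_payload=payload)


def _load_fst(state):
    t = pd.read_csv(state["outdir"] / "fst_full.tsv", sep="\t", index_col=0)
    fm = fst_mod.FstMatrix(list(t.columns), t.to_numpy(float))
    payload = json.loads((state["outdir"] / "fst_pairs.json").read_text())
    pairs = {frozenset(p) for p in payload["indistinct_pairs"]}
    state.update(fst_matrix=fm, indistinct_pairs=pairs, fst_payload=payload)


def _outputs_aims(cfg):
    return ["aims.tsv"]


def _stage_aims(state):
    cfg = state["cfg"]
    ranking = rank_aims(
        state["reference"],
        maf_threshold=float(cfg["maf_threshold"]),
        r2_threshold=float(cfg["r2_threshold"]),
        window_bp=int(cfg["window_bp"]),
    )
    _write_ranking_tsv(state["outdir"] / "aims.tsv", ranking, state["reference"])
    state["aims"] = ranking


def _load_aims(state):
    state["aims"] = _read_ranking_tsv(state["outdir"] / "aims.tsv", "informativeness")


def _outputs_lopo(cfg):
    return ["lopo.tsv"]


def _stage_lopo(state):
    cfg = state["cfg"]
    t = lopo_stability(state["reference"], maf_threshold=float(cfg["maf_threshold"]))
    t.to_csv(state["outdir"] / "lopo.tsv", sep="\t", index=False, float_format="%.6g")
    state["lopo"] = t


def _load_lopo(state):
    state["lopo"] = pd.read_csv(state["outdir"] / "lopo.tsv", sep="\t")


def _outputs_pcaims(cfg):
    return ["pcaims.tsv", "pcaims_pruned.tsv", "reference_pca_eigen.tsv"]


def _stage_pcaims(state):
    cfg = state["cfg"]
    ref = state["reference"]
    res = pca_with_tw(ref, n_pcs=int(cfg["n_pcs"]))
    pd.DataFrame(
        {
            "component": np.arange(1, res.n_pcs + 1),
            "eigenvalue": res.eigenvalues,
            "variance_fraction": res.variance_fraction,
            "tw_statistic": res.tw_stats,
            "tw_pvalue": res.tw_pvalues,
        }
    ).to_csv(state["outdir"] / "reference_pca_eigen.tsv", sep="\t", index=False, float_format="%.8g")
    raw, pruned = rank_pcaims(res, ref.snps, PcaimConfig(cluster_window_bp=int(cfg["window_bp"])))
    _write_ranking_tsv(state["outdir"] / "pcaims.tsv", raw, ref)
    _write_ranking_tsv(state["outdir"] / "pcaims_pruned.tsv", pruned, ref)
    state.update(reference_pca=res, pcaims_raw=raw, pcaims=pruned)


def _load_pcaims(state):
    state["pcaims_raw"] = _read_ranking_tsv(state["outdir"] / "pcaims.tsv", "pcaim")
    state["pcaims"] = _read_ranking_tsv(state["outdir"] / "pcaims_pruned.tsv", "pcaim")


def _outputs_assign(cfg):
    return ["curve_aims.tsv", "curve_pcaims.tsv", "heldout_profile.tsv"]


def _stage_assign(state):
    cfg = state["cfg"]
    pairs = state["indistinct_pairs"]
    test, heldout = state["test"], state["heldout"]
    top_n = int(cfg["top_n"])
    for label, ranking in (("aims", state["aims"]), ("pcaims", state["pcaims"])):
        counts = [c for c in cfg["marker_counts"] if c <= len(ranking)]
        curve = accuracy_curve(
            state["reference"], test, ranking, marker_counts=counts,
            indistinct_pairs=pairs,
        )
        curve.to_csv(state["outdir"] / f"curve_{label}.tsv", sep="\t", index=False, float_format="%.6g")
        state[f"curve_{label}"] = curve
    profiles = []
    if heldout.n_samples:
        for label, ranking in (("aims", state["aims"]), ("pcaims", state["pcaims"])):
            rep = knn_assign(state["reference"], heldout, ranking.top(top_n))
            frac = rep.samples["predicted"].value_counts(normalize=True)
            for pop, f in frac.items():
                profiles.append({"marker_set": label, "assigned_to": pop, "fraction": float(f)})
    t = pd.DataFrame(profiles, columns=["marker_set", "assigned_to", "fraction"])
    t.to_csv(state["outdir"] / "heldout_profile.tsv", sep="\t", index=False, float_format="%.6g")
    state["heldout_profile"] = t


def _load_assign(state):
    for label in ("aims", "pcaims"):
        state[f"curve_{label}"] = pd.read_csv(state["outdir"] / f"curve_{label}.tsv", sep="\t")
    state["heldout_profile"] = pd.read_csv(state["outdir"] / "heldout_profile.tsv", sep="\t")


def _outputs_substructure(cfg):
    return ["substructure.json"]


def _stage_substructure(state):
    cfg = state["cfg"]
    payload: dict[str, Any] = {"populations": {}, "admixed": None}
    for pop in cfg["substructure_pops"]:
        res = within_population_pca(state["cohort"], pop)
        rep = kmeans_subclusters(res, pop, seed=int(cfg["seed"]))
        payload["populations"][pop] = {
            "chosen_k": rep.chosen_k,
            "silhouette": None if np.isnan(rep.silhouette) else rep.silhouette,
            "cluster_sizes": rep.cluster_sizes,
            "tw_p_pc1": float(res.tw_pvalues[0]),
        }
    if cfg["admixed_cohort"]:
        sim_cfg, fm = state["sim_cfg"], state["fm"]
        cohort = simulate_mixture_cohort(
            fm, sim_cfg,
            components=["DE", "NL", "UK", "NIT", "ES", "FI"] if "DE" in sim_cfg.populations
            else sim_cfg.populations[:2],
            n_samples=int(cfg["admixed_n"]),
            weights=[0.30, 0.22, 0.22, 0.13, 0.12, 0.01] if "DE" in sim_cfg.populations else None,
            mode="discrete",
            label="EMIGRANT",
            seed=int(cfg["seed"]),
        )
        profile = nearest_population_profile(state["reference"], cohort)
        payload["admixed"] = {pop: float(f) for pop, f in profile.items()}
    (state["outdir"] / "substructure.json").write_text(json.dumps(payload, indent=2))
    state["substructure"] = payload


def _load_substructure(state):
    state["substructure"] = json.loads((state["outdir"] / "substructure.json").read_text())
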