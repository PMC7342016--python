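"""End-to-end orchestration: simulate -> time-frequency -> decode -> stats -> RSA.

A run is fully described by a :class:`RunConfig` (serializable to JSON) and
reproducible from config + seed alone.  Artifacts (group accuracy maps,
cluster masks, RDMs, summary tables) are written to an output directory with
a manifest of SHA-256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .decoding import (
    DecodingConfig,
    broadband_timegen,
    cross_task_timegen,
    electrode_subset,
    within_task_cv,
)
from .rsa import RDM, compare_rdms, model_rdm, neural_rdm_from_cluster
from .simulate import SimConfig, generate_cohort
from .stats import cluster_correct, fdr_correct, sign_permutation_p
from .timefreq import DEFAULT_BANDS, assign_bands, decompose, log_spaced_grid


@dataclass
class StatsConfig:
    n_perm: int = 10_000
    cluster_def_p: float = 0.05
    cluster_p: float = 0.05
    bonferroni_factor: int = 3
    tail: str = "right"


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    sim: SimConfig = field(default_factory=SimConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    variants: tuple[str, ...] = ("bands",)
    model_manifest: str | None = None
    geometry_stage: str | None = None
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw["sim"] = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in raw.get("sim", {}).items()})
        raw["decoding"] = DecodingConfig(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in raw.get("decoding", {}).items()})
        raw["stats"] = StatsConfig(**raw.get("stats", {}))
        raw["bands"] = {k: tuple(v) for k, v in raw.get("bands", {}).items()}
        raw["variants"] = tuple(raw.get("variants", ("bands",)))
        return cls(**raw)

    @classmethod
    def demo(cls, n_participants: int = 10, seed: int = 0) -> "RunConfig":
        """Desk-scale configuration used by the worked example and tests."""
        sim = SimConfig(
            n_participants=n_participants,
            trials_per_object_per_task=16,
            sampling_rate=250.0,
            seed=seed,
        )
        dec = DecodingConfig(
            n_repeats=20, perception_stride=2, imagery_stride=3, seed=seed
        )
        st = StatsConfig(n_perm=1_000)
        return cls(sim=sim, decoding=dec, stats=st, seed=seed)


def _group_stats(maps: np.ndarray, cfg: StatsConfig, rng, bonferroni: int):
    perm = sign_permutation_p(
        maps, n_perm=cfg.n_perm, tail=cfg.tail, chance_level=50.0, rng=rng
    )
    clusters = cluster_correct(
        perm,
        cluster_def_p=cfg.cluster_def_p,
        cluster_p=cfg.cluster_p,
        bonferroni_factor=bonferroni,
    )
    return perm, clusters


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Execute the full analysis graph on a synthetic cohort.

    Returns a result bundle with, per frequency band, the group
    time-generalization map, sign-permutation p-map and cluster result, plus
    optional broadband / electrode-half / RSA results depending on
    ``config.variants``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    geometry_features = None
    manifest_sets = None
    if config.model_manifest is not None:
        from .rsa import load_feature_manifest

        manifest_sets = load_feature_manifest(config.model_manifest)
        if config.geometry_stage is not None:
            by_name = {s.stage_name: s for s in manifest_sets}
            geometry_features = by_name[config.geometry_stage].features

    cohort = generate_cohort(config.sim, model_features=geometry_features)
    grid = log_spaced_grid(5.0, 31.0, 20)
    bands = assign_bands(grid, config.bands)

    results: dict = {"bands": {}, "config": config}
    per_band_maps: dict[str, list] = {b.name: [] for b in bands}
    per_band_pairs: dict[str, list] = {b.name: [] for b in bands}
    variant_maps: dict[str, list] = {}

    for p_idx, (participant, _truth) in enumerate(cohort):
        tf_per = decompose(participant.perception, grid)
        tf_im = decompose(participant.imagery, grid)
        dec_cfg = dataclasses.replace(config.decoding, seed=config.seed * 10_000 + p_idx)
        for band in bands:
            tg = cross_task_timegen(tf_per, tf_im, band, dec_cfg)
            per_band_maps[band.name].append(tg.accuracy)
            per_band_pairs[band.name].append(tg.per_pair)
            if band.name == bands[0].name and p_idx == 0:
                results["perception_times"] = tg.perception_times
                results["imagery_times"] = tg.imagery_times
        if "electrode_halves" in config.variants:
            alpha = next(b for b in bands if b.name == "alpha")
            for half in ("anterior", "posterior"):
                tg = cross_task_timegen(
                    electrode_subset(tf_per, half),
                    electrode_subset(tf_im, half),
                    alpha,
                    dec_cfg,
                )
                variant_maps.setdefault(half, []).append(tg.accuracy)
        if "broadband" in config.variants:
            # broadband runs at the acquisition rate: scale the strides so the
            # decoded time grid matches the 50 Hz band analyses
            factor = max(1, int(round(config.sim.sampling_rate / 50.0)))
            bb_cfg = dataclasses.replace(
                dec_cfg,
                perception_stride=config.decoding.perception_stride * factor,
                imagery_stride=config.decoding.imagery_stride * factor,
            )
            tg = broadband_timegen(participant.perception, participant.imagery, bb_cfg)
            variant_maps.setdefault("broadband", []).append(tg.accuracy)
        if "within_task" in config.variants:
            alpha = next(b for b in bands if b.name == "alpha")
            for task, tf in (("perception", tf_per), ("imagery", tf_im)):
                tc = within_task_cv(tf, alpha, dec_cfg, task=task)
                variant_maps.setdefault(f"within_{task}", []).append(tc.accuracy)
        if "concatenate" in config.variants:
            # control variant: keep the alpha bins separate (e.g. 6 x 63
            # features) instead of averaging them
            alpha = next(b for b in bands if b.name == "alpha")
            cat_cfg = dataclasses.replace(dec_cfg, mode="concatenate")
            tg = cross_task_timegen(tf_per, tf_im, alpha, cat_cfg)
            variant_maps.setdefault("alpha_concatenate", []).append(tg.accuracy)
        if "individual_alpha" in config.variants:
            from .decoding import peak_alpha_band

            peak = peak_alpha_band(participant.perception, dec_cfg)
            tf_per_int = decompose(participant.perception, peak["grid"])
            tf_im_int = decompose(participant.imagery, peak["grid"])
            tg = cross_task_timegen(tf_per_int, tf_im_int, peak["band"], dec_cfg)
            variant_maps.setdefault("individual_alpha", []).append(tg.accuracy)
            results.setdefault("peak_alpha_freqs", []).append(peak["peak_freq"])
        if "alpha_split" in config.variants:
            from .decoding import alpha_power_split

            alpha = next(b for b in bands if b.name == "alpha")
            split_rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(1, p_idx))
            )
            enh, sup = alpha_power_split(tf_per, alpha, rng=split_rng)
            for name, idx in (("alpha_enhanced", enh), ("alpha_suppressed", sup)):
                tf_sub = dataclasses.replace(
                    tf_per,
                    power=tf_per.power[idx],
                    task=tf_per.task[idx],
                    object_id=tf_per.object_id[idx],
                )
                tg = cross_task_timegen(tf_sub, tf_im, alpha, dec_cfg)
                variant_maps.setdefault(name, []).append(tg.accuracy)

    n_bands = len(bands)
    for band in bands:
        maps = np.stack(per_band_maps[band.name])
        perm, clusters = _group_stats(maps, config.stats, rng, n_bands)
        results["bands"][band.name] = {
            "group_accuracy": maps.mean(axis=0),
            "participant_accuracy": maps,
            "p_map": perm.p_map,
            "clusters": clusters,
            "significant": bool(clusters.significant_mask.any()),
        }
    for name, maps_list in variant_maps.items():
        maps = np.stack(maps_list)
        bonf = 1
        perm, clusters = _group_stats(maps, config.stats, rng, bonf)
        results[name] = {
            "group_accuracy": maps.mean(axis=0),
            "p_map": perm.p_map,
            "clusters": clusters,
            "significant": bool(clusters.significant_mask.any()),
        }

    if manifest_sets is not None:
        alpha_res = results["bands"]["alpha"]
        mask = alpha_res["clusters"].significant_mask
        if mask.any():
            labels = [f"object_{k:02d}" for k in range(1, config.sim.n_objects + 1)]
            neural = [
                neural_rdm_from_cluster(pp, mask, labels)
                for pp in per_band_pairs["alpha"]
            ]
            rsa_rows = []
            for s in manifest_sets:
                m = model_rdm(s.features, labels)
                rs = compare_rdms(neural, m)
                perm = sign_permutation_p(
                    rs, n_perm=config.stats.n_perm, tail=config.stats.tail,
                    chance_level=0.0, rng=rng,
                )
                rsa_rows.append(
                    {"stage": s.stage_name, "family": s.model_family,
                     "mean_r": float(np.mean(rs)), "p": float(perm.p_map)}
                )
            for family in {r["family"] for r in rsa_rows}:
                fam = [r for r in rsa_rows if r["family"] == family]
                reject, adj = fdr_correct([r["p"] for r in fam])
                for r, rej, a in zip(fam, reject, adj):
                    r["significant_fdr"] = bool(rej)
                    r["p_fdr"] = float(a)
            results["rsa"] = rsa_rows

    if output_dir is not None:
        _write_artifacts(results, config, Path(output_dir))
    return results


def _write_artifacts(results: dict, config: RunConfig, out: Path) -> None:
    import h5py

    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    h5path = out / "results.h5"
    with h5py.File(h5path, "w") as f:
        for band, res in results["bands"].items():
            g = f.create_group(f"decoding/{band}")
            g.create_dataset("timegen", data=res["group_accuracy"])
            g.create_dataset("p_map", data=res["p_map"])
            g.create_dataset("significant_mask", data=res["clusters"].significant_mask)
        f.create_dataset("perception_times", data=results["perception_times"])
        f.create_dataset("imagery_times", data=results["imagery_times"])

    summary = {
        "seed": config.seed,
        "bands": {
            band: {
                "significant": res["significant"],
                "n_clusters": len(res["clusters"].clusters),
                "cluster_sizes": [s for _, s in res["clusters"].clusters],
                "cluster_p_values": res["clusters"].cluster_p_values,
                "size_threshold": res["clusters"].size_threshold,
            }
            for band, res in results["bands"].items()
        },
    }
    if "rsa" in results:
        summary["rsa"] = results["rsa"]
    (out / "summary.json").write_text(json.dumps(summary, indent=1))

    manifest = {}
    for p in sorted(out.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
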