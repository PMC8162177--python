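"""End-to-end orchestration: synthetic cohort -> models -> analyses.

The cohort design mirrors the study conditions: two cultures, each split
between raters of own-ethnicity and other-ethnicity faces (four conditions),
with a planted preference structure — a culture-level centroid that
transfers across face ethnicities, a condition-specific interactive
component, and individual idiosyncrasies — so every downstream analysis has
a recoverable ground truth.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import features, io, repspace, revcorr, validation
from .errors import InvalidConfigError
from .raters import ParticipantSpec, make_participant, random_preference, simulate_ratings
from .space import (
    GenerativeSpaceSpec,
    SpaceConfig,
    build_generative_space,
    cell_label,
    synthesize_stimuli,
)

log = logging.getLogger("prefcorr3d")

CONDITIONS = (("WE", "WE"), ("WE", "EA"), ("EA", "EA"), ("EA", "WE"))


def condition_label(culture: str, face_ethnicity: str) -> str:
    kind = "same" if culture == face_ethnicity else "other"
    return f"{culture}_{kind}"


@dataclass
class RunConfig:
    """Full configuration of a synthetic study run.

    Defaults reproduce the study conditions: 20 participants per condition
    (80 total), 1,950 shared random stimuli per participant, drive SNR 2.
    """

    space: SpaceConfig = field(default_factory=SpaceConfig)
    n_participants_per_condition: int = 20
    n_trials: int = 1950
    snr: float = 2.0
    centroid_scale: float = 1.0      # culture-level preference magnitude
    interactive_scale: float = 0.5   # condition-specific addition (other-ethnicity)
    idiosyncrasy_scale: float = 0.7  # individual spread around the condition centroid
    n_boot_decomposition: int = 20
    n_boot_cosine: int = 200
    n_perm: int = 200
    alpha: float = 0.05
    n_validation_per_condition: int = 2
    k_folds: int = 13
    run_validation: bool = True
    run_local_models: bool = False
    seed: int = 0
    out_dir: str = "prefcorr3d_run"

    def to_yaml(self, path: str | Path) -> Path:
        d = asdict(self)
        d["space"]["texture_shape"] = list(self.space.texture_shape)
        d["space"]["ethnicities"] = list(self.space.ethnicities)
        d["space"]["sexes"] = list(self.space.sexes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        sp = d.pop("space", {})
        for key in ("texture_shape", "ethnicities", "sexes"):
            if key in sp:
                sp[key] = tuple(sp[key])
        cfg = cls(space=SpaceConfig(**sp), **d)
        round_trip = yaml.safe_load(cfg.to_yaml_str())
        if round_trip != yaml.safe_load(Path(path).read_text()):
            log.debug("config round-trip differs (defaults filled in)")
        return cfg

    def to_yaml_str(self) -> str:
        d = asdict(self)
        d["space"]["texture_shape"] = list(self.space.texture_shape)
        d["space"]["ethnicities"] = list(self.space.ethnicities)
        d["space"]["sexes"] = list(self.space.sexes)
        return yaml.safe_dump(d, sort_keys=True)


def simulate_cohort(
    space: GenerativeSpaceSpec,
    config: RunConfig,
    seed: int,
) -> list[ParticipantSpec]:
    """Participants with planted culture/condition/individual preference layers."""
    rng = np.random.default_rng(seed)
    culture_pref = {
        cult: random_preference(space, rng, scale=config.centroid_scale)
        for cult in space.config.ethnicities
    }
    participants = []
    for culture, face_eth in CONDITIONS:
        ws, wc = culture_pref[culture]
        if culture != face_eth:
            iws, iwc = random_preference(space, rng, scale=config.interactive_scale)
            ws, wc = ws + iws, wc + iwc
        for i in range(config.n_participants_per_condition):
            dws, dwc = random_preference(space, rng, scale=config.idiosyncrasy_scale)
            pid = f"{condition_label(culture, face_eth)}_p{i:02d}"
            participants.append(make_participant(
                space, pid, culture, face_eth,
                ws + dws, wc + dwc, snr=config.snr,
                seed=int(rng.integers(0, 2**31 - 1)),
            ))
    return participants


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not serializable: {type(o)}")


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and emit a reproducible run directory.

    Stages: space bundle, shared stimuli, cohort simulation, per-participant
    model fits, group models and feature analyses, the attractiveness space
    with bootstrap variance decomposition and permutation thresholds,
    transfer/interactive classification, and (optionally) cross-validated
    rating prediction for a subset of participants.  A machine-readable
    ``summary.json`` collects the headline numbers; identical configs produce
    identical summaries.
    """
    if config.n_participants_per_condition < 1 or config.n_trials < 10:
        raise InvalidConfigError("cohort or trial count too small")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    root_ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1)) for name, s in zip(
        ["space", "stimuli", "cohort", "boot", "perm", "validation", "cosine"],
        root_ss.spawn(7))}
    summary: dict = {"seeds": seeds, "stages": {}}
    t0 = time.time()

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)
        summary["stages"][name] = {"t_start": round(time.time() - t0, 1)}

    stage("space")
    space = build_generative_space(config.space, seed=seeds["space"])
    io.write_space_bundle(space, out / "space")

    stage("stimuli")
    stimuli = synthesize_stimuli(space, config.n_trials, seed=seeds["stimuli"])
    io.write_trials(stimuli, out / "stimuli.csv")

    stage("cohort")
    participants = simulate_cohort(space, config, seeds["cohort"])
    trials_dir = out / "trials"
    trials_dir.mkdir(exist_ok=True)
    rated = {}
    for p in participants:
        rated[p.participant_id] = simulate_ratings(p, stimuli, space)
        io.write_trials(rated[p.participant_id], trials_dir / f"{p.participant_id}.csv")

    stage("fit")
    models_dir = out / "models"
    models = {}
    truth_cosines = []
    for p in participants:
        cond = condition_label(p.culture, p.face_ethnicity)
        m = revcorr.fit_preference_model(rated[p.participant_id], p.participant_id, cond)
        models[p.participant_id] = m
        io.write_model(m, models_dir / p.participant_id)
        w = np.concatenate([p.true_shape_pref, p.true_complexion_pref.ravel()])
        b = m.concat_beta2()
        truth_cosines.append(float(w @ b / (np.linalg.norm(w) * np.linalg.norm(b))))
    summary["recovery"] = {
        "n_models": len(models),
        "median_truth_cosine": float(np.median(truth_cosines)),
        "frac_cosine_ge_0.9": float(np.mean(np.asarray(truth_cosines) >= 0.9)),
    }

    stage("groups")
    by_cond: dict[str, list] = {}
    for m in models.values():
        by_cond.setdefault(m.condition, []).append(m)
    group_models = {cond: features.average_group_model(ms, cond)
                    for cond, ms in by_cond.items()}
    for cond, gm in group_models.items():
        io.write_model(gm, out / "group_models" / cond)

    stage("features")
    dimorphism = {eth: features.compute_dimorphism_direction(space, eth)
                  for eth in space.config.ethnicities}
    cosine_results = {}
    rng_cos = np.random.default_rng(seeds["cosine"])
    for cond, gm in group_models.items():
        face_eth = next(p.face_ethnicity for p in participants
                        if condition_label(p.culture, p.face_ethnicity) == cond)
        pid0 = by_cond[cond][0].participant_id
        res = {}
        for domain in ("shape", "complexion"):
            res[domain] = asdict(features.cosine_similarity_test(
                rated[pid0], by_cond[cond][0], dimorphism[face_eth],
                domain=domain, n_boot=config.n_boot_cosine,
                seed=int(rng_cos.integers(0, 2**31 - 1))))
        cosine_results[cond] = res
    summary["cosine_tests"] = {
        cond: {d: {k: res[d][k] for k in ("cosine", "ci_low", "ci_high", "significant")}
               for d in res} for cond, res in cosine_results.items()}

    zmaps = {}
    for cond, ms in by_cond.items():
        face_eth = next(p.face_ethnicity for p in participants
                        if condition_label(p.culture, p.face_ethnicity) == cond)
        zl = [rated[m.participant_id] for m in ms]
        zmaps[cond] = features.zscore_attractive_features(
            zl, space, cell_label(face_eth, "female"))
    summary["zscore"] = {
        cond: {"max_abs_vertex_z": float(np.nanmax(np.abs(z.vertex_z))),
               "attractive_set_size": z.attractive_set_size}
        for cond, z in zmaps.items()}

    stage("space_pca")
    model_list = list(models.values())
    boot_rng = np.random.default_rng(seeds["boot"])
    boot_models = []
    for m in model_list:
        boot_models.extend(repspace.bootstrap_models(
            rated[m.participant_id], config.n_boot_decomposition,
            seed=int(boot_rng.integers(0, 2**31 - 1)),
            participant_id=m.participant_id, condition=m.condition))
    decomposition = {}
    for domain in ("shape", "complexion"):
        att = repspace.build_attractiveness_space(model_list, space, domain=domain)
        att_boot = repspace.build_attractiveness_space(boot_models, space, domain=domain)
        groups = att_boot.group_labels
        parts = att_boot.participant_labels
        dec = repspace.decompose_variance(
            att_boot.scores, groups, parts, att_boot.var_explained)
        thr_g = repspace.permutation_thresholds(
            att_boot.scores, groups, parts, att_boot.var_explained,
            mode="group", n_perm=config.n_perm, alpha=config.alpha,
            seed=seeds["perm"])
        thr_p = repspace.permutation_thresholds(
            att_boot.scores, groups, parts, att_boot.var_explained,
            mode="participant", n_perm=config.n_perm, alpha=config.alpha,
            seed=seeds["perm"] + 1)
        decomposition[domain] = {
            "n_kept": att.n_kept,
            "var_explained_first3": float(att.var_explained[:3].sum()),
            "var_explained_kept": float(att.var_explained[:att.n_kept].sum()),
            "weighted_r2_group": dec.weighted_r2_group,
            "weighted_r2_participant": dec.weighted_r2_participant,
            "group_significant": thr_g.weighted_significant,
            "participant_significant": thr_p.weighted_significant,
            "group_threshold": thr_g.weighted_threshold,
            "participant_threshold": thr_p.weighted_threshold,
        }
    summary["decomposition"] = decomposition

    stage("transfer")
    transfer = {}
    pairs = {"WE_other": ("WE_same", "WE_other", "EA_same"),
             "EA_other": ("EA_same", "EA_other", "WE_same")}
    for name, (own_same, own_other, other_same) in pairs.items():
        if {own_same, own_other, other_same} <= set(group_models):
            tmap = repspace.classify_transfer_interactive(
                group_models[own_same], group_models[own_other],
                group_models[other_same], space)
            counts = {cls: int((tmap.vertex_class == i).sum())
                      for i, cls in enumerate(tmap.classes)}
            transfer[name] = counts
    summary["transfer_interactive"] = transfer

    if config.run_validation:
        stage("validation")
        val_rng = np.random.default_rng(seeds["validation"])
        results = []
        for cond, ms in sorted(by_cond.items()):
            face_eth = next(p.face_ethnicity for p in participants
                            if condition_label(p.culture, p.face_ethnicity) == cond)
            for m in ms[: config.n_validation_per_condition]:
                context = [mm for mm in model_list if mm.participant_id != m.participant_id]
                results.append(validation.crossval_predict(
                    rated[m.participant_id], context, space, dimorphism[face_eth],
                    k_folds=config.k_folds,
                    seed=int(val_rng.integers(0, 2**31 - 1)),
                    participant_id=m.participant_id, condition=cond))
        comparison = validation.compare_predictors(results)
        summary["validation"] = {
            "n_participants": len(results),
            "mean_tau": {fam: float(np.mean(v))
                         for fam, v in comparison.mean_taus.items()},
            "tests": comparison.tests,
        }

    # timing is logged, never written: the summary must be bit-identical
    # across reruns of the same config
    for st in summary["stages"].values():
        st.pop("t_start", None)
    (out / "summary.json").write_text(
        json.dumps(_round_floats(summary), indent=2, sort_keys=True, default=_json_default))
    log.info("pipeline complete in %.1fs -> %s", time.time() - t0, out)
    return out
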