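"""End-to-end pipeline: stimuli -> schedule -> simulate -> analyze.

Every stochastic stage takes an explicit seed from the config (never the
wall clock), every intermediate artifact is written to disk, and the run
manifest records a SHA-256 hash of each output so that reruns with the same
config can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import eye_image as ei
from . import glmm, observer_sim, schedule

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures", "plot_accuracy"]

log = logging.getLogger("gazepolarity")

_DESIGNS = ("study1-exp1", "study1-exp2", "study2")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one reproducible run; every seed is explicit."""

    design: str = "study1-exp1"
    observer_preset: str = "full-threeway"
    n_participants: int = 25
    alpha: float = 0.05
    bonferroni_k: int = 1
    seed_stimuli: int = 11
    seed_schedule: int = 12
    seed_simulation: int = 13
    seed_bootstrap: int = 14
    first_species: str = "chimpanzee"
    study2_level: float = 3.0
    study2_polarity: str = "normal"
    maximal_slopes: bool = False
    bootstrap_resamples: int = 2000
    out_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if self.design not in _DESIGNS:
            raise ValueError(f"design must be one of {_DESIGNS}")
        if self.observer_preset not in observer_sim.PRESETS:
            raise ValueError(f"unknown observer preset {self.observer_preset!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _render_stimuli(out: Path, seed: int) -> list[Path]:
    """Write the stimulus set: species x polarity x {L1, L4} plus masks."""
    written = []
    for species in ("chimpanzee", "human"):
        img, masks = ei.render_eye_stimulus(
            ei.default_geometry(species), ei.default_appearance(species)
        )
        for polarity in ("normal", "reversed"):
            base = img if polarity == "normal" else ei.reverse_polarity(img, masks.eyeball_mask)
            for level in (1.0, 4.0):
                lv = ei.apply_level(base, level)
                p = out / f"{species}_{polarity}_L{level:g}.png"
                lv.save(p)
                written.append(p)
        masks.save(out, species)
        written.extend(out / f"{species}_{m}.png" for m in ("iris", "sclera", "eyeball"))
    reports = {
        f"{sp}_{pol}": ei.measure_colorimetry(
            ei.reverse_polarity(img, masks.eyeball_mask) if pol == "reversed" else img,
            masks,
        )
        for sp in ("chimpanzee", "human")
        for img, masks in [
            ei.render_eye_stimulus(ei.default_geometry(sp), ei.default_appearance(sp))
        ]
        for pol in ("normal", "reversed")
    }
    rep_path = out / "colorimetry.csv"
    ei.reports_to_frame(reports).to_csv(rep_path)
    written.append(rep_path)
    return written


def _build_plan(cfg: PipelineConfig) -> schedule.Plan:
    if cfg.design == "study1-exp1":
        return schedule.build_study1_exp1(cfg.seed_schedule, cfg.first_species)
    if cfg.design == "study1-exp2":
        return schedule.build_study1_exp2(cfg.seed_schedule, cfg.first_species)
    return schedule.build_study2_session(
        cfg.seed_schedule,
        level=cfg.study2_level,
        polarity=cfg.study2_polarity,  # type: ignore[arg-type]
        first_species=cfg.first_species,  # type: ignore[arg-type]
    )


def _model_spec(cfg: PipelineConfig) -> glmm.ModelSpec:
    if cfg.design == "study1-exp1":
        return glmm.study1_exp1_spec(maximal_slopes=cfg.maximal_slopes)
    if cfg.design == "study1-exp2":
        return glmm.study1_exp2_spec(maximal_slopes=cfg.maximal_slopes)
    return glmm.study2_spec()


def _analyze(cfg: PipelineConfig, responses: pd.DataFrame, out: Path) -> dict:
    spec = _model_spec(cfg)
    alpha = cfg.alpha / max(cfg.bonferroni_k, 1)
    if cfg.design == "study2":
        # per-"participant" model: sessions are the random unit; here the
        # simulated participants stand in for repeated sessions
        responses = responses.copy()
        responses["session_id"] = responses["participant_id"]
        unit = "session_id"
    else:
        unit = "participant_id"
    results, needs_simple, final_spec = glmm.prune_and_test(responses, spec, alpha=alpha)
    report: dict = {
        "design": cfg.design,
        "alpha": alpha,
        "lrt": [
            {
                "term": r.term,
                "chi2": r.chi2,
                "df": r.df,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ],
        "needs_simple_effects": needs_simple,
    }
    fit = glmm.fit_glmm(responses, final_spec)
    report["fit"] = {
        "coefficients": fit.params.to_dict(),
        "se": fit.se.to_dict(),
        "sigma": fit.sigma,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "dispersion": glmm.dispersion(fit),
    }
    if needs_simple and cfg.design == "study1-exp2":
        strata = {"level": sorted(responses["level"].unique()), "polarity": ["normal", "reversed"]}
        simple = glmm.simple_effects(responses, spec, focal="species", within=strata, alpha=alpha)
        report["simple_effects"] = [
            {"stratum": combo, "chi2": r.chi2, "df": r.df, "p_value": r.p_value}
            for combo, r in simple
        ]
    # condition-wise proportions correct with bootstrap CIs
    group_cols = [c for c in ("species", "level", "polarity") if responses[c].nunique() > 1]
    cis = []
    for keys, sub in responses.groupby(group_cols):
        keys = keys if isinstance(keys, tuple) else (keys,)
        ci = glmm.bootstrap_ci(
            sub, unit_col=unit, n_resamples=cfg.bootstrap_resamples, seed=cfg.seed_bootstrap
        )
        cis.append(dict(zip(group_cols, keys)) | {
            "estimate": ci.estimate, "lower": ci.lower, "upper": ci.upper,
        })
    report["bootstrap_ci"] = cis
    ci_frame = pd.DataFrame(cis)
    ci_frame.to_csv(out / "condition_means.csv", index=False)
    plot_accuracy(ci_frame, out / "accuracy.png")
    (out / "analysis.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def plot_accuracy(ci_frame: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of condition-wise proportion correct with bootstrap CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = ci_frame.copy()
    label_cols = [c for c in frame.columns if c not in ("estimate", "lower", "upper")]
    labels = frame[label_cols].astype(str).agg("\n".join, axis=1)
    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(frame)), 3.2))
    x = np.arange(len(frame))
    err = np.vstack(
        [frame["estimate"] - frame["lower"], frame["upper"] - frame["estimate"]]
    )
    ax.bar(x, frame["estimate"], yerr=err, capsize=3, color="#777777")
    ax.axhline(1 / 3, ls=":", color="k", lw=0.8)  # 3-alternative chance
    ax.set_xticks(x, labels, fontsize=7)
    ax.set_ylim(0, 1)
    ax.set_ylabel("proportion correct")
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": "gazepolarity"})
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)

    log.info("stage=stimuli seed=%d", config.seed_stimuli)
    stim_dir = out / "stimuli"
    stim_dir.mkdir(exist_ok=True)
    artifacts = _render_stimuli(stim_dir, config.seed_stimuli)

    log.info("stage=schedule seed=%d design=%s", config.seed_schedule, config.design)
    plan = _build_plan(config)
    plan_path = out / "plan.csv"
    plan.to_csv(plan_path)
    artifacts.append(plan_path)

    log.info(
        "stage=simulate seed=%d preset=%s n=%d",
        config.seed_simulation, config.observer_preset, config.n_participants,
    )
    params = observer_sim.PRESETS[config.observer_preset]
    responses = observer_sim.simulate_responses(
        plan, params, config.n_participants, config.seed_simulation
    )
    resp_path = out / "responses.csv"
    responses.to_csv(resp_path, index=False)
    artifacts.append(resp_path)
    params.save(out / "observer_params.json")
    artifacts.append(out / "observer_params.json")

    log.info("stage=analyze alpha=%g k=%d", config.alpha, config.bonferroni_k)
    _analyze(config, responses, out)
    artifacts.extend([out / "analysis.json", out / "condition_means.csv", out / "accuracy.png"])

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_trials": len(plan),
        "n_responses": len(responses),
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("manifest written: %d artifacts", len(manifest["artifacts"]))
    return manifest


def make_fixtures(seed: int, out_dir: str | Path) -> dict:
    """Emit the small canned fixture set used by the test suite.

    Contains one stimulus per species x polarity x {L1, L4}, a keypress
    experiment plan, one search session plan, and a 2-participant response
    table — all regenerable bit-exactly from ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = _render_stimuli(out, seed)
    plan = schedule.build_study1_exp1(seed)
    plan.to_csv(out / "plan_study1_exp1.csv")
    session = schedule.build_study2_session(seed + 1, level=2.5)
    session.to_csv(out / "plan_study2_session.csv")
    responses = observer_sim.simulate_responses(
        plan, observer_sim.PRESETS["species-only"], n_participants=2, seed=seed + 2
    )
    responses.to_csv(out / "responses.csv", index=False)
    files.extend(
        out / n for n in ("plan_study1_exp1.csv", "plan_study2_session.csv", "responses.csv")
    )
    manifest = {
        "seed": seed,
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(files))},
    }
    (out / "fixture_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
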