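"""End-to-end orchestration: phantom → simulate → Fgas → V/Q → Ki → stats.

A pipeline run simulates a small cohort of subjects (each with its own
physiologic jitter and noise realization), analyses each subject exactly
as real data would be analysed, and compares the per-subject lobe means
across the three conditions with the rank-based statistics. Every output
embeds provenance (config hash, seed, package version).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .aeration import hu_to_fgas, lobe_relative_fgas
from .core import LOBE_ROLES
from .io import read_cell_counts, write_lobe_mask, write_report, write_volume
from .patlak import build_input_function, lobe_ki, lobe_ki_table
from .phantom import (
    PhantomSpec,
    TracerSimConfig,
    generate_phantom,
    simulate_fdg,
    simulate_nn13,
)
from .regional import anova_on_ranks, bal_concentrations, gravity_profile
from .washout import WashoutModel

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: Path = Path("pulmopet_out")
    seed: int = 0
    n_subjects: int = 6
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    noise: str = "gaussian"
    noise_level: float = 2.0
    apnea_window: tuple[float, float] = (0.0, 30.0)
    washout_window: tuple[float, float] | None = None
    smoothing_mm: float | None = 10.125
    signal_threshold: float = 0.05
    t_star_min: float = 10.0
    alpha: float = 0.05
    run_fdg: bool = True
    write_maps: bool = True
    cell_counts_csv: Path | None = None
    # inter-subject physiologic jitter (1 sd, relative)
    subject_sv_jitter: float = 0.10
    subject_q_mult_jitter: float = 0.05
    subject_sv_mult_jitter: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        phantom_kw = raw.pop("phantom", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if phantom_kw:
            cfg.phantom = PhantomSpec(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in phantom_kw.items()
            })
        cfg.out_dir = Path(cfg.out_dir)
        if cfg.washout_window is not None:
            cfg.washout_window = tuple(cfg.washout_window)
        cfg.apnea_window = tuple(cfg.apnea_window)
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("cell_counts_csv", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _subject_spec(
    base: PhantomSpec, cfg: PipelineConfig, rng: np.random.Generator
) -> PhantomSpec:
    """Per-subject physiology: jittered sV baseline and allergen multipliers."""
    sv = base.sv_base_per_min * float(
        np.clip(rng.normal(1.0, cfg.subject_sv_jitter), 0.6, 1.4)
    )
    qm = float(np.clip(rng.normal(base.allergen_q_multiplier, cfg.subject_q_mult_jitter), 0.3, 0.85))
    sm = float(
        np.clip(rng.normal(base.allergen_sv_multiplier, cfg.subject_sv_mult_jitter), 0.3, 0.85)
    )
    return dataclasses.replace(
        base, sv_base_per_min=sv, allergen_q_multiplier=qm, allergen_sv_multiplier=sm
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full simulated study; returns a report bundle of artifacts.

    Raises :class:`PipelineError` naming the failed stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    rng = np.random.default_rng(config.seed)
    per_subject_rows: list[dict[str, Any]] = []
    artifacts: dict[str, Any] = {"provenance": provenance}

    if config.cell_counts_csv is not None and not Path(config.cell_counts_csv).exists():
        raise PipelineError(f"stats: cell-count input not found: {config.cell_counts_csv}")

    for s in range(config.n_subjects):
        subj_seed = int(config.seed * 1009 + s) % (2**31 - 1)
        try:
            spec = _subject_spec(config.phantom, config, rng)
            hu, mask, truth = generate_phantom(spec, seed=subj_seed)
        except Exception as exc:
            raise PipelineError(f"phantom (subject {s}): {exc}") from exc

        sim_cfg = TracerSimConfig(noise=config.noise, noise_level=config.noise_level)
        try:
            nn_scan = simulate_nn13(truth, sim_cfg, seed=subj_seed + 1)
        except Exception as exc:
            raise PipelineError(f"simulate-nn13 (subject {s}): {exc}") from exc

        try:
            fgas = hu_to_fgas(hu)
            fgas_rel = lobe_relative_fgas(fgas, mask)
        except Exception as exc:
            raise PipelineError(f"fgas (subject {s}): {exc}") from exc

        try:
            vq = WashoutModel(
                nn_scan,
                mask,
                apnea_window=config.apnea_window,
                washout_window=config.washout_window,
                smoothing_mm=config.smoothing_mm,
                signal_threshold_frac=config.signal_threshold,
            ).fit()
            lobe_vq = vq.lobe_means().set_index("lobe")
        except Exception as exc:
            raise PipelineError(f"vq (subject {s}): {exc}") from exc

        ki_by_lobe: dict[str, float] = {}
        if config.run_fdg:
            try:
                fdg_scan, plasma = simulate_fdg(truth, sim_cfg, seed=subj_seed + 2)
                input_fn = build_input_function(plasma)
                ki_results = lobe_ki(fdg_scan, mask, input_fn, t_star=config.t_star_min)
                ki_by_lobe = {r: res.ki for r, res in ki_results.items()}
            except Exception as exc:
                raise PipelineError(f"ki (subject {s}): {exc}") from exc

        for role in LOBE_ROLES:
            row = {
                "subject": s,
                "lobe": role,
                "q_rel": lobe_vq.loc[role, "q_rel"],
                "sv_norm": lobe_vq.loc[role, "sv_norm"],
                "fgas_relative": fgas_rel[role],
            }
            if ki_by_lobe:
                row["ki_per_min"] = ki_by_lobe[role]
            per_subject_rows.append(row)

        if s == 0:
            try:
                profile = gravity_profile(vq.perfusion, mask)
                profile.to_frame().to_csv(out / "gravity_profile.csv", index=False)
                artifacts["gravity_profile"] = out / "gravity_profile.csv"
            except Exception as exc:
                raise PipelineError(f"regional (subject {s}): {exc}") from exc
            if config.write_maps:
                write_volume(hu, out / "subject0_hu.nii.gz")
                write_lobe_mask(mask, out / "subject0_lobes.nii.gz")
                write_volume(fgas, out / "subject0_fgas.nii.gz")
                write_volume(vq.perfusion, out / "subject0_q_rel.nii.gz")
                write_volume(vq.specific_ventilation, out / "subject0_sv.nii.gz")
            if config.run_fdg and config.write_maps:
                ki_df = lobe_ki_table(ki_results)
                with open(out / "subject0_patlak.csv", "w", newline="") as fh:
                    fh.write(f"# config_hash: {provenance['config_hash']}\n")
                    ki_df.to_csv(fh, index=False)

    import pandas as pd

    lobe_table = pd.DataFrame(per_subject_rows)
    with open(out / "lobe_means.csv", "w", newline="") as fh:
        for k, v in provenance.items():
            fh.write(f"# {k}: {v}\n")
        lobe_table.to_csv(fh, index=False)
    artifacts["lobe_means"] = out / "lobe_means.csv"

    try:
        comparisons: dict[str, Any] = {}
        metrics = ["q_rel", "sv_norm", "fgas_relative"] + (
            ["ki_per_min"] if config.run_fdg else []
        )
        for metric in metrics:
            groups = {
                role: lobe_table.loc[lobe_table.lobe == role, metric].tolist()
                for role in LOBE_ROLES
            }
            cmp = anova_on_ranks(groups, alpha=config.alpha, seed=config.seed)
            comparisons[metric] = {
                "H": cmp.statistic,
                "p": cmp.p_value,
                "pairwise": {
                    f"{a}_vs_{b}": {
                        "q": d.statistic,
                        "p": d.p_value,
                        "significant": bool(d.significant),
                    }
                    for (a, b), d in cmp.pairwise.items()
                },
            }
        if config.cell_counts_csv is not None:
            records = read_cell_counts(config.cell_counts_csv)
            conc_rows = [
                {"lobe_role": r.lobe_role, **bal_concentrations(r)} for r in records
            ]
            comparisons["bal_concentrations"] = conc_rows
        write_report(comparisons, out / "comparison.json", "json", provenance)
        artifacts["comparison"] = out / "comparison.json"
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stats: {exc}") from exc

    artifacts["lobe_table"] = lobe_table
    artifacts["comparisons"] = comparisons
    log.info("pipeline complete: %d subjects, outputs in %s", config.n_subjects, out)
    return artifacts
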