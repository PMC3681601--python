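"""End-to-end analysis harnesses and the config-driven pipeline runner.

Chains the stages into the three analyses the package exists for:

1. FRAP turnover — simulate or load an ensemble of bleached/control trace
   pairs, correct for acquisition bleaching against the averaged control,
   normalize, pool, and fit/select recovery models;
2. axial profile comparison — profile two groups of spindle images and
   compare their sub-polar/equator ratios with a Wilcoxon rank-sum test;
3. congression correlation — correlate chromosome spread with log pole
   intensity across spindles.

All randomness derives from a single master seed; reports embed the
resolved configuration so runs are auditable and repeatable.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .frap import (
    FitResult,
    FrapTrace,
    NormalizedTrace,
    correct_photobleach,
    fit_recovery,
    normalize_trace,
    pool_traces,
    select_model,
)
from .poles import congression_correlation
from .presets import CONDITION_N_TRACES, CONDITIONS
from .profile import (
    bin_medians,
    compare_groups,
    extract_line_profile,
    normalize_profile,
    region_ratio,
)
from .synthetic import (
    ImageSimConfig,
    TraceSimConfig,
    gen_congression_dataset,
    gen_spindle_image,
    gen_trace_ensemble,
)

__all__ = [
    "derive_seed",
    "mean_control",
    "normalize_ensemble",
    "recover_condition",
    "profile_region_ratio",
    "RunConfig",
    "run_pipeline",
]


def derive_seed(master: int, *key) -> int:
    """Deterministic sub-seed (< 2**31) for a named pipeline stage."""
    parts = [int(master)] + [zlib.crc32(str(k).encode()) for k in key]
    ss = np.random.SeedSequence(parts)
    return int(ss.generate_state(1)[0] % 2**31)


def mean_control(controls: list[FrapTrace]) -> FrapTrace:
    """Average non-bleached control spindles into one control trace."""
    if not controls:
        raise ValueError("no control traces")
    grid = controls[0].times
    for tr in controls[1:]:
        if tr.times.shape != grid.shape or not np.allclose(tr.times, grid):
            raise ValueError("control traces must share a time grid")
    mean = np.mean([tr.intensities for tr in controls], axis=0)
    return FrapTrace(grid, mean, controls[0].n_pre, label="mean_control")


def normalize_ensemble(
    pairs: list[tuple[FrapTrace, FrapTrace]],
) -> tuple[NormalizedTrace, np.ndarray]:
    """Correct, normalize and pool an ensemble of (sample, control) pairs.

    Acquisition bleaching is estimated from the average of all control
    spindles, then each bleached trace is corrected against that mean
    control, normalized, and the ensemble pooled into a mean trace with
    per-timepoint SEM.
    """
    ctrl = mean_control([c for _, c in pairs])
    normalized = [
        normalize_trace(correct_photobleach(s, ctrl)) for s, _ in pairs
    ]
    return pool_traces(normalized)


def recover_condition(
    condition: str,
    seed: int,
    n_traces: int | None = None,
    noise_sd: float = 0.03,
    n_starts: int = 16,
) -> FitResult:
    """Simulate a condition's FRAP ensemble and re-fit its own model kind.

    This is the parameter-recovery harness: traces are generated from the
    condition's reference turnover parameters under the standard protocol
    (3 pre-bleach frames, 5 s sampling to 165 s, acquisition bleaching),
    pushed through correction/normalization/pooling, and fitted with the
    model family the condition was originally described by.
    """
    params = CONDITIONS[condition]
    n = n_traces if n_traces is not None else CONDITION_N_TRACES[condition]
    cfg = TraceSimConfig(params=params, noise_sd=noise_sd, seed=seed)
    pairs = gen_trace_ensemble(cfg, n)
    pooled, _ = normalize_ensemble(pairs)
    return fit_recovery(pooled, params.model_kind, n_starts=n_starts, seed=seed)


def profile_region_ratio(image, channel: str = "tubulin", width: int = 1) -> float:
    """Sub-polar/equator ratio of one spindle image's axial profile."""
    pos, ints = extract_line_profile(image, channel, width=width)
    prof = normalize_profile(pos, ints)
    return region_ratio(bin_medians(prof))


# ---------------------------------------------------------------------------
# config-driven runner


@dataclass
class RunConfig:
    """Parameters for one full pipeline run.

    Unknown keys in any block are rejected rather than ignored, so typos
    cannot silently fall back to defaults.
    """

    seed: int = 0
    out_dir: str | None = None
    verbose: bool = False
    frap: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    congression: dict = field(default_factory=dict)

    _FRAP_KEYS = {"condition", "n_traces", "noise_sd", "n_starts"}
    _PROFILE_KEYS = {"n_per_group", "subpolar_scale_mutant", "noise_sd"}
    _CONGRESSION_KEYS = {"n", "slope", "intercept", "noise_sd"}

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        for blk, allowed in [
            (cfg.frap, cls._FRAP_KEYS),
            (cfg.profile, cls._PROFILE_KEYS),
            (cfg.congression, cls._CONGRESSION_KEYS),
        ]:
            extra = set(blk) - allowed
            if extra:
                raise ValueError(f"unknown config key(s): {sorted(extra)}")
        return cfg


def _fit_to_dict(res: FitResult) -> dict:
    p = res.params
    return {
        "model_kind": p.model_kind,
        "f": p.f,
        "s": p.s,
        "tf_half_s": p.tf_half,
        "ts_half_s": p.ts_half,
        "immobile_fraction": p.immobile_fraction,
        "rss": res.rss,
        "aicc": res.aicc,
        "n_obs": res.n_obs,
        "converged": res.converged,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analyses and return one JSON-ready report."""
    report: dict = {
        "version": __version__,
        "config": {
            "seed": config.seed,
            "frap": dict(config.frap),
            "profile": dict(config.profile),
            "congression": dict(config.congression),
        },
        "stages": {},
    }

    # --- FRAP turnover ---
    stage = "frap"
    try:
        fr = config.frap
        condition = fr.get("condition", "oocyte_metaphase_I")
        params = CONDITIONS[condition]
        n = fr.get("n_traces", CONDITION_N_TRACES[condition])
        cfg = TraceSimConfig(
            params=params,
            noise_sd=fr.get("noise_sd", 0.03),
            seed=derive_seed(config.seed, "frap", condition),
        )
        pairs = gen_trace_ensemble(cfg, n)
        pooled, sem = normalize_ensemble(pairs)
        best, table, indeterminate = select_model(
            pooled, seed=derive_seed(config.seed, "frap-select")
        )
        report["stages"]["frap"] = {
            "condition": condition,
            "n_traces": n,
            "selected_model": best,
            "selection_indeterminate": indeterminate,
            "fits": {k: _fit_to_dict(v) for k, v in table.items()},
            "pooled_sem_mean": float(np.mean(sem)),
        }
    except Exception as exc:  # pragma: no cover - surfaced to the caller
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- axial profile comparison ---
    stage = "profile"
    try:
        pr = config.profile
        n_per = pr.get("n_per_group", 20)
        scale_mut = pr.get("subpolar_scale_mutant", 0.75)
        noise = pr.get("noise_sd", 0.05)
        ratios = {}
        for group, scale in [("wild_type", 1.0), ("mutant", scale_mut)]:
            vals = []
            for i in range(n_per):
                img = gen_spindle_image(
                    ImageSimConfig(
                        subpolar_scale=scale,
                        noise_sd=noise,
                        seed=derive_seed(config.seed, "profile", group, i),
                    )
                )
                vals.append(profile_region_ratio(img))
            ratios[group] = vals
        stat, p = compare_groups(ratios["wild_type"], ratios["mutant"])
        report["stages"]["profile"] = {
            "n_per_group": n_per,
            "ratio_mean_wild_type": float(np.mean(ratios["wild_type"])),
            "ratio_mean_mutant": float(np.mean(ratios["mutant"])),
            "wilcoxon_statistic": stat,
            "wilcoxon_p": p,
        }
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- congression correlation ---
    stage = "congression"
    try:
        cg = config.congression
        records = gen_congression_dataset(
            n=cg.get("n", 26),
            slope=cg.get("slope", -1.5),
            intercept=cg.get("intercept", 12.0),
            noise_sd=cg.get("noise_sd"),
            seed=derive_seed(config.seed, "congression"),
        )
        r, p, n = congression_correlation(records)
        report["stages"]["congression"] = {"r": r, "p": p, "n": n}
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
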