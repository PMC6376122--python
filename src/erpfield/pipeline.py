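"""Orchestration of the full analysis over synthetic or stored data.

``run_full_analysis`` wires the modules together exactly as the analysis
design prescribes: preprocessing and per-participant condition averages,
mass-univariate amplitude statistics with temporal/spatial persistence
criteria and sign-flip randomization for each condition contrast, global
field strength (GFP) and topography (TANOVA) randomization tests, and — for
every TANOVA window intersecting the late-positive-potential search range —
LAURA source estimation with voxel-wise group statistics.  The orchestration
layer computes nothing itself; every reported number comes from a module
operation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavioral, globalfield, pointwise, preprocess, sources, synthetic
from .montage import PERIPHERAL_BELT, apply_exclusion, build_montage
from .synthetic import CONDITIONS, GeneratorConfig

__all__ = ["AnalysisConfig", "run_full_analysis", "face1_control_analysis"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to reproduce one full analysis run."""

    data_source: str = "synthetic"  # or a path to an HDF5 epoch container
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    artifact_rate: float = 0.0
    p2p_threshold_uv: float = 200.0
    alpha: float = 0.01
    min_samples: int = 10
    min_channels: int = 5
    n_perm: int = 1000
    min_duration_ms: float = 20.0
    grid_spacing: float = 0.15
    laura_exponent: float = 2.0
    lambda_frac: float = 0.01
    min_cluster: int = 10
    lpp_range_ms: tuple[float, float] = (300.0, 800.0)
    comparisons: tuple = (("Fear", "Neutral"), ("Happiness", "Neutral"),
                          ("Fear", "Happiness"))
    seed: int = 0

    def __post_init__(self):
        for name in ("p2p_threshold_uv", "alpha", "min_samples", "min_channels",
                     "n_perm", "min_duration_ms", "grid_spacing", "min_cluster"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for a, b in self.comparisons:
            if a not in CONDITIONS or b not in CONDITIONS:
                raise ValueError(f"comparison ({a}, {b}) references unknown conditions")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = dataclasses.asdict(self.generator)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        if "window_ms" in gen:
            gen["window_ms"] = tuple(gen["window_ms"])
        d["generator"] = GeneratorConfig(**gen)
        if "lpp_range_ms" in d:
            d["lpp_range_ms"] = tuple(d["lpp_range_ms"])
        if "comparisons" in d:
            d["comparisons"] = tuple(tuple(c) for c in d["comparisons"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _prepare_evokeds(config: AnalysisConfig, *, full_sequence: bool = False):
    """Generate/load epochs, reject trials, re-reference, and average."""
    mont = apply_exclusion(build_montage(), PERIPHERAL_BELT)
    if config.data_source == "synthetic":
        design = synthetic.generate_design(config.generator.n_participants,
                                           config.seed)
        templates = synthetic.default_templates(mont)
        epochs = synthetic.generate_epochs(design, templates, config.generator,
                                           mont, full_sequence=full_sequence)
        ratings = synthetic.generate_ratings(design, seed=config.seed)
    else:
        from .io import load_epochs

        epochs = load_epochs(config.data_source)
        design = None
        ratings = None
    if config.artifact_rate > 0:
        epochs, _truth = synthetic.inject_artifacts(
            epochs, rate=config.artifact_rate, seed=config.seed)
    epochs, counts = preprocess.reject_trials(epochs, config.p2p_threshold_uv)
    epochs = [preprocess.rereference_average(ep) for ep in epochs]
    lock = "Face_1" if full_sequence else "Face_2"
    evokeds = {}
    for ep in epochs:
        ev = preprocess.average_evoked(ep, (0.0, 1200.0), lock=lock)
        evokeds.setdefault(ep.condition, []).append(ev)
    for cond in evokeds:
        evokeds[cond].sort(key=lambda e: e.participant)
    log.info("evokeds prepared: %s participants x %d conditions",
             len(next(iter(evokeds.values()))), len(evokeds))
    return mont, evokeds, counts, ratings


def _amplitude_analysis(config, mont, ev_a, ev_b, comparison):
    tmap = pointwise.paired_t_map(ev_a, ev_b, comparison)
    mask = tmap.p < config.alpha
    mask = pointwise.temporal_persistence_filter(mask, config.min_samples)
    mask = pointwise.spatial_extent_filter(mask, mont, config.min_channels)
    diffs = pointwise.stack_differences(ev_a, ev_b)
    _p_rand, rand_mask = pointwise.signflip_randomization(
        diffs, config.alpha, config.n_perm, config.min_samples, config.seed)
    report = pointwise.summarize_effects(
        mask, tmap, mont, ev_a[0].sfreq, float(ev_a[0].tmin_ms),
        randomization_mask=rand_mask)
    return report


def run_full_analysis(config: AnalysisConfig, outdir: str | Path | None = None) -> dict:
    """Run the complete pipeline; optionally write the report bundle.

    Returns a dict with, per comparison, the amplitude ``SignificanceReport``,
    GFP and TANOVA windows, and — for TANOVA windows intersecting the LPP
    search range — the voxel-wise source statistics.  Re-running with the
    same config reproduces the bundle bit-for-bit.
    """
    mont, evokeds, counts, ratings = _prepare_evokeds(config)
    bundle: dict = {"config": config.to_dict(), "comparisons": {}}

    wide = counts.pivot(index="participant", columns="condition", values="accepted")
    F, dfs, p = preprocess.trial_count_anova(wide.to_numpy())
    bundle["trial_counts"] = {"F": F, "df": list(dfs), "p": p,
                              "table": counts.to_dict(orient="records")}

    grid = lead = op = None
    for cond_a, cond_b in config.comparisons:
        name = f"{cond_a} vs {cond_b}"
        ev_a, ev_b = evokeds[cond_a], evokeds[cond_b]
        amp = _amplitude_analysis(config, mont, ev_a, ev_b, name)
        _p_gfp, gfp_windows = globalfield.gfp_randomization_test(
            ev_a, ev_b, config.alpha, config.n_perm, config.min_duration_ms,
            config.seed)
        _diss, _p_tan, tan_windows = globalfield.tanova(
            ev_a, ev_b, config.alpha, config.n_perm, config.min_duration_ms,
            config.seed)
        entry = {
            "amplitude": amp.to_json_dict(),
            "gfp_windows": [w.to_dict() for w in gfp_windows],
            "tanova_windows": [w.to_dict() for w in tan_windows],
            "sources": [],
        }
        lo, hi = config.lpp_range_ms
        for w in tan_windows:
            if w.end_ms < lo or w.start_ms > hi:
                continue
            if op is None:
                grid = sources.build_solution_grid(config.grid_spacing)
                lead = sources.compute_leadfield(grid, mont)
                op = sources.build_laura_operator(lead, grid,
                                                  config.laura_exponent,
                                                  config.lambda_frac)
            est_a = [sources.rms_normalize(sources.apply_inverse(e, (w.start_ms, w.end_ms), op))
                     for e in ev_a]
            est_b = [sources.rms_normalize(sources.apply_inverse(e, (w.start_ms, w.end_ms), op))
                     for e in ev_b]
            rep = sources.voxelwise_ttest(est_a, est_b, grid, config.alpha,
                                          config.min_cluster)
            entry["sources"].append({"window": [w.start_ms, w.end_ms],
                                     **rep.to_json_dict()})
        bundle["comparisons"][name] = entry

    if ratings is not None:
        rescaled = behavioral.rescale_scores(ratings)
        bundle["behavior"] = {
            "summary": behavioral.condition_summary(rescaled).to_dict(orient="records")
        }

    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def face1_control_analysis(config: AnalysisConfig,
                           outdir: str | Path | None = None) -> dict:
    """Amplitude analysis locked to the first face (negative control).

    The synthetic generator injects condition effects only at the second
    face onset, so first-face contrasts should come out empty.  The report
    schema matches the second-face amplitude reports.
    """
    mont, evokeds, counts, _ = _prepare_evokeds(config, full_sequence=True)
    bundle: dict = {"config": config.to_dict(), "comparisons": {}}
    for cond_a, cond_b in config.comparisons:
        name = f"{cond_a} vs {cond_b}"
        amp = _amplitude_analysis(config, mont, evokeds[cond_a], evokeds[cond_b], name)
        bundle["comparisons"][name] = {"amplitude": amp.to_json_dict()}
    if outdir is not None:
        _write_bundle(bundle, Path(outdir), stem="face1_control")
    return bundle


def _write_bundle(bundle: dict, outdir: Path, stem: str = "report") -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"{stem}.json").write_text(
        json.dumps(bundle, indent=1, sort_keys=True, default=_jsonable))
    for name, entry in bundle.get("comparisons", {}).items():
        effects = entry.get("amplitude", {}).get("effects", [])
        if effects:
            import pandas as pd

            safe = name.replace(" ", "_")
            pd.DataFrame(effects).to_csv(outdir / f"{stem}_{safe}_effects.tsv",
                                         sep="\t", index=False)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
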