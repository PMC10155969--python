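"""Figure-level experiment runner: configured, seeded, logged model runs.

Ties the pipeline together (stimulus → optics → EMD array → lobula network →
segmentation scoring) and runs the model's standard experiments: stage-wise
F-measure dissection, receptive-field/τ_m/dot/bar/speed/contrast sweeps,
direction-opposition tests, and the LC15-like single-unit protocols.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .emd import EMDArray, EMDConfig
from .evaluation import SegmentationSeries, evaluate_series, TRANSIENT_FRAMES
from .lobula import LobulaNetwork, NetworkConfig
from .optics import OpticsConfig, downsample_mask, preprocess
from .stimulus import StimulusMovie, StimulusSpec, make_movie

__all__ = [
    "RunResult",
    "ExperimentConfig",
    "rf_side_units",
    "run_model",
    "stage_signal",
    "evaluate_stage",
    "run_experiment",
    "sweep",
    "direction_opposition_test",
    "textured_bar_spec",
    "square_figure_spec",
    "theta_bar_spec",
    "theta_moving_background_spec",
    "small_object_spec",
    "dark_bar_spec",
    "wide_field_grating_spec",
    "bar_plus_grating_spec",
    "panorama_bar_spec",
]


def rf_side_units(rf_deg: float, optics_cfg: OpticsConfig) -> int:
    """Receptive-field side in EMD units: nearest odd integer to
    rf_deg / (η · deg_per_pixel).  E.g. 10° → 5 units, 14° → 7 units at the
    default optics."""
    side = rf_deg / optics_cfg.deg_per_unit
    lo = max(1, int(np.floor(side)) // 2 * 2 + 1)  # nearest odd below-or-at
    hi = lo + 2
    return lo if abs(side - lo) <= abs(hi - side) else hi


# ---------------------------------------------------------------------------
# model run
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Recorded per-frame signals of one model run on the EMD grid."""

    spec: StimulusSpec
    optics_cfg: OpticsConfig
    emd_cfg: EMDConfig
    net_cfg: NetworkConfig
    gt_masks: np.ndarray  # (T, h, w) bool, downsampled ground truth
    signals: dict  # stage name -> (T, h, w) float stack
    v_center: dict  # module -> (T,) center-unit membrane potential trace

    @property
    def n_frames(self) -> int:
        return self.gt_masks.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.gt_masks.shape[1:]


_DEFAULT_RECORD = ("emd_output", "Ir_input", "Ir_output")


def run_model(
    movie: StimulusMovie | StimulusSpec,
    optics_cfg: OpticsConfig | None = None,
    emd_cfg: EMDConfig | None = None,
    net_cfg: NetworkConfig | None = None,
    record: tuple[str, ...] = _DEFAULT_RECORD,
    record_center_traces: bool = False,
) -> RunResult:
    """Stream a stimulus movie through optics, EMD array and lobula network.

    ``record`` names the per-frame stage stacks to keep: ``"emd_output"``,
    ``"<module>_input"`` (signed conductance; Ir/Il only), ``"<module>_output"``
    (sigmoid output) or ``"<module>_v"`` (membrane potential) for any of the
    six modules.  Frames are processed one at a time so full-resolution
    stimuli never need to be held per stage.
    """
    spec = movie if isinstance(movie, StimulusSpec) else movie.spec
    if optics_cfg is None:
        optics_cfg = OpticsConfig(deg_per_pixel=spec.deg_per_pixel)
    if emd_cfg is None:
        emd_cfg = EMDConfig()
    if net_cfg is None:
        net_cfg = NetworkConfig()
    if isinstance(movie, StimulusSpec):
        movie = make_movie(movie)

    eta = optics_cfg.downsample_factor
    emd_array = EMDArray(emd_cfg)
    net: LobulaNetwork | None = None
    signals: dict[str, list[np.ndarray]] = {name: [] for name in record}
    gt_ds: list[np.ndarray] = []
    v_center: dict[str, list[float]] = {}

    for t in range(len(movie)):
        frame_ds = preprocess(movie.frames[t], optics_cfg)
        if net is None:
            emd_array.reset(frame_ds)
            net = LobulaNetwork(frame_ds.shape, net_cfg)
        mf = emd_array.step(frame_ds)
        combined = mf.combined
        net.step_frame(combined)

        gt_ds.append(downsample_mask(movie.gt_masks[t], eta))
        for name in record:
            if name == "emd_output":
                signals[name].append(combined)
            elif name.endswith("_input"):
                signals[name].append(net.input_conductance(combined, name[:-6]))
            elif name.endswith("_output"):
                signals[name].append(net.output(name[:-7]))
            elif name.endswith("_v"):
                signals[name].append(net.state.v[name[:-2]].copy())
            else:
                raise ValueError(f"unknown stage {name!r}")
        if record_center_traces:
            h, w = frame_ds.shape
            for m, vm in net.state.v.items():
                v_center.setdefault(m, []).append(float(vm[h // 2, w // 2]))

    return RunResult(
        spec=spec,
        optics_cfg=optics_cfg,
        emd_cfg=emd_cfg,
        net_cfg=net_cfg,
        gt_masks=np.stack(gt_ds),
        signals={k: np.stack(v) for k, v in signals.items()},
        v_center={m: np.array(tr) for m, tr in v_center.items()},
    )


def stage_signal(run: RunResult, stage: str, module: str = "Ir") -> np.ndarray:
    """Per-frame signed stage matrices of a recorded run.

    ``stage`` is one of ``emd_output`` (combined motion field),
    ``module_input`` (signed conductance of Ir/Il) or ``module_output``
    (sigmoid output of any module).
    """
    if stage == "emd_output":
        key = "emd_output"
    elif stage == "module_input":
        key = f"{module}_input"
    elif stage == "module_output":
        key = f"{module}_output"
    else:
        raise ValueError(f"unknown stage {stage!r}")
    if key not in run.signals:
        raise KeyError(f"stage {key!r} was not recorded in this run")
    return run.signals[key]


def evaluate_stage(
    run: RunResult,
    stage: str,
    module: str = "Ir",
    threshold_fraction: float = 0.5,
    transient_frames: int = TRANSIENT_FRAMES,
    border_margin: int = 0,
) -> SegmentationSeries:
    """Segment a stage and score it against the downsampled ground truth.

    At the EMD stage the component whose sign matches the evaluated module's
    preferred direction is scored (+1 for Ir, −1 for Il); module input
    conductances and sigmoid outputs are already oriented by the module's
    receptive-field polarity, so they are evaluated with +1.
    """
    preferred_sign = -1 if (stage == "emd_output" and module == "Il") else 1
    return evaluate_series(
        stage_signal(run, stage, module),
        run.gt_masks,
        stage=f"{module}:{stage}" if stage != "emd_output" else stage,
        threshold_fraction=threshold_fraction,
        preferred_sign=preferred_sign,
        transient_frames=transient_frames,
        border_margin=border_margin,
    )


# ---------------------------------------------------------------------------
# stimulus presets for the standard experiments
# ---------------------------------------------------------------------------

def textured_bar_spec(
    bar_width: float = 25.0,
    contrast: float = 0.8,
    dot_size: float = 2.6,
    figure_speed: float = 66.0,
    background_speed: float = 0.0,
    duration_frames: int = 300,
    seed: int = 0,
) -> StimulusSpec:
    """Random-dot bar over a random-dot ground (stationary or moving)."""
    return StimulusSpec(
        kind="bar_on_ground",
        figure_width=bar_width,
        figure_height=90.0,
        michelson_contrast=contrast,
        dot_size=dot_size,
        figure_speed=figure_speed,
        background_speed=background_speed,
        duration_frames=duration_frames,
        rng_seed=seed,
    )


def square_figure_spec(
    side: float = 34.0, contrast: float = 0.8, speed: float = 66.0,
    duration_frames: int = 300, seed: int = 0,
) -> StimulusSpec:
    """Textured square moving over a stationary similarly textured ground."""
    return StimulusSpec(
        kind="square",
        figure_width=side,
        figure_height=side,
        michelson_contrast=contrast,
        figure_speed=speed,
        duration_frames=duration_frames,
        rng_seed=seed,
    )


def theta_bar_spec(
    bar_width: float = 25.0, speed: float = 66.0, dot_size: float = 2.6,
    duration_frames: int = 300, seed: int = 0,
) -> StimulusSpec:
    """Theta-motion bar: envelope moves right, internal texture moves left."""
    return StimulusSpec(
        kind="theta",
        figure_width=bar_width,
        figure_height=90.0,
        dot_size=dot_size,
        figure_speed=speed,
        internal_texture_speed=-speed,
        background_speed=0.0,
        duration_frames=duration_frames,
        rng_seed=seed,
    )


def theta_moving_background_spec(
    bar_width: float = 25.0, speed: float = 66.0, dot_size: float = 2.6,
    duration_frames: int = 300, seed: int = 0,
) -> StimulusSpec:
    """Theta figure sharing the background's leftward motion while its
    internal texture coherently moves rightward."""
    return StimulusSpec(
        kind="theta_moving_bg",
        figure_width=bar_width,
        figure_height=90.0,
        dot_size=dot_size,
        figure_speed=-speed,
        background_speed=-speed,
        internal_texture_speed=speed,
        figure_start_deg=140.0,
        duration_frames=duration_frames,
        rng_seed=seed,
    )


def _second_type(**kw) -> StimulusSpec:
    base = dict(
        azimuth_extent=180.0,
        elevation_extent=70.0,
        figure_speed=33.0,
        figure_start_deg=60.0,
        duration_frames=300,
        background_luminances=(0.25, 0.75),
    )
    base.update(kw)
    return StimulusSpec(**base)


def small_object_spec(**kw) -> StimulusSpec:
    """Dark 8.9°×8.9° square over a light background."""
    return _second_type(kind="small_obj", figure_width=8.9, figure_height=8.9, **kw)


def dark_bar_spec(height: float = 70.0, speed: float = 33.0, **kw) -> StimulusSpec:
    """Dark 8.9°-wide vertical bar over a light background."""
    return _second_type(
        kind="bar", figure_width=8.9, figure_height=height, figure_speed=speed, **kw
    )


def wide_field_grating_spec(speed: float = 33.0, **kw) -> StimulusSpec:
    """Full-field square grating (wavelength 17.8°, 50 % contrast) drifting
    rightward; no foreground, so the ground-truth masks are all false."""
    return _second_type(
        kind="wide_field_grating",
        grating_wavelength=17.8,
        figure_speed=0.0,
        background_speed=speed,
        **kw,
    )


def bar_plus_grating_spec(moving_background: bool = False, **kw) -> StimulusSpec:
    """Black bar over a 33 %-contrast square grating, stationary or co-moving."""
    return _second_type(
        kind="bar_plus_grating",
        figure_width=8.9,
        figure_height=70.0,
        figure_luminance=0.0,
        background_luminances=(0.25, 0.5),
        grating_wavelength=17.8,
        background_speed=33.0 if moving_background else 0.0,
        **kw,
    )


def panorama_bar_spec(
    c_rms: float = 1.0, speed: float = 33.0, duration_frames: int = 300, seed: int = 0,
) -> StimulusSpec:
    """Synthetic 360° panorama with a leftward gray bar over a rightward-
    moving scene (natural-scene stand-in)."""
    return StimulusSpec(
        kind="synthetic_scene_bar",
        azimuth_extent=360.0,
        elevation_extent=97.0,
        deg_per_pixel=0.39,
        figure_width=15.0,
        figure_height=97.0,
        figure_luminance=0.5,
        figure_speed=-speed,
        background_speed=speed,
        c_rms=c_rms,
        figure_start_deg=180.0,
        duration_frames=duration_frames,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# configured experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Everything needed to replay one experiment deterministically."""

    stimulus: StimulusSpec
    optics: OpticsConfig | None = None
    emd: EMDConfig = field(default_factory=EMDConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    stages: tuple[str, ...] = _DEFAULT_RECORD
    eval_module: str = "Ir"
    threshold_fraction: float = 0.5
    transient_frames: int = TRANSIENT_FRAMES
    record_center_traces: bool = False

    def resolved_optics(self) -> OpticsConfig:
        return self.optics or OpticsConfig(deg_per_pixel=self.stimulus.deg_per_pixel)

    def config_hash(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


_STAGE_OF_KEY = {
    "emd_output": "emd_output",
    "input": "module_input",
    "output": "module_output",
}


def _stage_and_module(key: str, default_module: str) -> tuple[str, str]:
    if key == "emd_output":
        return "emd_output", default_module
    module, _, suffix = key.partition("_")
    return _STAGE_OF_KEY[suffix], module


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run one configured experiment; optionally write metrics to disk.

    Returns a dict with the :class:`RunResult`, one
    :class:`SegmentationSeries` per recorded stage, and a JSON-able summary
    (config hash, seed, package version, mean F per stage).  With
    ``out_dir`` set, writes ``metrics.csv`` (frame, stage, threshold, TP,
    FP, TN, FN, precision, recall, f_measure) and ``summary.json``.
    """
    run = run_model(
        cfg.stimulus,
        cfg.resolved_optics(),
        cfg.emd,
        cfg.network,
        record=cfg.stages,
        record_center_traces=cfg.record_center_traces,
    )
    series: dict[str, SegmentationSeries] = {}
    rows = []
    for key in cfg.stages:
        if key.endswith("_v"):
            continue
        stage, module = _stage_and_module(key, cfg.eval_module)
        s = evaluate_stage(
            run, stage, module, cfg.threshold_fraction, cfg.transient_frames
        )
        series[key] = s
        for t in range(run.n_frames):
            from .evaluation import confusion

            c = confusion(s.masks[t], run.gt_masks[t])
            rows.append(
                dict(
                    frame_index=t,
                    stage=key,
                    threshold=cfg.threshold_fraction,
                    TP=c.tp, FP=c.fp, TN=c.tn, FN=c.fn,
                    precision=s.precision[t],
                    recall=s.recall[t],
                    f_measure=s.f[t],
                )
            )
    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.stimulus.rng_seed,
        "version": __version__,
        "n_frames": run.n_frames,
        "grid_shape": list(run.grid_shape),
        "mean_f": {k: s.mean_f for k, s in series.items()},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return {"run": run, "series": series, "summary": summary}


def _set_param(cfg: ExperimentConfig, path: str, value) -> ExperimentConfig:
    group, _, name = path.partition(".")
    if group == "stimulus":
        return replace(cfg, stimulus=replace(cfg.stimulus, **{name: value}))
    if group == "network":
        return replace(cfg, network=replace(cfg.network, **{name: value}))
    if group == "emd":
        return replace(cfg, emd=replace(cfg.emd, **{name: value}))
    if group == "optics":
        return replace(cfg, optics=replace(cfg.resolved_optics(), **{name: value}))
    raise ValueError(f"unknown parameter group {group!r}")


def sweep(
    cfg: ExperimentConfig,
    parameter_path: str,
    grid,
    metric: str = "mean_f",
    metric_stage: str | None = None,
    peak_module: str = "Lm",
) -> pd.DataFrame:
    """Re-run an experiment over a parameter grid.

    ``metric`` is ``"mean_f"`` (transient-excluded mean F at
    ``metric_stage``, default the evaluated module's output) or ``"peak_v"``
    (peak membrane potential of ``peak_module``'s center unit).  Returns one
    row per grid value.
    """
    if not len(grid):
        raise ValueError("sweep grid must be nonempty")
    if metric not in ("mean_f", "peak_v"):
        raise ValueError("metric must be 'mean_f' or 'peak_v'")
    rows = []
    for value in grid:
        sub = _set_param(cfg, parameter_path, value)
        if metric == "peak_v":
            sub = replace(sub, record_center_traces=True)
        res = run_experiment(sub)
        row = {parameter_path: value}
        if metric == "mean_f":
            key = metric_stage or f"{cfg.eval_module}_output"
            row["mean_f"] = res["series"][key].mean_f
        else:
            trace = res["run"].v_center[peak_module]
            row["peak_v"] = float(trace.max())
        rows.append(row)
    return pd.DataFrame(rows)


def direction_opposition_test(
    bar_velocities,
    background_velocity: float = -132.0,
    cfg: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Mean Ir-output F-measure versus bar velocity on a moving background.

    Reports, per bar velocity, whether its sign opposes the background's;
    discrimination is expected to hold only for opposite-sign velocities.
    """
    if cfg is None:
        cfg = ExperimentConfig(stimulus=textured_bar_spec())
    rows = []
    for v in bar_velocities:
        sub = _set_param(cfg, "stimulus.figure_speed", float(v))
        sub = _set_param(sub, "stimulus.background_speed", float(background_velocity))
        res = run_experiment(sub)
        rows.append(
            dict(
                bar_velocity=float(v),
                background_velocity=float(background_velocity),
                opposite_direction=bool(v * background_velocity < 0),
                mean_f=res["series"][f"{cfg.eval_module}_output"].mean_f,
            )
        )
    return pd.DataFrame(rows)
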