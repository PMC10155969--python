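"""Figure-ground discrimination of a textured bar, dissected by stage.

Runs a random-dot bar over a similarly textured stationary background
through the full pipeline and scores the segmentation (50 %-of-maximum
threshold, F-measure against the analytic ground truth) at three stages:
the raw EMD motion field, the Ir module's input conductance (spatial
smoothing only), and the Ir module's sigmoid output (spatial + temporal
smoothing).  The F-measure should improve monotonically downstream.

Uses a reduced 60°x30° field so the script finishes in seconds; pass
--full for the 180°x90°, 300-frame configuration.
"""

import sys

from emdlobula import NetworkConfig, StimulusSpec, evaluate_stage, run_model
from emdlobula.experiments import textured_bar_spec

if "--full" in sys.argv:
    spec = textured_bar_spec(seed=1)
    rf_units = 5  # 10° x 10° receptive field
    transient = 50
else:
    spec = StimulusSpec(
        kind="bar_on_ground", azimuth_extent=60.0, elevation_extent=30.0,
        figure_width=15.0, figure_height=30.0, duration_frames=80,
        figure_start_deg=5.0, rng_seed=7,
    )
    rf_units = 5
    transient = 30

run = run_model(spec, net_cfg=NetworkConfig(rf_side_emd_units=rf_units),
                record=("emd_output", "Ir_input", "Ir_output"))
print(f"EMD grid: {run.grid_shape[0]} x {run.grid_shape[1]} units, "
      f"{run.n_frames} frames of 10 ms")
for stage, label in [("emd_output", "EMD array output  "),
                     ("module_input", "Ir input (spatial)"),
                     ("module_output", "Ir output         ")]:
    f = evaluate_stage(run, stage, "Ir", transient_frames=transient).mean_f
    print(f"mean F-measure at {label}: {f:.3f}")
# A mean F near 1 at the Ir output while the EMD stage stays low shows that
# the figure is recovered by the lobula's spatiotemporal smoothing, not by
# the local motion detectors themselves.
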