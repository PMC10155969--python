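"""Octopamine-like state modulation rescues figure-ground discrimination.

A dark bar over a low-contrast grating is discriminated while the grating is
stationary, but once the grating co-moves with the bar the background drives
the motion pathway everywhere and the bar-locked segmentation collapses.
Shifting the half-activation voltage θ of the Ir/Il sigmoids from −40 mV to
−28 mV (mimicking an octopamine-induced shift of the input-output curve)
silences the weaker background drive and restores the bar response.
"""

from emdlobula import NetworkConfig, evaluate_stage, modulate_octopamine, run_model
from emdlobula.experiments import bar_plus_grating_spec

net = NetworkConfig(alpha_emd_to_lo=100.0)


def bar_locked_f(moving_bg, cfg):
    run = run_model(bar_plus_grating_spec(moving_background=moving_bg),
                    net_cfg=cfg, record=("Ir_output",))
    return evaluate_stage(run, "module_output", "Ir").mean_f


print(f"stationary grating, theta=-40 mV: F = {bar_locked_f(False, net):.3f}")
print(f"co-moving grating,  theta=-40 mV: F = {bar_locked_f(True, net):.3f}  (suppressed)")
rescued = modulate_octopamine(net, -28.0, scope=("Ir", "Il"))
print(f"co-moving grating,  theta=-28 mV: F = {bar_locked_f(True, rescued):.3f}  (restored)")
# The F-measure is computed at the Ir output with the bar as ground truth:
# high F means the network's activity is locked to the bar, not the grating.
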