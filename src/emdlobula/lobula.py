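"""Three-layer conductance-based non-spiking lobula network.

Six retinotopic modules share the EMD array's grid:

* **Ir / Il** — direction-selective inputs.  Each unit pools the signed
  ON+OFF motion field through a square 2D Gaussian receptive field; Ir uses
  the positive kernel (depolarized by rightward motion), Il the negated one.
* **Im** — direction-insensitive: pools the summed sigmoid outputs of Ir and
  Il through a small center-weighted 3×3 kernel.
* **Lr / Ll / Lm** — edge extractors postsynaptic to Ir, Il, Im, reading
  their sigmoid outputs through a 3×3 vertical Prewitt kernel.

Each unit is a leaky non-spiking neuron

    τ_m dV/dt = −V + E_Leak + R·I_syn,
    I_syn = α[g⁺(E_ext − V) + |g⁻|(E_inh − V)],

where the conductance matrix of a module is the receptive-field weighting of
its presynaptic matrix, split *after* the weighting into positive
(excitatory, reversal E_ext = 0 mV) and negative (inhibitory, reversal
E_inh = −80 mV) components.  Within each 10 ms stimulus frame the motion
input is held fixed and the network is integrated in 25 substeps of 0.4 ms;
inter-module conductances are recomputed from the evolving sigmoid outputs
at every substep.  The integrator is classical fourth-order Runge–Kutta
with the conductances frozen per substep; because the frozen-conductance
membrane equation is affine, an exact exponential propagator is also
available (``integrator="exact"``) and serves as the integration oracle.

Note that RK4 at dt = 0.4 ms becomes numerically unstable when the
effective membrane time constant τ_m/(1 + Rα·g_tot) drops below
dt/2.785…; sweeping τ_m downward therefore destroys segmentation below a
stimulus-dependent threshold.  This instability boundary is part of the
model's phenomenology (see docs/methods.md), which is why RK4 (not the
exact propagator) is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import correlate as _nd_correlate

__all__ = [
    "MODULES",
    "NetworkConfig",
    "ReceptiveField",
    "LobulaState",
    "LobulaNetwork",
    "IM_KERNEL",
    "PREWITT_KERNEL",
    "gaussian_rf",
    "conductances",
    "synaptic_current",
    "activation",
    "modulate_octopamine",
    "step_network",
]

MODULES = ("Ir", "Il", "Im", "Lr", "Ll", "Lm")

#: center-weighted kernel of the Im module (3×3, unit sum)
IM_KERNEL = np.array(
    [[0.0, 0.1, 0.0],
     [0.1, 0.6, 0.1],
     [0.0, 0.1, 0.0]]
)

#: vertical-edge Prewitt kernel shared by Lr, Ll and Lm
PREWITT_KERNEL = 0.05 * np.array(
    [[1.0, 0.0, -1.0],
     [1.0, 0.0, -1.0],
     [1.0, 0.0, -1.0]]
)


@dataclass(frozen=True)
class NetworkConfig:
    """Dynamical and synaptic parameters of the lobula network.

    ``theta_overrides`` / ``beta_overrides`` map module names to per-module
    sigmoid parameters (used for the octopamine manipulation).
    """

    tau_m: float = 5.0  # ms
    e_leak: float = -50.0  # mV
    e_ext: float = 0.0  # mV
    e_inh: float = -80.0  # mV
    r: float = 1.0  # dimensionless membrane resistance
    alpha_emd_to_lo: float = 150.0
    alpha_lo_to_lo: float = 20.0
    theta: float = -40.0  # mV, sigmoid half-activation
    beta: float = 0.5  # mV, sigmoid steepness
    rf_side_emd_units: int = 7
    dt_integrate: float = 0.4  # ms
    substeps_per_frame: int = 25
    integrator: str = "rk4"  # classical RK4, or "exact" (exponential propagator)
    theta_overrides: dict = field(default_factory=dict)
    beta_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if not self.e_inh < self.e_leak < self.e_ext:
            raise ValueError("require E_inh < E_Leak < E_ext")
        if self.rf_side_emd_units < 1 or self.rf_side_emd_units % 2 == 0:
            raise ValueError("rf_side_emd_units must be odd and >= 1")
        if self.integrator not in ("exact", "rk4"):
            raise ValueError("integrator must be 'exact' or 'rk4'")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def frame_interval_ms(self) -> float:
        return self.dt_integrate * self.substeps_per_frame

    def theta_of(self, module: str) -> float:
        return self.theta_overrides.get(module, self.theta)

    def beta_of(self, module: str) -> float:
        return self.beta_overrides.get(module, self.beta)


@dataclass(frozen=True)
class ReceptiveField:
    """Signed receptive-field kernel with an overall polarity."""

    kernel: np.ndarray
    polarity: int = 1

    @property
    def signed_kernel(self) -> np.ndarray:
        return self.polarity * self.kernel


def gaussian_rf(side_emd_units: int) -> np.ndarray:
    """Square isotropic Gaussian receptive field, SD = side/4, unit sum.

    The unit-sum normalization keeps conductance magnitudes comparable
    across receptive-field sizes, so one synaptic weight α serves the whole
    size sweep.
    """
    if side_emd_units < 1 or side_emd_units % 2 == 0:
        raise ValueError("receptive-field side must be odd and >= 1")
    if side_emd_units == 1:
        return np.ones((1, 1))
    sd = side_emd_units / 4.0
    x = np.arange(side_emd_units) - (side_emd_units - 1) / 2.0
    k1 = np.exp(-(x**2) / (2.0 * sd**2))
    k = np.outer(k1, k1)
    return k / k.sum()


def conductances(presyn: np.ndarray, rf: ReceptiveField) -> tuple[np.ndarray, np.ndarray]:
    """Receptive-field weighting of the presynaptic matrix, then sign split.

    Returns (g_plus, g_minus) with g_plus = max(c, 0), g_minus = min(c, 0),
    where c is the same-size correlation of the presynaptic matrix with the
    signed kernel (zero padding at the array borders).  The split happens
    after the weighting, so excitation and inhibition can both arise from a
    single signed kernel or a signed input.
    """
    c = _nd_correlate(np.asarray(presyn, dtype=float), rf.signed_kernel, mode="constant", cval=0.0)
    return np.maximum(c, 0.0), np.minimum(c, 0.0)


def synaptic_current(
    v: np.ndarray,
    g_plus: np.ndarray,
    g_minus: np.ndarray,
    cfg: NetworkConfig,
    alpha: float,
) -> np.ndarray:
    """I_syn = α[g⁺(E_ext − V) + |g⁻|(E_inh − V)], elementwise."""
    return alpha * (g_plus * (cfg.e_ext - v) + np.abs(g_minus) * (cfg.e_inh - v))


def activation(v: np.ndarray, theta: float, beta: float) -> np.ndarray:
    """Sigmoid output 1/(1 + exp((θ − V)/β)) mapping potential to conductance drive.

    Tolerates extreme potentials (e.g. from an unstable integration run):
    overflow saturates to 0/1 rather than raising.
    """
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp((theta - v) / beta))


def modulate_octopamine(
    cfg: NetworkConfig,
    theta_new: float,
    beta_new: float | None = None,
    scope: tuple[str, ...] = ("Ir", "Il"),
) -> NetworkConfig:
    """Octopamine-like gain-state change: shift the sigmoid half-activation
    voltage θ (and optionally the steepness β) of the modules in ``scope``.

    A θ equal to the config's baseline (with no β change) returns an
    unchanged config.
    """
    unknown = set(scope) - set(MODULES)
    if unknown:
        raise ValueError(f"unknown modules in scope: {sorted(unknown)}")
    theta_over = dict(cfg.theta_overrides)
    beta_over = dict(cfg.beta_overrides)
    for m in scope:
        if theta_new != cfg.theta:
            theta_over[m] = theta_new
        else:
            theta_over.pop(m, None)
        if beta_new is not None and beta_new != cfg.beta:
            beta_over[m] = beta_new
        elif beta_new is not None:
            beta_over.pop(m, None)
    return replace(cfg, theta_overrides=theta_over, beta_overrides=beta_over)


@dataclass
class LobulaState:
    """Membrane potentials (mV) of all six modules plus simulation time."""

    v: dict
    time_ms: float = 0.0

    @classmethod
    def at_rest(cls, shape: tuple[int, int], cfg: NetworkConfig) -> "LobulaState":
        return cls(v={m: np.full(shape, cfg.e_leak) for m in MODULES}, time_ms=0.0)

    def copy(self) -> "LobulaState":
        return LobulaState(v={m: a.copy() for m, a in self.v.items()}, time_ms=self.time_ms)


def _advance_membrane(
    v: np.ndarray,
    g_plus: np.ndarray,
    g_minus: np.ndarray,
    cfg: NetworkConfig,
    alpha: float,
    tau_m: float,
    dt: float,
) -> np.ndarray:
    """One substep of τ_m dV/dt = −V + E_Leak + R·I_syn with frozen g.

    The equation is affine, dV/dt = (V_inf − V)/τ_eff with
    τ_eff = τ_m / (1 + Rα(g⁺ + |g⁻|)).  ``integrator="exact"`` applies the
    exact propagator V ← V_inf + (V − V_inf)·exp(−dt/τ_eff); the default
    classical RK4 reproduces it to its truncation error while stable, and
    diverges (by design, like any explicit integrator) when dt/τ_eff
    exceeds the RK4 stability bound.
    """
    ga = alpha * g_plus
    gb = alpha * np.abs(g_minus)
    with np.errstate(over="ignore", invalid="ignore"):
        if cfg.integrator == "exact":
            denom = 1.0 + cfg.r * (ga + gb)
            v_inf = (cfg.e_leak + cfg.r * (ga * cfg.e_ext + gb * cfg.e_inh)) / denom
            decay = np.exp(-dt * denom / tau_m)
            return v_inf + (v - v_inf) * decay

        def f(vv: np.ndarray) -> np.ndarray:
            i_syn = ga * (cfg.e_ext - vv) + gb * (cfg.e_inh - vv)
            return (-vv + cfg.e_leak + cfg.r * i_syn) / tau_m

        k1 = f(v)
        k2 = f(v + 0.5 * dt * k1)
        k3 = f(v + 0.5 * dt * k2)
        k4 = f(v + dt * k3)
        return v + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


class LobulaNetwork:
    """Stateful six-module network advanced one stimulus frame at a time."""

    def __init__(self, shape: tuple[int, int], cfg: NetworkConfig = NetworkConfig()):
        self.cfg = cfg
        self.shape = shape
        g = gaussian_rf(cfg.rf_side_emd_units)
        self.rf = {
            "Ir": ReceptiveField(g, +1),
            "Il": ReceptiveField(g, -1),
            "Im": ReceptiveField(IM_KERNEL, +1),
            "Lr": ReceptiveField(PREWITT_KERNEL, +1),
            "Ll": ReceptiveField(PREWITT_KERNEL, +1),
            "Lm": ReceptiveField(PREWITT_KERNEL, +1),
        }
        self.state = LobulaState.at_rest(shape, cfg)

    # -- conveniences ------------------------------------------------------
    def output(self, module: str) -> np.ndarray:
        """Sigmoid output of a module's current membrane potentials."""
        cfg = self.cfg
        return activation(self.state.v[module], cfg.theta_of(module), cfg.beta_of(module))

    def input_conductance(self, motion_combined: np.ndarray, module: str) -> np.ndarray:
        """Signed conductance matrix (g⁺ + g⁻) of Ir or Il for a motion field."""
        if module not in ("Ir", "Il"):
            raise ValueError("input_conductance is defined for Ir and Il")
        gp, gm = conductances(motion_combined, self.rf[module])
        return gp + gm

    def step_frame(self, motion_combined: np.ndarray) -> LobulaState:
        """Integrate one 10 ms frame with the motion field held fixed."""
        if motion_combined.shape != self.shape:
            raise ValueError("motion field shape does not match network")
        cfg = self.cfg
        v = self.state.v
        # EMD-driven conductances are frozen for the whole frame
        g_ir = conductances(motion_combined, self.rf["Ir"])
        g_il = conductances(motion_combined, self.rf["Il"])
        dt = cfg.dt_integrate
        for _ in range(cfg.substeps_per_frame):
            act_r = activation(v["Ir"], cfg.theta_of("Ir"), cfg.beta_of("Ir"))
            act_l = activation(v["Il"], cfg.theta_of("Il"), cfg.beta_of("Il"))
            act_m = activation(v["Im"], cfg.theta_of("Im"), cfg.beta_of("Im"))
            g_im = conductances(act_r + act_l, self.rf["Im"])
            g_lr = conductances(act_r, self.rf["Lr"])
            g_ll = conductances(act_l, self.rf["Ll"])
            g_lm = conductances(act_m, self.rf["Lm"])
            pre = {
                "Ir": (g_ir, cfg.alpha_emd_to_lo),
                "Il": (g_il, cfg.alpha_emd_to_lo),
                "Im": (g_im, cfg.alpha_lo_to_lo),
                "Lr": (g_lr, cfg.alpha_lo_to_lo),
                "Ll": (g_ll, cfg.alpha_lo_to_lo),
                "Lm": (g_lm, cfg.alpha_lo_to_lo),
            }
            for m, ((gp, gm), alpha) in pre.items():
                v[m] = _advance_membrane(v[m], gp, gm, cfg, alpha, cfg.tau_m, dt)
        self.state.time_ms += cfg.frame_interval_ms
        return self.state


def step_network(
    motion_combined: np.ndarray, state: LobulaState, cfg: NetworkConfig
) -> LobulaState:
    """Functional single-frame step: returns the advanced state, leaving the
    input state untouched."""
    net = LobulaNetwork(motion_combined.shape, cfg)
    net.state = state.copy()
    return net.step_frame(motion_combined)
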