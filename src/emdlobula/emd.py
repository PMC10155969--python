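"""Retinotopic array of horizontal two-quadrant elementary motion detectors.

Each downsampled pixel feeds a Hassenstein–Reichardt-type correlator split
into parallel ON (brightness-increment) and OFF (brightness-decrement)
pathways:

1. first-order temporal high-pass (τ_HP = 250 ms) with a 10 % unfiltered DC
   bypass, removing slow luminance drift while keeping some mean level;
2. half-wave rectification into ON and OFF signals (cutoffs 0 and 0.05);
3. per pathway, a delay-and-correlate stage between horizontally adjacent
   pixels using a first-order low-pass (τ_LP = 50 ms) as the delay line,
   wired to give positive output for rightward motion;
4. a small amplitude threshold (thr = 0.002) that silences near-zero
   responses, then retinotopic ON + OFF summation.

The array is a discrete-time system updated once per 10 ms stimulus frame;
all filters use the exact exponential update for a frame-held input.
State is initialized to the first frame's steady state, so a static first
frame produces an exactly zero motion field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EMDConfig", "EMDState", "MotionField", "EMDArray",
           "high_pass", "rectify_on_off", "correlate"]


@dataclass(frozen=True)
class EMDConfig:
    tau_hp: float = 250.0  # ms
    dc_fraction: float = 0.1
    on_cutoff: float = 0.0
    off_cutoff: float = 0.05
    tau_lp: float = 50.0  # ms
    thr: float = 0.002
    dt_frame: float = 10.0  # ms
    zero_init: bool = False  # start filters at zero instead of steady state
    block_pathway: str | None = None  # "on", "off" or None

    def __post_init__(self):
        if self.tau_hp <= 0 or self.tau_lp <= 0 or self.dt_frame <= 0:
            raise ValueError("time constants and frame interval must be positive")
        if not 0.0 <= self.dc_fraction <= 1.0:
            raise ValueError("dc_fraction must lie in [0, 1]")
        if self.thr < 0:
            raise ValueError("thr must be nonnegative")
        if self.block_pathway not in (None, "on", "off"):
            raise ValueError("block_pathway must be 'on', 'off' or None")

    @property
    def k_hp(self) -> float:
        """Per-frame update gain of the τ_HP low-pass memory."""
        return 1.0 - float(np.exp(-self.dt_frame / self.tau_hp))

    @property
    def k_lp(self) -> float:
        return 1.0 - float(np.exp(-self.dt_frame / self.tau_lp))


@dataclass
class EMDState:
    """Per-pixel filter memories (τ_HP low-pass; ON/OFF τ_LP low-passes)."""

    hp_memory: np.ndarray
    lp_on: np.ndarray
    lp_off: np.ndarray

    @classmethod
    def from_first_frame(cls, frame: np.ndarray, cfg: EMDConfig) -> "EMDState":
        frame = np.asarray(frame, dtype=float)
        if cfg.zero_init:
            z = np.zeros_like(frame)
            return cls(z.copy(), z.copy(), z.copy())
        hp_out = cfg.dc_fraction * frame  # steady-state high-pass output
        on, off = rectify_on_off(hp_out, cfg)
        return cls(frame.copy(), on, off)


@dataclass
class MotionField:
    """Signed retinotopic motion estimate for one frame (+ = rightward)."""

    on_field: np.ndarray
    off_field: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return self.on_field + self.off_field


def high_pass(frame: np.ndarray, state: EMDState, cfg: EMDConfig) -> np.ndarray:
    """DC-bypassed high-pass: (1−dc)·(x − LP_τHP(x)) + dc·x.

    Output uses the pre-update memory (a luminance step passes in full on
    the frame it occurs), then the memory advances by one frame interval.
    """
    out = (1.0 - cfg.dc_fraction) * (frame - state.hp_memory) + cfg.dc_fraction * frame
    state.hp_memory += cfg.k_hp * (frame - state.hp_memory)
    return out


def rectify_on_off(hp_out: np.ndarray, cfg: EMDConfig) -> tuple[np.ndarray, np.ndarray]:
    """Half-wave rectifiers: on = max(s − on_cutoff, 0), off = max(−s − off_cutoff, 0)."""
    on = np.maximum(hp_out - cfg.on_cutoff, 0.0)
    off = np.maximum(-hp_out - cfg.off_cutoff, 0.0)
    return on, off


def correlate(signal: np.ndarray, lp_memory: np.ndarray, cfg: EMDConfig) -> np.ndarray:
    """Delay-and-correlate between horizontal neighbors, updating the delay
    line in place.

    R_i = LP(a_i)·a_{i+1} − a_i·LP(a_{i+1}); the rightmost column has no
    right neighbor and outputs 0.  Responses below ``thr`` in magnitude are
    zeroed.  A static pattern gives LP(a) = a in steady state, so the two
    products cancel and only motion is signaled.
    """
    lp_memory += cfg.k_lp * (signal - lp_memory)
    out = np.zeros_like(signal)
    out[:, :-1] = (
        lp_memory[:, :-1] * signal[:, 1:] - signal[:, :-1] * lp_memory[:, 1:]
    )
    if cfg.thr > 0:
        out[np.abs(out) < cfg.thr] = 0.0
    return out


class EMDArray:
    """Stateful ON/OFF EMD array stepped once per stimulus frame."""

    def __init__(self, cfg: EMDConfig = EMDConfig(), first_frame: np.ndarray | None = None):
        self.cfg = cfg
        self.state: EMDState | None = None
        if first_frame is not None:
            self.reset(first_frame)

    def reset(self, first_frame: np.ndarray) -> None:
        self.state = EMDState.from_first_frame(first_frame, self.cfg)

    def step(self, frame: np.ndarray) -> MotionField:
        """Advance one 10 ms frame and return the signed motion field."""
        frame = np.asarray(frame, dtype=float)
        if self.state is None:
            self.reset(frame)
        if frame.shape != self.state.hp_memory.shape:
            raise ValueError("frame shape does not match detector state")
        cfg = self.cfg
        hp = high_pass(frame, self.state, cfg)
        on, off = rectify_on_off(hp, cfg)
        r_on = correlate(on, self.state.lp_on, cfg)
        r_off = correlate(off, self.state.lp_off, cfg)
        if cfg.block_pathway == "on":
            r_on = np.zeros_like(r_on)
        elif cfg.block_pathway == "off":
            r_off = np.zeros_like(r_off)
        return MotionField(on_field=r_on, off_field=r_off)
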