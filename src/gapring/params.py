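"""Parameter records for cells, synapses, noise and stimuli.

All quantities are dimensionless. Parameters are carried in frozen dataclasses so
that parameter sweeps can run concurrently without shared mutable state.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, replace


@dataclass(frozen=True)
class CellParams:
    """Constants of the two-variable relaxation-oscillator cell.

    The cell has a fast membrane potential ``V`` and a slow recovery current
    ``W``.  The instantaneous (fast) current is N-shaped in ``V`` so the
    V-nullcline is cubic; the slow current activates sigmoidally with ``V`` and
    relaxes with a voltage-dependent time constant ``tau_w(V)`` that
    interpolates between ``tau_w_min`` (depolarized, active phase) and
    ``tau_w_max`` (hyperpolarized, silent phase).  The large ratio
    ``tau_w_max/tau_w_min`` together with the slow-activation offset
    ``w_floor`` (which places the silent-phase rest level of ``W`` just below
    the left knee of the V-nullcline) gives the cell its short duty cycle of
    1-2 %.

    Parameters
    ----------
    g_fast : float
        Scale of the N-shaped instantaneous current (default 2).
    g_slow : float
        Amplitude of the sigmoidal slow-current activation (default 2).
    tau_m : float
        Membrane time constant of the fast variable.  Only the tau_w values
        are quantitatively anchored; ``tau_m`` sets how fast jumps between
        branches are relative to the slow crawl.
    tau_w_min, tau_w_max : float
        Minimal (active phase) and maximal (silent phase) slow time constants,
        defaults 5 and 50.
    k_tw, theta_tw : float
        Rate (0.2) and half-activation voltage (0.16) of the sigmoidal voltage
        dependence of ``tau_w``; both act on the cell's normalized voltage
        ``u = (V - v_mid)/v_scale`` (the model is dimensionless and its
        printed gating constants live in the cell's own voltage unit, while
        coupling and injected currents act on physical V).
    fast_shape : float
        Shape constant of the cubic fast current
        ``I_fast(V) = g_fast * fast_shape * (u**3/3 - u)`` with
        ``u = (V - v_mid)/v_scale``; the knees of the free V-nullcline sit at
        ``V = v_mid -+ v_scale`` with ``W = -+ 2/3 * g_fast * fast_shape``.
    v_mid, v_scale : float
        Centre and half-width (in physical V) of the N-shaped region of the
        fast current.  ``v_scale`` converts between the cell's internal
        voltage unit and the scale on which gap-junction and injected
        currents act; it is the constant that calibrates the network's
        coupling sensitivity.
    theta_slow, k_slow : float
        Midpoint and steepness (in normalized voltage u) of the slow-current
        activation sigmoid.
    w_floor : float
        Offset of the slow activation: ``W_inf = w_floor +
        g_slow * s(-(u - theta_slow)/k_slow)`` with ``s(x) = 1/(1+e^x)``.
        Its distance below the left-knee ``W`` controls the length of the
        silent phase (hence the duty cycle).
    """

    g_fast: float = 2.0
    g_slow: float = 2.0
    tau_m: float = 0.3
    tau_w_min: float = 5.0
    tau_w_max: float = 50.0
    k_tw: float = 0.2
    theta_tw: float = 0.16
    fast_shape: float = 0.3
    v_mid: float = 0.0
    v_scale: float = 0.28
    theta_slow: float = 0.16
    k_slow: float = 0.1
    w_floor: float = -0.425

    def __post_init__(self) -> None:
        if not (self.tau_w_min > 0 and self.tau_w_max > self.tau_w_min):
            raise ValueError("require 0 < tau_w_min < tau_w_max")
        if self.g_fast <= 0 or self.g_slow <= 0:
            raise ValueError("conductance scales must be positive")
        if self.tau_m <= 0 or self.k_tw <= 0 or self.k_slow <= 0:
            raise ValueError("time/rate constants must be positive")
        if self.v_scale <= 0:
            raise ValueError("v_scale must be positive")

    @property
    def fast_amplitude(self) -> float:
        """Amplitude ``g_fast * fast_shape`` of the cubic fast current."""
        return self.g_fast * self.fast_shape

    @property
    def knee_w(self) -> float:
        """|W| of the free V-nullcline knees (at ``V = v_mid -+ v_scale``)."""
        return 2.0 / 3.0 * self.fast_amplitude

    def replace(self, **kw) -> "CellParams":
        return replace(self, **kw)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SynParams:
    """Graded chemical synapse of the reciprocal-excitation comparison network.

    The synaptic current is written in an outward-positive convention,
    ``I_syn = g_syn * s(-(V_pre - theta_syn)/k_syn) * (E_syn - V_post)``,
    and is subtracted in the voltage equation, so a saturated synapse
    depolarizes the postsynaptic cell by about ``g_syn * |E_syn|``.
    """

    g_syn: float = 0.05
    E_syn: float = -4.0
    theta_syn: float = 0.0
    k_syn: float = 0.02

    def __post_init__(self) -> None:
        if self.g_syn < 0:
            raise ValueError("g_syn must be non-negative")
        if self.k_syn <= 0:
            raise ValueError("k_syn must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Piecewise-constant Gaussian current noise.

    An independent N(0, sigma^2) current is drawn for every cell at the start
    of each ``update_dt`` interval and held constant until the next redraw.
    """

    sigma: float = 0.002
    update_dt: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.update_dt <= 0:
            raise ValueError("update_dt must be positive")


@dataclass(frozen=True)
class StimulusSpec:
    """A transient current pulse delivered to a set of cells.

    ``amplitudes`` holds one signed amplitude per target cell (by default the
    switching protocol uses +1 / -1).  ``n_repeats`` delivers the pulse in
    immediately successive ``duration``-long attempts.
    """

    cells: tuple = ()
    amplitudes: tuple = ()
    onset: float = 0.0
    duration: float = 0.2
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if len(self.cells) != len(self.amplitudes):
            raise ValueError("cells and amplitudes must have equal length")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def offset(self) -> float:
        return self.onset + self.duration * self.n_repeats


DEFAULT_CELL = CellParams()
DEFAULT_SYN = SynParams()
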