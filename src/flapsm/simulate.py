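"""Synthetic-data generator for flap-DNA FRET/PIFE experiments.

Emulates the statistical structure of the measurements the analysis
modules consume:

* two-state Markov (telegraph) conformational switching with distinct
  FRET efficiencies per state, sampled exactly (Gillespie);
* TIRF-style rendering of donor/acceptor photon counts with frame
  averaging, shot noise, state-dependent donor brightness (PIFE),
  acceptor blinking and single-step photobleaching;
* real-time injection experiments with exponential binding and cleavage
  waiting times and an optional delayed clamp-departure (PIFE-loss) step;
* ensemble titration curves (Hill two-state or quadratic tight-binding)
  with replicate noise;
* right-censored exponential dwell-time samples.

Units: time in s, rates in s^-1, concentrations in nM (mM for Mg2+),
intensities in detected counts per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np
import pandas as pd

__all__ = [
    "TwoStateKinetics",
    "PhotophysicsModel",
    "InjectionScheme",
    "TitrationModel",
    "StatePath",
    "TitrationCurve",
    "DwellSample",
    "simulate_state_path",
    "render_trace",
    "simulate_injection_profile",
    "simulate_titration",
    "simulate_dwells",
    "quadratic_bound_fraction",
    "hill_fraction",
]

from flapsm.trace import IntensityTrace


def _check_rate(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a finite non-negative rate, got {value!r}")


@dataclass(frozen=True)
class TwoStateKinetics:
    """Two-state conformational exchange with per-state photophysics.

    ``k_forward`` is the state1 -> state2 rate, ``k_backward`` the
    state2 -> state1 rate.  The stationary occupancy of state 1 is
    k_backward / (k_forward + k_backward).
    """

    k_forward: float
    k_backward: float
    E_state1: float
    E_state2: float
    pife_state1: float = 1.0
    pife_state2: float = 1.0

    def __post_init__(self) -> None:
        _check_rate("k_forward", self.k_forward)
        _check_rate("k_backward", self.k_backward)
        for name in ("E_state1", "E_state2"):
            e = getattr(self, name)
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {e!r}")
        for name in ("pife_state1", "pife_state2"):
            p = getattr(self, name)
            if not p > 0:
                raise ValueError(f"{name} must be > 0, got {p!r}")

    @property
    def occupancy_state1(self) -> float:
        total = self.k_forward + self.k_backward
        if total == 0:
            raise ValueError("occupancy undefined when both rates are zero")
        return self.k_backward / total

    def efficiency(self, state: int) -> float:
        return self.E_state1 if state == 1 else self.E_state2

    def pife(self, state: int) -> float:
        return self.pife_state1 if state == 1 else self.pife_state2


@dataclass(frozen=True)
class PhotophysicsModel:
    """Detection model for TIRF rendering.

    ``total_brightness`` is the mean detected count rate per frame at
    E = 0 and pife = 1; the donor channel receives
    B * pife * (1 - E) / gamma and the acceptor B * E, plus channel
    backgrounds.  Bleaching and blinking are single-step Poisson
    processes in time.
    """

    total_brightness: float = 500.0
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    gamma: float = 1.0
    noise_model: str | tuple[str, float] = "poisson"  # "none" | "poisson" | ("gaussian", sd)
    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 0.0
    acceptor_blink_on_rate: float = 0.0   # dark -> emitting recovery rate
    acceptor_blink_off_rate: float = 0.0  # emitting -> dark rate

    def __post_init__(self) -> None:
        if self.total_brightness < 0 or self.background_donor < 0 or self.background_acceptor < 0:
            raise ValueError("brightness and backgrounds must be >= 0")
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        for name in (
            "donor_bleach_rate",
            "acceptor_bleach_rate",
            "acceptor_blink_on_rate",
            "acceptor_blink_off_rate",
        ):
            _check_rate(name, getattr(self, name))
        kind = self.noise_model[0] if isinstance(self.noise_model, tuple) else self.noise_model
        if kind not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass(frozen=True)
class InjectionScheme:
    """Real-time injection experiment: unbound substrate, then exponential
    binding, cleavage (catalysis + product release lumped into one step)
    and an optional delayed PIFE-loss (clamp departure) step."""

    t_injection: float
    k_bind: float
    k_cleave: float
    E_unbound: float
    E_bound: float
    pife_bound: float = 1.0
    p_delayed_pife_loss: float = 0.0
    k_pife_loss: float = 0.0

    def __post_init__(self) -> None:
        _check_rate("k_bind", self.k_bind)
        _check_rate("k_cleave", self.k_cleave)
        _check_rate("k_pife_loss", self.k_pife_loss)
        if not 0.0 <= self.p_delayed_pife_loss <= 1.0:
            raise ValueError("p_delayed_pife_loss must lie in [0, 1]")
        for name in ("E_unbound", "E_bound"):
            e = getattr(self, name)
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.pife_bound > 0:
            raise ValueError("pife_bound must be > 0")


@dataclass(frozen=True)
class TitrationModel:
    """Parametric titration curve.

    ``hill``: y = baseline + amplitude * x^n / (half_point^n + x^n)
    ``quadratic_binding``: y = baseline + amplitude * f_bound with the
    ligand-depletion (tight-binding) bound fraction of the labelled
    probe at total probe concentration ``probe_total``.
    """

    baseline_signal: float
    amplitude: float
    half_point: float
    hill_n: float = 1.0
    model_kind: Literal["hill", "quadratic_binding"] = "hill"
    probe_total: float | None = None

    def __post_init__(self) -> None:
        if not self.half_point > 0:
            raise ValueError("half_point must be > 0")
        if not self.hill_n > 0:
            raise ValueError("hill_n must be > 0")
        if self.model_kind == "quadratic_binding" and not (
            self.probe_total is not None and self.probe_total > 0
        ):
            raise ValueError("probe_total must be > 0 for quadratic_binding")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("concentrations must be >= 0")
        if self.model_kind == "hill":
            frac = hill_fraction(x, self.half_point, self.hill_n)
        else:
            frac = quadratic_bound_fraction(x, self.probe_total, self.half_point)
        return self.baseline_signal + self.amplitude * frac


def hill_fraction(x: np.ndarray, half_point: float, n: float) -> np.ndarray:
    """Two-state Hill saturation fraction x^n / (K^n + x^n)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        xn = np.power(x, n)
    return xn / (half_point**n + xn)


def quadratic_bound_fraction(
    titrant: np.ndarray, probe_total: float, k_d: float
) -> np.ndarray:
    """Bound fraction of the probe under ligand depletion (tight binding).

    Mass balance for P (titrant, total) binding D (probe, total) with
    dissociation constant K gives

        f = ((P + D + K) - sqrt((P + D + K)^2 - 4 P D)) / (2 D).
    """
    p = np.asarray(titrant, dtype=float)
    d = float(probe_total)
    s = p + d + k_d
    disc = np.maximum(s * s - 4.0 * p * d, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * d)


@dataclass
class StatePath:
    """Exact continuous-time two-state trajectory.

    ``entry_times[i]`` is when ``states[i]`` is entered; the final
    segment runs to ``duration``.
    """

    entry_times: np.ndarray
    states: np.ndarray
    duration: float

    @property
    def segments(self) -> list[tuple[int, float]]:
        return [(int(s), float(t)) for s, t in zip(self.states, self.entry_times)]

    def occupancy(self, state: int) -> float:
        """Fraction of total duration spent in `state`."""
        bounds = np.append(self.entry_times, self.duration)
        dwell = np.diff(bounds)
        return float(dwell[self.states == state].sum() / self.duration)

    def dwell_times(self, state: int, drop_edges: bool = True) -> np.ndarray:
        """Complete dwell times in `state`; the first and last segments are
        censored by the observation window and dropped by default."""
        bounds = np.append(self.entry_times, self.duration)
        dwell = np.diff(bounds)
        keep = self.states == state
        if drop_edges:
            edge = np.zeros_like(keep)
            edge[0] = edge[-1] = True
            keep = keep & ~edge
        return dwell[keep]


def simulate_state_path(
    kin: TwoStateKinetics,
    duration: float,
    seed: int | np.random.Generator,
    start_state: int | None = None,
) -> StatePath:
    """Exact (Gillespie) simulation of the two-state telegraph process.

    The initial state is drawn from the stationary distribution unless
    ``start_state`` is given.  Dwell times are exponential with the
    exit rate of the current state; a state with zero exit rate is
    absorbing.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    exit_rate = {1: kin.k_forward, 2: kin.k_backward}
    if start_state is None:
        if kin.k_forward + kin.k_backward == 0:
            raise ValueError(
                "both rates are zero: a start_state must be requested explicitly"
            )
        start_state = 1 if rng.random() < kin.occupancy_state1 else 2
    if start_state not in (1, 2):
        raise ValueError("start_state must be 1 or 2")

    times = [0.0]
    states = [start_state]
    t = 0.0
    s = start_state
    while True:
        rate = exit_rate[s]
        if rate == 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        s = 2 if s == 1 else 1
        times.append(t)
        states.append(s)
    return StatePath(np.asarray(times), np.asarray(states, dtype=int), float(duration))


# ---------------------------------------------------------------------------
# frame-averaged rendering


def _frame_means(
    breaks: np.ndarray, values: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Frame means of a piecewise-constant function.

    ``values[i]`` holds on [breaks[i], breaks[i+1]); breaks has one more
    entry than values.  Returns the mean over each [edges[j], edges[j+1])
    frame via the cumulative integral.
    """
    # cumulative integral at the breakpoints, then linear interpolation
    seg = np.diff(breaks)
    cum = np.concatenate([[0.0], np.cumsum(seg * values)])
    frame_int = np.diff(np.interp(edges, breaks, cum))
    return frame_int / np.diff(edges)


def _alive_fraction(edges: np.ndarray, t_off: float) -> np.ndarray:
    """Per-frame fraction of the frame preceding an off-switch at t_off."""
    return np.clip((t_off - edges[:-1]) / np.diff(edges), 0.0, 1.0)


def _apply_noise(expected: np.ndarray, phys: PhotophysicsModel, rng: np.random.Generator) -> np.ndarray:
    kind = phys.noise_model
    if kind == "none":
        return expected
    if kind == "poisson":
        return rng.poisson(np.maximum(expected, 0.0)).astype(float)
    # ("gaussian", sd)
    _, sd = kind
    return expected + rng.normal(0.0, sd, size=expected.shape)


def _render_piecewise(
    breaks: np.ndarray,
    e_vals: np.ndarray,
    pife_vals: np.ndarray,
    acceptor_on: np.ndarray,
    phys: PhotophysicsModel,
    frame_time: float,
    n_frames: int,
    rng: np.random.Generator,
    donor_bleach_time: float = np.inf,
    acceptor_bleach_time: float = np.inf,
    metadata: dict[str, Any] | None = None,
) -> IntensityTrace:
    """Render a piecewise-constant (E, pife, acceptor-present) timeline to a
    noisy frame trace, with acceptor blinking and photobleaching.

    While the FRET channel is open the donor emits B*pife*(1-E)/gamma and
    the acceptor B*E; when the acceptor is dark, bleached or cleaved away
    the transferred energy returns to the donor (donor emits B*pife/gamma).
    After donor bleach both channels drop to background.
    """
    b = phys.total_brightness
    edges = np.arange(n_frames + 1, dtype=float) * frame_time
    t_end = edges[-1]
    breaks = np.append(breaks, t_end)

    # exact frame means of the piecewise coefficients
    a_mean = _frame_means(breaks, e_vals * acceptor_on, edges)       # acceptor coeff E (when present)
    p_mean = _frame_means(breaks, pife_vals, edges)                  # pife
    q_mean = _frame_means(breaks, pife_vals * e_vals * acceptor_on, edges)  # pife*E (donor deficit)

    # acceptor blinking: telegraph between emitting (1) and dark (0)
    dark_frac = np.zeros(n_frames)
    if phys.acceptor_blink_off_rate > 0:
        blink = simulate_state_path(
            TwoStateKinetics(
                k_forward=phys.acceptor_blink_off_rate,   # emitting -> dark
                k_backward=phys.acceptor_blink_on_rate,
                E_state1=0.0,
                E_state2=0.0,
            ),
            duration=t_end,
            seed=rng,
            start_state=1,  # start emitting
        )
        bb = np.append(blink.entry_times, t_end)
        dark = (blink.states == 2).astype(float)
        dark_frac = _frame_means(bb, dark, edges)

    # single-step photobleaching (forced times override the stochastic draw)
    t_ableach = acceptor_bleach_time
    if np.isinf(t_ableach) and phys.acceptor_bleach_rate > 0:
        t_ableach = rng.exponential(1.0 / phys.acceptor_bleach_rate)
    t_dbleach = donor_bleach_time
    if np.isinf(t_dbleach) and phys.donor_bleach_rate > 0:
        t_dbleach = rng.exponential(1.0 / phys.donor_bleach_rate)

    f_a = _alive_fraction(edges, t_ableach) if np.isfinite(t_ableach) else np.ones(n_frames)
    f_d = _alive_fraction(edges, t_dbleach) if np.isfinite(t_dbleach) else np.ones(n_frames)

    # fraction of the frame with an open FRET channel (acceptor alive & bright);
    # within-frame processes are treated as independent (documented approximation)
    open_frac = f_a * (1.0 - dark_frac)
    exp_acceptor = b * a_mean * open_frac * f_d + phys.background_acceptor
    exp_donor = (b / phys.gamma) * (p_mean - q_mean * open_frac) * f_d + phys.background_donor

    donor = _apply_noise(exp_donor, phys, rng)
    acceptor = _apply_noise(exp_acceptor, phys, rng)

    meta = dict(metadata or {})
    meta.setdefault("donor_bleach_time", float(t_dbleach))
    meta.setdefault("acceptor_bleach_time", float(t_ableach))
    return IntensityTrace(
        times=edges[:-1],
        donor_counts=donor,
        acceptor_counts=acceptor,
        frame_time=frame_time,
        metadata=meta,
    )


def render_trace(
    path: StatePath,
    kin: TwoStateKinetics,
    phys: PhotophysicsModel,
    frame_time: float,
    seed: int | np.random.Generator,
    donor_bleach_time: float = np.inf,
    acceptor_bleach_time: float = np.inf,
) -> IntensityTrace:
    """Render a two-state path to a camera trace.

    Per-frame expected counts are time averages over the frame of
    I_D = B*pife(state)*(1-E(state))/gamma + bg_D and
    I_A = B*E(state) + bg_A, then noise-corrupted.  Bleaching truncates
    the relevant channel to background for all later frames; acceptor
    blinking zeroes the acceptor during dark intervals and routes the
    energy to the donor.
    """
    if not frame_time > 0:
        raise ValueError("frame_time must be > 0")
    n_frames = int(np.floor(path.duration / frame_time + 1e-9))
    if n_frames < 1:
        raise ValueError("frame_time longer than the path duration")
    rng = np.random.default_rng(seed)
    e_vals = np.where(path.states == 1, kin.E_state1, kin.E_state2)
    pife_vals = np.where(path.states == 1, kin.pife_state1, kin.pife_state2)
    return _render_piecewise(
        breaks=path.entry_times,
        e_vals=e_vals,
        pife_vals=pife_vals,
        acceptor_on=np.ones_like(e_vals),
        phys=phys,
        frame_time=frame_time,
        n_frames=n_frames,
        rng=rng,
        donor_bleach_time=donor_bleach_time,
        acceptor_bleach_time=acceptor_bleach_time,
    )


def simulate_injection_profile(
    scheme: InjectionScheme,
    phys: PhotophysicsModel,
    duration: float,
    frame_time: float,
    seed: int | np.random.Generator,
) -> IntensityTrace:
    """Simulate one real-time injection reaction profile.

    Before binding the trace follows E_unbound; binding occurs at
    t_injection + Exp(k_bind); the bound complex shows E_bound with the
    donor PIFE multiplier; cleavage (+Exp(k_cleave)) removes the acceptor
    strand; with probability p_delayed_pife_loss the PIFE multiplier
    persists for a further Exp(k_pife_loss), otherwise it drops with
    cleavage.  Ground-truth event times are stored in the metadata.
    """
    if not scheme.t_injection < duration:
        raise ValueError("t_injection must precede the end of the trace")
    rng = np.random.default_rng(seed)
    t_bind = scheme.t_injection + (
        rng.exponential(1.0 / scheme.k_bind) if scheme.k_bind > 0 else np.inf
    )
    t_cleave = t_bind + (
        rng.exponential(1.0 / scheme.k_cleave) if scheme.k_cleave > 0 else np.inf
    )
    delayed = rng.random() < scheme.p_delayed_pife_loss
    if delayed and scheme.k_pife_loss > 0:
        t_pife_loss = t_cleave + rng.exponential(1.0 / scheme.k_pife_loss)
    else:
        t_pife_loss = t_cleave

    n_frames = int(np.floor(duration / frame_time + 1e-9))
    t_end = n_frames * frame_time
    events = [t for t in (t_bind, t_cleave, t_pife_loss) if t < t_end]
    breaks = np.concatenate([[0.0], np.sort(np.unique(events))])

    def stage(t: float) -> tuple[float, float, float]:
        # (E, pife, acceptor_present) for the segment starting at t
        if t < t_bind:
            return scheme.E_unbound, 1.0, 1.0
        if t < t_cleave:
            return scheme.E_bound, scheme.pife_bound, 1.0
        if t < t_pife_loss:
            return 0.0, scheme.pife_bound, 0.0
        return 0.0, 1.0, 0.0

    vals = np.array([stage(t) for t in breaks])
    meta = {
        "t_injection": float(scheme.t_injection),
        "binding_time": float(t_bind),
        "cleavage_time": float(t_cleave),
        "pife_loss_time": float(t_pife_loss),
        "delayed_pife_loss": bool(delayed and scheme.k_pife_loss > 0),
    }
    return _render_piecewise(
        breaks=breaks,
        e_vals=vals[:, 0],
        pife_vals=vals[:, 1],
        acceptor_on=vals[:, 2],
        phys=phys,
        frame_time=frame_time,
        n_frames=n_frames,
        rng=rng,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# titrations and dwell samples


@dataclass
class TitrationCurve:
    """(concentration, signal, replicate) records for one dataset."""

    concentration: np.ndarray
    signal: np.ndarray
    replicate: np.ndarray
    dataset_id: str = "curve"
    probe_total: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration": self.concentration,
                "signal": self.signal,
                "replicate": self.replicate,
                "dataset_id": self.dataset_id,
            }
        )


def simulate_titration(
    model: TitrationModel,
    x_values: np.ndarray,
    noise_sd: float,
    replicates: int,
    seed: int | np.random.Generator,
    dataset_id: str = "curve",
    noise_mode: Literal["additive", "multiplicative"] = "additive",
) -> TitrationCurve:
    """Noisy replicate titration measurements from a parametric model.

    Gaussian noise per replicate point, either additive (sd in signal
    units) or multiplicative (sd as a fraction of the signal).
    """
    x = np.asarray(x_values, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    clean = model.evaluate(x)
    conc = np.tile(x, replicates)
    rep = np.repeat(np.arange(replicates), len(x))
    y = np.tile(clean, replicates)
    if noise_sd > 0:
        eps = rng.normal(0.0, noise_sd, size=y.shape)
        y = y * (1.0 + eps) if noise_mode == "multiplicative" else y + eps
    return TitrationCurve(
        concentration=conc,
        signal=y,
        replicate=rep,
        dataset_id=dataset_id,
        probe_total=model.probe_total,
    )


@dataclass
class DwellSample:
    """Exponential dwell times with right-censoring flags."""

    times: np.ndarray
    censored: np.ndarray
    observation_window: float

    def __len__(self) -> int:
        return len(self.times)


def simulate_dwells(
    rate: float,
    n: int,
    observation_window: float,
    seed: int | np.random.Generator,
) -> DwellSample:
    """i.i.d. Exp(rate) dwells; draws exceeding the window are reported at
    the window length and flagged censored."""
    if not rate > 0:
        raise ValueError("rate must be > 0")
    if not n > 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    raw = rng.exponential(1.0 / rate, size=n)
    censored = raw > observation_window
    times = np.where(censored, observation_window, raw)
    return DwellSample(times=times, censored=censored, observation_window=float(observation_window))
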