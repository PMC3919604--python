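"""FRET efficiency, distance and junction-geometry calculations.

Converts donor/acceptor intensities to apparent FRET efficiencies,
efficiencies to inter-dye distances through the Forster relation, applies
the PIFE (donor quantum-yield enhancement) correction, and infers the
kink angle between the two duplex arms of a branched DNA junction by the
law of cosines.

The gamma detection-correction factor defaults to 1 everywhere: the
efficiencies handled here are *apparent* efficiencies, as is standard for
single-channel-calibrated TIRF data.  Distances are in Angstrom, angles
in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ForsterPair",
    "CY3_CY5",
    "FLUORESCEIN_CY3",
    "efficiency",
    "distance_from_efficiency",
    "efficiency_from_distance",
    "pife_corrected_efficiency",
    "pife_corrected_distance",
    "donor_quench_corrected_efficiency",
    "kink_angle",
    "distance_from_angle",
    "arm_length",
]


@dataclass(frozen=True)
class ForsterPair:
    """Donor/acceptor pair characterised by its Forster radius R0 (A)."""

    R0: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.R0 > 0:
            raise ValueError("R0 must be > 0")


#: Cy3-Cy5, R0 ~ 53 A.
CY3_CY5 = ForsterPair(R0=53.0, name="Cy3-Cy5")
#: Fluorescein-Cy3; literature-typical default, a configuration choice.
FLUORESCEIN_CY3 = ForsterPair(R0=56.0, name="fluorescein-Cy3")


def efficiency(donor_counts, acceptor_counts, gamma: float = 1.0):
    """Apparent FRET efficiency E_app = I_A / (I_A + gamma * I_D).

    Accepts scalars or arrays.  Zero total signal is undefined and
    returned as NaN.
    """
    d = np.asarray(donor_counts, dtype=float)
    a = np.asarray(acceptor_counts, dtype=float)
    if np.any(d < 0) or np.any(a < 0):
        raise ValueError("counts must be >= 0")
    denom = a + gamma * d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(denom > 0, a / denom, np.nan)
    return float(e) if e.ndim == 0 else e


def distance_from_efficiency(E, pair: ForsterPair = CY3_CY5):
    """Inter-dye distance R = R0 * ((1 - E) / E)^(1/6).

    E at 0 or 1 maps to inf / 0 respectively (flagged by the caller's
    use of the open interval); values outside (0, 1) are rejected.
    """
    e = np.asarray(E, dtype=float)
    if np.any((e < 0) | (e > 1)):
        raise ValueError("E must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        r = pair.R0 * np.power((1.0 - e) / e, 1.0 / 6.0)
    return float(r) if r.ndim == 0 else r


def efficiency_from_distance(R, pair: ForsterPair = CY3_CY5):
    """Inverse of :func:`distance_from_efficiency`: E = 1 / (1 + (R/R0)^6)."""
    r = np.asarray(R, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be >= 0")
    e = 1.0 / (1.0 + np.power(r / pair.R0, 6.0))
    return float(e) if e.ndim == 0 else e


def pife_corrected_efficiency(E_app, alpha: float, gamma: float = 1.0):
    """True transfer efficiency from a raw apparent efficiency measured
    while the donor quantum yield is enhanced alpha-fold (PIFE).

    The detection-correction factor is gamma = eta_A*Phi_A / (eta_D*Phi_D),
    so an alpha-fold brighter donor lowers it to gamma' = gamma / alpha;
    with raw E computed at the unenhanced gamma,

        E_corr = I_A / (I_A + (gamma/alpha) I_D)
               = alpha E / (alpha E + (1 - E)).
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    e = np.asarray(E_app, dtype=float)
    out = alpha * e / (alpha * e + (1.0 - e))
    return float(out) if out.ndim == 0 else out


def pife_corrected_distance(
    E_app, pair: ForsterPair, alpha: float, gamma: float = 1.0
):
    """Distance from a raw apparent efficiency measured in a PIFE state.

    Two corrections compose: the detection-factor correction
    (gamma' = gamma / alpha, see :func:`pife_corrected_efficiency`) and
    the Forster-radius correction R0' = R0 * alpha^(1/6) for the
    enhanced donor quantum yield (R0^6 scales with Phi_D).  The two
    alpha factors cancel algebraically, so the ratiometric distance is
    invariant to a pure donor quantum-yield change -- the correction
    composes to the identity on intensity-ratio data, and matters only
    for efficiencies obtained by donor quenching against an unenhanced
    reference.  With alpha = 1 every step reduces to the uncorrected
    pipeline.
    """
    e_corr = pife_corrected_efficiency(E_app, alpha=alpha, gamma=gamma)
    pair_corr = ForsterPair(R0=pair.R0 * alpha ** (1.0 / 6.0), name=pair.name)
    return distance_from_efficiency(e_corr, pair_corr)


def donor_quench_corrected_efficiency(E_quench, alpha: float):
    """Transfer efficiency from a donor-quenching measurement
    (E = 1 - F_DA/F_D) whose bound-state donor is alpha-fold enhanced
    relative to the donor-only reference: E_corr = 1 - (1 - E)/alpha."""
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    e = np.asarray(E_quench, dtype=float)
    out = 1.0 - (1.0 - e) / alpha
    return float(out) if out.ndim == 0 else out


def kink_angle(L1: float, L2: float, R: float, tol: float = 1e-6) -> float:
    """Junction kink angle (degrees) from the two arm lengths and the
    inter-dye distance, by the law of cosines.

    Raises if the triangle inequality is violated beyond `tol` (relative).
    """
    if not (L1 > 0 and L2 > 0 and R >= 0):
        raise ValueError("lengths must be positive")
    slack = tol * max(L1, L2, R)
    if R > L1 + L2 + slack or R < abs(L1 - L2) - slack:
        raise ValueError(
            f"invalid geometry: R={R} outside [{abs(L1 - L2)}, {L1 + L2}]"
        )
    cos_t = np.clip((L1**2 + L2**2 - R**2) / (2.0 * L1 * L2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_t)))


def distance_from_angle(L1: float, L2: float, theta_deg: float) -> float:
    """Inverse of :func:`kink_angle`: inter-dye distance for a given kink."""
    if not (L1 > 0 and L2 > 0):
        raise ValueError("lengths must be positive")
    if not 0.0 <= theta_deg <= 180.0:
        raise ValueError("angle must lie in [0, 180] degrees")
    t = np.radians(theta_deg)
    return float(np.sqrt(L1**2 + L2**2 - 2.0 * L1 * L2 * np.cos(t)))


def arm_length(
    bp_to_dye: int,
    rise_per_bp: float = 3.4,
    stacking_offset: float = 5.0,
    linker_extra: float = 0.0,
) -> float:
    """Effective junction-to-dye arm length (A).

    Duplex rise of 3.4 A/bp times the base pairs between junction and
    label, plus a terminal stacking offset (Cy3 stacks ~5 A beyond the
    last base pair) and any free-linker extension (e.g. ~10 A for a
    fluorescein on a flexible tether).
    """
    if bp_to_dye < 0:
        raise ValueError("bp_to_dye must be >= 0")
    return rise_per_bp * bp_to_dye + stacking_offset + linker_extra
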