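"""Electromechanics of microtubule detachment under pulsed electric fields.

The model: a microtubule (MT) lying on an antibody-functionalised surface is
pulled sideways by the electrophoretic force on its net charge,
``F_E = Q_MT * E`` with ``Q_MT = L_MT * rho_MT``, and held down by its
antibody anchors, ``F_HOLD = D_AB * L_MT * F_AB``.  Because both forces are
proportional to filament length, the detachment condition reduces to a
per-unit-length balance: the MT releases once

    E * rho_MT > D_AB * F_AB

where ``rho_MT = N * Q_TUB / L_TUB`` is the linear charge density of the MT
lattice (N protofilaments, one tubulin dimer of length L_TUB carrying an
effective charge of magnitude Q_TUB), ``D_AB`` is the number of antibody
anchors per micron of MT length and ``F_AB`` the rupture force of a single
antibody-MT bond.  Solving the balance for ``D_AB`` converts an observed
detachment field into an anchoring density and vice versa.

The module also provides the linear voltage-to-field calibration of the
on-chip electrode gap (anchored at 25 kV/cm for a 300 V pulse), a parametric
spatial field profile across the gap, pulse-train timing/duty arithmetic,
the ideal-rectangular-pulse voltage spectral density, and Debye screening
length for the electrolyte.

Sign convention: tubulin is net negative, so MTs migrate toward the anode.
All force/charge computations here use magnitudes; migration polarity is a
separate flag consumed by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, InvalidProtocolError

__all__ = [
    "ELEMENTARY_CHARGE",
    "BOLTZMANN",
    "AVOGADRO",
    "VACUUM_PERMITTIVITY",
    "FieldCalibration",
    "MicrotubuleCharge",
    "BindingModel",
    "PulseProtocol",
    "field_from_voltage",
    "mt_linear_charge_density",
    "electric_force_per_length",
    "antibody_linear_density_at_detachment",
    "areal_to_linear_antibody_density",
    "ionic_strength",
    "debye_length",
    "pulse_train_summary",
    "pulse_spectral_density",
]

# CODATA 2018 exact/recommended values.
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

KV_PER_CM_TO_V_PER_M = 1e5


@dataclass(frozen=True)
class FieldCalibration:
    """Linear map from applied pulse voltage to field strength at the MT plane.

    The reference point (300 V -> 25 kV/cm) comes from a finite-element
    simulation of the chip cross-section; the field scales linearly with
    voltage.  The spatial profile is parametric: a plateau of the calibrated
    strength across the electrode gap, decaying exponentially beyond both
    electrode edges with a configurable length scale (of the order of the
    channel height).

    Parameters
    ----------
    reference_voltage : float
        Anchor voltage of the calibration, V.
    reference_field : float
        Field strength at the MT plane for the anchor voltage, kV/cm.
    gap_width_um : float
        Width of the electrode gap, µm.
    gap_start_um : float
        Lab-frame x coordinate (µm) of the cathode-side electrode edge; the
        plateau spans ``[gap_start_um, gap_start_um + gap_width_um]``.
    decay_length_um : float
        Exponential decay length of the field beyond the electrode edges, µm.
    """

    reference_voltage: float = 300.0
    reference_field: float = 25.0
    gap_width_um: float = 60.0
    gap_start_um: float = 0.0
    decay_length_um: float = 50.0

    def __post_init__(self) -> None:
        if self.reference_voltage <= 0 or self.reference_field <= 0:
            raise InvalidParameterError("calibration reference values must be > 0")
        if self.gap_width_um <= 0 or self.decay_length_um <= 0:
            raise InvalidParameterError("gap width and decay length must be > 0")

    def field_at(self, voltage: float) -> float:
        """Plateau field strength (kV/cm) for an applied voltage."""
        return field_from_voltage(voltage, self)

    def field_profile(self, x_um, voltage: float):
        """Field strength (kV/cm) at lab-frame position(s) ``x_um`` along the gap axis.

        Plateau inside the gap; exponential decay with ``decay_length_um``
        beyond either electrode edge.  Accepts scalars or arrays.
        """
        x = np.asarray(x_um, dtype=float)
        e0 = self.field_at(voltage)
        lo = self.gap_start_um
        hi = self.gap_start_um + self.gap_width_um
        # distance outside the plateau (0 inside)
        outside = np.maximum(lo - x, 0.0) + np.maximum(x - hi, 0.0)
        out = e0 * np.exp(-outside / self.decay_length_um)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class MicrotubuleCharge:
    """Lattice parameters fixing the linear charge density of a microtubule.

    Defaults: 13 protofilaments, 8 nm tubulin dimer repeat, effective dimer
    charge magnitude of 23 elementary charges (net negative in solution).
    """

    n_protofilaments: int = 13
    charges_per_dimer: float = 23.0
    dimer_length_nm: float = 8.0

    def __post_init__(self) -> None:
        if self.n_protofilaments <= 0 or self.dimer_length_nm <= 0:
            raise InvalidParameterError("protofilament count and dimer length must be > 0")
        if self.charges_per_dimer < 0:
            raise InvalidParameterError("charge magnitude must be >= 0")

    @property
    def linear_charge_density(self) -> float:
        """Magnitude of the MT linear charge density, C/m."""
        return (
            self.n_protofilaments
            * self.charges_per_dimer
            * ELEMENTARY_CHARGE
            / (self.dimer_length_nm * 1e-9)
        )


@dataclass(frozen=True)
class BindingModel:
    """Antibody anchoring of a microtubule to the substrate.

    ``f_ab`` is the rupture force of a single antibody-MT bond (default
    50 pN); ``d_ab`` the number of anchors per µm of MT length.
    """

    f_ab: float = 50e-12  # N
    d_ab: float = 0.0  # anchors per µm

    def __post_init__(self) -> None:
        if self.f_ab <= 0:
            raise InvalidParameterError("antibody holding force must be > 0")
        if self.d_ab < 0:
            raise InvalidParameterError("anchor density must be >= 0")


@dataclass(frozen=True)
class PulseProtocol:
    """One pulse-train application: N rectangular pulses fired at a fixed rate."""

    amplitude_v: float
    pulse_width_s: float = 5e-6
    n_pulses: int = 100
    repetition_rate_hz: float = 10.0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_v < 0:
            raise InvalidParameterError("pulse amplitude must be >= 0")
        if self.pulse_width_s <= 0 or self.repetition_rate_hz <= 0 or self.n_pulses <= 0:
            raise InvalidParameterError("pulse width, count and repetition rate must be > 0")
        if self.pulse_width_s * self.repetition_rate_hz >= 1.0:
            raise InvalidProtocolError("duty cycle must be < 100%")

    @property
    def treatment_duration_s(self) -> float:
        """Length of the whole pulsing treatment, N / repetition rate."""
        return self.n_pulses / self.repetition_rate_hz

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + self.treatment_duration_s

    @property
    def total_on_time_s(self) -> float:
        return self.n_pulses * self.pulse_width_s

    @property
    def duty(self) -> float:
        return self.pulse_width_s * self.repetition_rate_hz

    def pulse_times(self) -> np.ndarray:
        """Start times (s) of the individual pulses."""
        return self.start_time_s + np.arange(self.n_pulses) / self.repetition_rate_hz

    def on_time_between(self, t0: float, t1: float) -> float:
        """Seconds of pulse-on time whose pulses start within ``(t0, t1]``."""
        times = self.pulse_times()
        n = int(np.count_nonzero((times > t0) & (times <= t1)))
        return n * self.pulse_width_s


def field_from_voltage(voltage: float, calibration: FieldCalibration | None = None) -> float:
    """Field strength (kV/cm) at the MT plane for an applied pulse voltage.

    Linear scaling through the calibration anchor: 300 V -> 25 kV/cm by
    default, so 210 V -> 17.5 kV/cm and 45 V -> 3.75 kV/cm.
    """
    if voltage < 0:
        raise InvalidParameterError("voltage must be >= 0")
    cal = calibration or FieldCalibration()
    return cal.reference_field * voltage / cal.reference_voltage


def mt_linear_charge_density(charge: MicrotubuleCharge | None = None) -> float:
    """Magnitude of the MT linear charge density rho_MT = N * Q_TUB / L_TUB, C/m."""
    return (charge or MicrotubuleCharge()).linear_charge_density


def electric_force_per_length(field_kv_cm: float, rho_c_per_m: float | None = None) -> float:
    """Electrophoretic force per unit MT length, N/µm, for a field in kV/cm."""
    if field_kv_cm < 0:
        raise InvalidParameterError("field strength must be >= 0")
    rho = mt_linear_charge_density() if rho_c_per_m is None else rho_c_per_m
    return field_kv_cm * KV_PER_CM_TO_V_PER_M * rho * 1e-6


def antibody_linear_density_at_detachment(
    field_kv_cm: float,
    charge: MicrotubuleCharge | None = None,
    f_ab: float = 50e-12,
) -> float:
    """Anchor density D_AB (antibodies/µm) balancing the electric force at a given field.

    From F_HOLD = F_E: ``D_AB = E * rho_MT / F_AB``.  A filament anchored more
    densely than this survives the field; one anchored less densely detaches.
    """
    if f_ab <= 0:
        raise InvalidParameterError("antibody holding force must be > 0")
    rho = mt_linear_charge_density(charge)
    return electric_force_per_length(field_kv_cm, rho) / f_ab


def areal_to_linear_antibody_density(areal_per_um2: float, mt_width_um: float = 0.025) -> float:
    """Convert an areal antibody density to anchors per µm of MT length.

    The MT footprint on the surface is its width (25 nm) times its length,
    so the linear density is simply ``areal * width``.
    """
    if areal_per_um2 < 0 or mt_width_um < 0:
        raise InvalidParameterError("densities and widths must be >= 0")
    return areal_per_um2 * mt_width_um


def ionic_strength(concentrations_mol_l, valences) -> float:
    """Ionic strength I = 1/2 * sum(c_i * z_i^2) in mol/L from ion tables."""
    c = np.asarray(concentrations_mol_l, dtype=float)
    z = np.asarray(valences, dtype=float)
    if c.shape != z.shape:
        raise InvalidParameterError("concentration and valence tables must align")
    if np.any(c < 0):
        raise InvalidParameterError("concentrations must be >= 0")
    return float(0.5 * np.sum(c * z**2))


def debye_length(
    ionic_strength_mol_l: float,
    temperature_k: float = 295.15,
    eps_r: float = 80.0,
) -> float:
    """Debye screening length of an electrolyte, in nm.

    kappa^-1 = sqrt(eps0 * eps_r * k_B * T / (2 * N_A * e^2 * I)), with I
    converted from mol/L to mol/m^3.  At I = 0.1 mol/L, 298.15 K, eps_r = 78.4
    this evaluates to ~0.96 nm, the standard reference point.
    """
    if ionic_strength_mol_l <= 0:
        raise InvalidParameterError("ionic strength must be > 0")
    if temperature_k <= 0 or eps_r <= 0:
        raise InvalidParameterError("temperature and permittivity must be > 0")
    i_si = ionic_strength_mol_l * 1000.0 * AVOGADRO  # ions/m^3 equivalent
    lam = np.sqrt(
        VACUUM_PERMITTIVITY * eps_r * BOLTZMANN * temperature_k
        / (2.0 * ELEMENTARY_CHARGE**2 * i_si)
    )
    return float(lam * 1e9)


def pulse_train_summary(protocol: PulseProtocol) -> dict:
    """Timing summary of a pulse train: treatment duration, on-time, duty."""
    return {
        "treatment_duration_s": protocol.treatment_duration_s,
        "total_on_time_s": protocol.total_on_time_s,
        "duty": protocol.duty,
    }


def pulse_spectral_density(protocol: PulseProtocol, freqs_hz) -> np.ndarray:
    """Voltage spectral density magnitude (V*s) of one ideal rectangular pulse.

    |S(f)| = V0 * tau * |sinc(f * tau)| with the normalised sinc
    sin(pi x)/(pi x); the DC value is the pulse area V0 * tau.
    """
    f = np.asarray(freqs_hz, dtype=float)
    if np.any(f < 0):
        raise InvalidParameterError("frequencies must be >= 0")
    tau = protocol.pulse_width_s
    return protocol.amplitude_v * tau * np.abs(np.sinc(f * tau))
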