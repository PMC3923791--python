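"""Canonical parameter sets and the matching circuit bias presets.

The amplitude/time-constant presets are representative nearest-spike triplet
parameter sets of the kind used to model hippocampal-culture (pairing +
triplet + quadruplet) and visual-cortex (frequency-dependent pairing + BCM)
plasticity phenomenology.  Bias presets are derived by inverting the
subthreshold mapping so that the circuit realises the same rule, with the
per-event voltage step scaled to ~0.1 V per unit fractional weight change.
"""

from __future__ import annotations

from .circuit import CircuitBiases, DeviceParams, bias_for_amplitude, bias_for_tau
from .rules import TripletParams

__all__ = [
    "HIPPOCAMPAL_PARAMS",
    "VISUAL_CORTEX_PARAMS",
    "DEFAULT_DEVICE",
    "biases_for_params",
    "hippocampal_biases",
    "visual_cortex_biases",
]

#: Minimal hippocampal-style triplet parameters (A3- = 0): fits pairing,
#: triplet and quadruplet phenomenology with one parameter set.
HIPPOCAMPAL_PARAMS = TripletParams(
    A2_plus=4.6e-3, A2_minus=3.0e-3, A3_plus=9.1e-3, A3_minus=0.0,
    tau_plus=16.8e-3, tau_minus=33.7e-3, tau_x=101e-3, tau_y=114e-3,
)

#: Minimal visual-cortex-style parameters (A2+ = A3- = 0): frequency-
#: dependent pairing and BCM-like rate behaviour.
VISUAL_CORTEX_PARAMS = TripletParams(
    A2_plus=0.0, A2_minus=8.0e-3, A3_plus=5.0e-2, A3_minus=0.0,
    tau_plus=16.8e-3, tau_minus=33.7e-3, tau_x=101e-3, tau_y=114e-3,
)

DEFAULT_DEVICE = DeviceParams()

#: Weight-voltage step (V) corresponding to one unit of fractional weight
#: change in the bias presets.
VOLTS_PER_UNIT_DW = 0.1


def biases_for_params(
    params: TripletParams,
    device: DeviceParams = DEFAULT_DEVICE,
    volts_per_unit_dw: float = VOLTS_PER_UNIT_DW,
) -> CircuitBiases:
    """Bias voltages for which the circuit realises ``params``.

    Amplitude currents are chosen so a unit-exponential event moves the
    weight node by ``amplitude * volts_per_unit_dw`` volts; time constants
    are converted to the accelerated timescale.  Zero amplitudes map to a
    grounded gate (the branch current I0 is then ~1e-15 A, i.e. off).
    """
    s = device.Cw * volts_per_unit_dw / device.pulse_width_accel  # A per unit
    a = device.time_accel

    def amp_bias(A: float) -> float:
        return bias_for_amplitude(A * s, device) if A > 0 else 0.0

    return CircuitBiases(
        V_A2p=amp_bias(params.A2_plus),
        V_A2m=amp_bias(params.A2_minus),
        V_A3p=amp_bias(params.A3_plus),
        V_A3m=amp_bias(params.A3_minus),
        V_tp=bias_for_tau(params.tau_plus / a, device.Cp_pot, device),
        V_td=bias_for_tau(params.tau_minus / a, device.Cp_dep, device),
        V_ty=bias_for_tau(params.tau_y / a, device.Cp_y, device),
        V_tx=bias_for_tau(params.tau_x / a, device.Cp_x, device),
    )


def hippocampal_biases(device: DeviceParams = DEFAULT_DEVICE) -> CircuitBiases:
    """Bias preset realising :data:`HIPPOCAMPAL_PARAMS` (minimal14 variant)."""
    return biases_for_params(HIPPOCAMPAL_PARAMS, device)


def visual_cortex_biases(device: DeviceParams = DEFAULT_DEVICE) -> CircuitBiases:
    """Bias preset realising :data:`VISUAL_CORTEX_PARAMS` (minimal13 variant)."""
    return biases_for_params(VISUAL_CORTEX_PARAMS, device)
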