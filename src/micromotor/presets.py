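"""Illustrative kinetic presets for the synthetic generator.

These constants are NOT fitted to experimental dose-response data; they are
chosen so the rate law reproduces the qualitative shapes reported for the
two propulsive enzymes: a urease-like optimum near 100 mM substrate with a
mild decline beyond it, and an acetylcholinesterase-like optimum near
0.1 mM. The speed couplings place the saturating speeds at 2.07 and
0.43 um s^-1 respectively, the reference maxima for the two enzymes.
"""

from __future__ import annotations

from .kinetics import KineticParams

__all__ = ["UREASE", "ACHE", "PRESETS"]

#: Urease-like preset: peak rate near sqrt(K_m * K_s) ~ 110 mM urea;
#: single-digit-mM competitive inhibitor constant (acetohydroxamic-acid-like).
UREASE = KineticParams(
    k_m_mM=30.0,
    k_i_mM=3.0,
    k_s_mM=400.0,
    speed_coupling_um_s=2.07,
)

#: Acetylcholinesterase-like preset: peak rate near 0.1 mM acetylcholine.
ACHE = KineticParams(
    k_m_mM=0.05,
    k_i_mM=1.0,
    k_s_mM=0.2,
    speed_coupling_um_s=0.86,
)

PRESETS: dict[str, KineticParams] = {"urease": UREASE, "ache": ACHE}
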