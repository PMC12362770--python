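"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from beadpulse import KineticsParams, SyntheticSpec


def euler_binding(params: KineticsParams, antigen0: float, t_end: float, n: int):
    """Fine-grid explicit-Euler integration of the two-step binding scheme.

    Deliberately naive (fixed step, forward Euler) so that it is independent
    of the adaptive integrator it checks.  Returns (t, captured, sandwich).
    """
    dt = t_end / n
    c = 0.0
    s = 0.0
    e = params.enhancement
    out_t = [0.0]
    out_c = [0.0]
    out_s = [0.0]
    stride = max(1, n // 1000)
    for k in range(1, n + 1):
        free = antigen0 - c - s
        cap_free = params.cap_sites - c - s
        det_free = params.det_ab - s
        flux2 = e * params.kon2 * c * det_free - params.koff2 * s
        dc = e * params.kon1 * free * cap_free - params.koff1 * c - flux2
        c += dt * dc
        s += dt * flux2
        if k % stride == 0 or k == n:
            out_t.append(k * dt)
            out_c.append(c)
            out_s.append(s)
    return np.array(out_t), np.array(out_c), np.array(out_s)


@pytest.fixture(scope="session")
def default_params() -> KineticsParams:
    return KineticsParams()


@pytest.fixture()
def sparse_clean_spec() -> SyntheticSpec:
    """Noiseless scan with well-separated pulses (isolated-event oracle)."""
    return SyntheticSpec(
        event_rate=0.25,
        noise_sd=0.0,
        contaminant_rate=0.0,
        bead_loss=0.0,
        height_cv=0.2,
        seed=42,
    )
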