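"""Independent numerical oracles used only by the test suite.

The delay-equation oracle integrates by the method of steps with scipy's
adaptive DOP853 solver and dense output for the delayed lookup; it shares
no code with the package's fixed-step integrator.
"""

from __future__ import annotations

from scipy.integrate import solve_ivp

from sappa.core import OscillatorParams, StimulusSpec, sappa_derivative, stimulus_input


def dde_method_of_steps(
    params: OscillatorParams,
    spec: StimulusSpec,
    duration: float,
    z0: complex = 1 + 0j,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> complex:
    """Terminal state z(duration) via method-of-steps adaptive integration."""
    tau = params.tau
    segments: list[tuple[float, float, object]] = []

    def z_delayed(t: float) -> complex:
        td = t - tau
        if td <= 1e-12:
            return z0
        for a, b, sol in segments:
            if a - 1e-9 <= td <= b + 1e-9:
                y = sol(min(max(td, a), b))
                return complex(y[0], y[1])
        raise RuntimeError(f"delayed lookup outside solved segments: t-tau={td}")

    def rhs(t, y):
        z = complex(y[0], y[1])
        F = stimulus_input(t, spec, z, params.A)
        dz = sappa_derivative(z, z_delayed(t) if tau > 0 else z, F, params)
        return [dz.real, dz.imag]

    t0, y0 = 0.0, [z0.real, z0.imag]
    while t0 < duration - 1e-12:
        t1 = min(t0 + tau, duration) if tau > 0 else duration
        sol = solve_ivp(
            rhs, (t0, t1), y0, method="DOP853", rtol=rtol, atol=atol, dense_output=True
        )
        assert sol.success
        segments.append((t0, t1, sol.sol))
        y0 = sol.y[:, -1]
        t0 = t1
    return complex(y0[0], y0[1])
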