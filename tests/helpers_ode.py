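"""Shared independent oracle: numerical ODE integration of the mammillary model."""

import numpy as np
from scipy.integrate import solve_ivp

from cefpk import PKParameters


def ode_concentration(params: PKParameters, dose: float, t: float) -> float:
    """Central concentration after a bolus, by stiff numerical integration."""
    K = params.n_compartments
    k10 = params.cl / params.vc

    def rhs(_, a):
        da = np.zeros(K)
        da[0] = -k10 * a[0]
        for m in range(K - 1):
            k1m = params.q[m] / params.vc
            km1 = params.q[m] / params.vp[m]
            da[0] += -k1m * a[0] + km1 * a[m + 1]
            da[m + 1] = k1m * a[0] - km1 * a[m + 1]
        return da

    a0 = np.zeros(K)
    a0[0] = dose
    sol = solve_ivp(rhs, (0.0, t), a0, method="LSODA", rtol=1e-11, atol=1e-12,
                    t_eval=[t])
    return sol.y[0, -1] / params.vc
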