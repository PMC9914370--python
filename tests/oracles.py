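"""Independent reference implementations used only to cross-check the package.

These are deliberately written in a naive, term-by-term style directly from
the model equations, sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def rhs_reference(state, p: dict, s: float, u: float,
                  cd8_self_renewal: bool = False) -> list[float]:
    """Term-by-term per-day rates of the nine compartments.

    ``p`` is a plain dict of parameter values; ``s`` and ``u`` are the
    effective therapy controls at the evaluation time.
    """
    Tu, Ti, V, X, Y, C, W, Z, N = [max(v, 0.0) for v in state]

    logistic_u = p["r_u"] * Tu * (1.0 - (Tu + Ti) / p["K_t"])
    infection = p["beta_t"] * Tu / (p["m_v"] + Tu) * V
    cytokine_kill_u = p["delta_c"] * Tu / (p["m_t"] + Tu) * C
    cd8_kill_u = p["delta_x"] * X / (p["m_x"] + X) * Tu
    nk_kill_u = p["d_u"] * N * Tu
    dTu = logistic_u - infection - cytokine_kill_u - cd8_kill_u - nk_kill_u

    logistic_i = p["r_i"] * Ti * (1.0 - (Tu + Ti) / p["K_t"])
    lysis = p["a_t"] * Ti
    cd8_kill_i = p["delta_x"] * X / (p["m_x"] + X) * Ti
    cytokine_kill_i = p["delta_c"] * Ti / (p["m_t"] + Ti) * C
    antiviral_kill = p["delta_z"] * Z * Ti
    nk_kill_i = p["d_i"] * N * Ti
    dTi = (logistic_i + infection - lysis - cd8_kill_i - cytokine_kill_i
           - antiviral_kill - nk_kill_i)

    burst = p["b_t"] * p["a_t"] * Ti
    dV = burst - p["delta_v"] * V * Z - p["gamma_v"] * V - p["d_v"] * N * V + s

    recruit = p["a_v"] * N * V
    antigen = p["a_x"] * (Ti + Tu) / (p["h_x"] + Ti + Tu)
    if cd8_self_renewal:
        antigen = antigen * X
    dX = recruit + antigen - p["gamma_x"] * X

    inhib = 1.0 + p["nu"] * W
    dY = (p["a_v"] * N * V / inhib
          + p["a_y"] * (Ti + Tu) / ((p["h_y"] + Ti + Tu) * inhib) * C
          - p["gamma_y"] * Y)

    dC = (p["alpha_n"] * (Ti + Tu) / (1.0 + p["b_n"] * W) * N
          + p["alpha_x"] * (Ti + Tu) / (1.0 + p["b_x"] * W) * X
          + p["alpha_y"] * (Ti + Tu) / (1.0 + p["b_y"] * W) * Y
          - p["gamma_c"] * C)

    dW = p["r_x"] * (1.0 - u) * X + p["r_y"] * (1.0 - u) * Y - p["gamma_w"] * W
    dZ = p["p_v"] * Ti - p["gamma_z"] * Z

    recruit_icd = (p["r_n"] * N * (1.0 - N / p["K_n"]) * (Ti / (Ti + p["m_n"])))
    stim_ifng = p["zeta"] * C * N / (C + p["h_n"])
    dN = (p["s_n"] + recruit_icd + stim_ifng
          - p["delta_n"] * (Tu + Ti) * N - p["gamma_n"] * N)

    return [dTu, dTi, dV, dX, dY, dC, dW, dZ, dN]


def prcc_via_corr_inverse(samples: np.ndarray, outputs: np.ndarray) -> np.ndarray:
    """Partial rank correlation via inversion of the rank correlation matrix.

    Returns one coefficient per column of ``samples`` (the partial
    correlation of that column with ``outputs`` given all other columns).
    """
    ranks = np.column_stack(
        [rankdata(samples[:, j]) for j in range(samples.shape[1])]
        + [rankdata(outputs)]
    )
    corr = np.corrcoef(ranks, rowvar=False)
    precision = np.linalg.inv(corr)
    k = samples.shape[1]
    return np.array([
        -precision[j, k] / np.sqrt(precision[j, j] * precision[k, k])
        for j in range(k)
    ])
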