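"""Independent oracles used by the test suite.

Everything here is written directly from the model equations, term by
term, without touching the package's reaction-list compiler — so tests
comparing the two paths genuinely cross-check the implementation.
"""

import numpy as np

# state order must match her2traffic.network.RECEPTOR_SPECIES + (T, A)


def rhs_model_a_oracle(state, params, s_on_T, s_on_A):
    """Hand-coded right-hand side of the single-population model."""
    Nm, Ni, NmT, NiT, NmA, NmTA, NiA, NiTA, T, A = state
    r = params.elementary_rates()
    k_prod, k_int, k_rec, k_deg = (r["k_prod"], r["k_int"],
                                   r["k_rec"], r["k_deg"])
    k_act, k_diss = r["k_act"], r["k_diss"]
    k_int_T, k_rec_T, k_deg_T = r["k_int_T"], r["k_rec_T"], r["k_deg_T"]
    k_on, k_off = r["k_on"], r["k_off"]
    Te = T * s_on_T
    Ae = A * s_on_A

    dNm = (k_prod - k_act * Nm * Te + k_diss * NmT - k_int * Nm
           + k_rec * Ni - k_on * Ae * Nm + k_off * NmA)
    dNi = (k_diss * NiT + k_int * Nm - k_rec * Ni - k_deg * Ni
           + k_off * NiA)
    dNmT = (k_act * Nm * Te - k_diss * NmT - k_int_T * NmT
            + k_rec_T * NiT - k_on * Ae * NmT + k_off * NmTA)
    dNiT = (-k_diss * NiT + k_int_T * NmT - k_rec_T * NiT
            - k_deg_T * NiT + k_off * NiTA)
    dNmA = (-k_act * NmA * Te + k_diss * NmTA - k_int * NmA
            + k_rec * NiA + k_on * Ae * Nm - k_off * NmA)
    dNmTA = (k_act * NmA * Te - k_diss * NmTA - k_int_T * NmTA
             + k_rec_T * NiTA + k_on * Ae * NmT - k_off * NmTA)
    dNiA = (k_diss * NiTA + k_int * NmA - k_rec * NiA - k_deg * NiA
            - k_off * NiA)
    dNiTA = (-k_diss * NiTA + k_int_T * NmTA - k_rec_T * NiTA
             - k_deg_T * NiTA - k_off * NiTA)
    dT = s_on_T * (-k_act * NmA * Te + k_diss * NmTA
                   - k_act * Nm * Te + k_diss * NmT)
    dA = s_on_A * (-k_on * Ae * Nm + k_off * NmA
                   - k_on * Ae * NmT + k_off * NmTA)
    return np.array([dNm, dNi, dNmT, dNiT, dNmA, dNmTA, dNiA, dNiTA,
                     dT, dA])


def _region_block(m, i, mT, iT, mA, mTA, iA, iTA, Te, Ae,
                  k_act, k_diss, k_int, k_rec, k_deg, k_on, k_off):
    """One membrane region of the two-region model, written out."""
    dm = (-k_act * m * Te + k_diss * mT - k_on * Ae * m + k_off * mA)
    di = k_diss * iT + k_off * iA
    dmT = (k_act * m * Te - k_diss * mT - k_int * mT + k_rec * iT
           - k_on * Ae * mT + k_off * mTA)
    diT = (-k_diss * iT + k_int * mT - k_rec * iT - k_deg * iT
           + k_off * iTA)
    dmA = (-k_act * mA * Te + k_diss * mTA + k_on * Ae * m - k_off * mA)
    dmTA = (k_act * mA * Te - k_diss * mTA - k_int * mTA + k_rec * iTA
            + k_on * Ae * mT - k_off * mTA)
    diA = k_diss * iTA - k_off * iA
    diTA = (-k_diss * iTA + k_int * mTA - k_rec * iTA - k_deg * iTA
            - k_off * iTA)
    dT_contrib = -k_act * m * Te + k_diss * mT \
        - k_act * mA * Te + k_diss * mTA
    dA_contrib = -k_on * Ae * m + k_off * mA \
        - k_on * Ae * mT + k_off * mTA
    return (dm, di, dmT, diT, dmA, dmTA, diA, diTA,
            dT_contrib, dA_contrib)


def rhs_model_b_oracle(state, params, s_on_T, s_on_A):
    """Hand-coded right-hand side of the two-region model."""
    (NR, NiR, NRT, NiRT, NRA, NRTA, NiRA, NiRTA,
     NF, NiF, NFT, NiFT, NFA, NFTA, NiFA, NiFTA, T, A) = state
    r = params.elementary_rates()
    Te, Ae = T * s_on_T, A * s_on_A
    ruff = _region_block(NR, NiR, NRT, NiRT, NRA, NRTA, NiRA, NiRTA,
                         Te, Ae, r["k_act_R"], r["k_diss"], r["k_int_RT"],
                         r["k_rec_RT"], r["k_deg_RT"], r["k_on"], r["k_off"])
    flat = _region_block(NF, NiF, NFT, NiFT, NFA, NFTA, NiFA, NiFTA,
                         Te, Ae, r["k_act_F"], r["k_diss"], r["k_int_FT"],
                         r["k_rec_FT"], r["k_deg_FT"], r["k_on"], r["k_off"])
    dT = s_on_T * (ruff[8] + flat[8])
    dA = s_on_A * (ruff[9] + flat[9])
    return np.array(list(ruff[:8]) + list(flat[:8]) + [dT, dA])


def linear_two_state_solution(a, d, ki, x0, t):
    """Closed-form eigen-decomposition solution of the flat subsystem.

    dM/dt = -a M + d B;  dB/dt = a M - (d + ki) B  (B = drug-bound
    membrane, internalization rate ki); returns (M(t), B(t), internal(t)).
    """
    A = np.array([[-a, d], [a, -(d + ki)]])
    w, V = np.linalg.eig(A)
    c = np.linalg.solve(V, np.asarray(x0, dtype=float))
    out = np.array([(V @ (c * np.exp(w * tt))).real for tt in np.atleast_1d(t)])
    internal = (x0[0] + x0[1]) - out.sum(axis=1)
    return out[:, 0], out[:, 1], internal


def gaussian_profile_ci(theta_hat, covariance, j, threshold=3.841458820694124):
    """Exact profile interval for a quadratic cost: hat +- sqrt(q) * se."""
    se = np.sqrt(covariance[j, j])
    half = np.sqrt(threshold) * se
    return theta_hat[j] - half, theta_hat[j] + half
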