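"""Independent second transcription of the seven governing equations.

Deliberately written in a different style from the package implementation
(scalar math, explicit intermediate named terms, no shared helpers) so that
agreement between the two is a genuine double-entry check of the
transcription, not of one code path against itself.
"""

import math


def oracle_derivatives(state, p):
    """state: length-7 sequence (N_CB, N_PB, N_SB, S_O, S_R, O, P);
    p: ModelParameters. Returns a 7-tuple of time derivatives."""
    N_CB, N_PB, N_SB, S_O, S_R, O, P = [float(v) for v in state]

    # growth functions: Monod, multiplicative for two limiting substrates
    g_CB = p.g_max_CB * P / (p.K_CB_P + P)
    g_PB = p.g_max_PB * (P / (p.K_PB_P + P)) * (S_R / (p.K_PB_SR + S_R))
    g_SB = p.g_max_SB * (P / (p.K_SB_P + P)) * (S_O / (p.K_SB_SO + S_O))

    # Haldane inhibition: sulfide on CB, oxygen on PB and SB
    h_CB = 1.0 / (1.0 + S_R / p.H_CB_SR)
    h_PB = 1.0 / (1.0 + O / p.H_PB_O)
    h_SB = 1.0 / (1.0 + O / p.H_SB_O)

    dN_CB = g_CB * h_CB * N_CB - p.m_CB * N_CB
    dN_PB = g_PB * h_PB * N_PB - p.m_PB * N_PB
    dN_SB = g_SB * h_SB * N_SB - p.m_SB * N_SB

    dS_O = (
        (1.0 / p.y_PB_S) * g_PB * h_PB * N_PB
        - (1.0 / p.y_SB_S) * g_SB * h_SB * N_SB
        + p.c * O * S_R
        + p.alpha_S * (p.S_O_b - S_O)
    )
    dS_R = (
        -(1.0 / p.y_PB_S) * g_PB * h_PB * N_PB
        + (1.0 / p.y_SB_S) * g_SB * h_SB * N_SB
        - p.c * O * S_R
        + p.alpha_S * (p.S_R_b - S_R)
    )
    dO = (
        p.p_CB * g_CB * h_CB * N_CB
        - p.c * O * S_R
        + p.alpha_O * (p.O_b - O)
    )
    dP = (
        -(1.0 / p.y_CB_P) * g_CB * h_CB * N_CB
        - (1.0 / p.y_PB_P) * g_PB * h_PB * N_PB
        - (1.0 / p.y_SB_P) * g_SB * h_SB * N_SB
        + p.alpha_P * (p.P_b - P)
    )
    return (dN_CB, dN_PB, dN_SB, dS_O, dS_R, dO, dP)
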