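"""Independent monolithic transcription of the model right-hand side.

Written term by term from the flux definitions, deliberately without
reusing any package internals beyond plain parameter access, so it can
serve as a brute-force oracle for the modular implementation.
"""

import math

import numpy as np


def oracle_rhs(t, y, p, uE=0.0, uH=0.0, uC=0.0, uI=0.0, temperature=37.0,
               immuno_boost=1.0, alpha=1.0, resistance_multiplier=1.0,
               drug_input=0.0, theta_t=0.1):
    y = np.maximum(np.asarray(y, dtype=float), 1e-6)
    N1, N2, I1, I2, P, A, Q, R1, R2, S, D, Dm, G, M, H = y
    G = min(G, 1.0)

    total = N1 + N2 + Q + R1 + R2 + S
    K = p.carrying_capacity
    ccf = max(0.0, 1.0 - total / K)
    growth_factor = ccf * (1.0 + 0.2 * M)
    acidosis = 1.0 + p.acidosis_factor * M * (total / K)
    hf = max(0.0, total / K - p.hypoxia_threshold) / (1.0 - p.hypoxia_threshold)
    ikf = 1.0 / (1.0 + 0.5 * hf)
    qf = 1.0 + 0.5 * hf

    if p.circadian_enabled:
        cf = 1.0 + p.circadian_amplitude * math.sin(
            2 * math.pi * (t / p.circadian_period - p.circadian_phase))
    else:
        cf = 1.0
    lam1, lam2 = p.lambda1 * cf, p.lambda2 * cf
    beta1, delta_i = p.beta1 * cf, p.delta_i * cf

    therapy = (p.eta_e * uE + p.eta_h * uH + p.eta_c * uC) * (
        1.0 + theta_t * max(0.0, temperature - 37.0))
    rdf = 1.0 + (1.0 - G)
    gdr = p.mutation_rate * p.genetic_instability * (1.0 + therapy + 0.5 * hf)

    sat = 1.0 + 0.01 * total
    growth_n1 = lam1 * N1 * growth_factor / acidosis
    growth_n2 = lam2 * N2 * growth_factor / acidosis
    growth_r1 = p.lambda_r1 * R1 * growth_factor / acidosis
    growth_r2 = p.lambda_r2 * R2 * growth_factor / acidosis
    ik_n1 = beta1 * N1 * I1 * ikf / sat
    ik_n2 = beta1 * N2 * I1 * 0.5 * ikf / sat
    ik_r1 = beta1 * R1 * I1 * p.immune_resist_factor1 * ikf / sat
    ik_r2 = beta1 * R2 * I1 * p.immune_resist_factor2 * ikf / sat
    rdev1 = max(p.omega_r1 * resistance_multiplier * therapy * N1 * rdf, 0.0)
    rdev2 = max(p.omega_r2 * resistance_multiplier * therapy * N1 * rdf, 0.0)
    qi1 = p.kappa_q * N1 * qf
    qi2 = p.kappa_q * N2 * qf
    qre = p.lambda_q * Q / qf
    sen = p.kappa_s * therapy * N1 * (1.0 + 0.3 * (1.0 - G))
    adj = p.elimination_rate * p.liver_function * p.kidney_function

    d = np.array([
        growth_n1 - ik_n1 * immuno_boost - therapy * N1 - qi1 - rdev1 - rdev2 - sen,
        growth_n2 - ik_n2 * immuno_boost - 0.5 * therapy * N2 - qi2,
        (p.phi1 + p.phi2 * total / sat) - p.beta2 * I1 * I2 / (1.0 + I1)
        - delta_i * I1 + 0.1 * uI * I1,
        p.phi3 * total / sat - delta_i * I2 - 0.1 * uI * I2,
        p.gamma_met * total / (1.0 + 0.5 * hf) - p.delta_p * P,
        p.alpha_a * total / sat - p.delta_a * A,
        qi1 + qi2 - qre,
        rdev1 + growth_r1 - ik_r1 * immuno_boost,
        rdev2 + growth_r2 - ik_r2 * immuno_boost,
        sen - p.delta_s * S,
        drug_input - adj * D,
        adj * D,
        -gdr * G + 0.001 * (1.0 - G),
        M * hf * p.metabolic_switch_rate - 0.05 * M,
        0.1 * hf - 0.1 * A * H,
    ])
    if t <= 0:
        gamma = 1.0
    else:
        gamma = 0.01 * (1.0 + (1.0 - alpha) * min(t ** (-alpha), 100.0))
    return d * gamma
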