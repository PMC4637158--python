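"""Bondarenko et al. mouse left-ventricular (apex) membrane kinetics.

A hand port of the 2004 mouse ventricular myocyte model: 41 differential
variables (transmembrane voltage plus a 40-component state vector η),
15 transmembrane currents, with the fast Na+ channel, the L-type Ca2+
channel, the rapid delayed rectifier and the ryanodine receptor
represented as Markov chains.  Calcium handling comprises a dyadic
subspace, junctional and network SR compartments, SERCA uptake,
calmodulin/calsequestrin buffering and troponin binding.

Units follow the source publication: mV, ms, μM, currents in pA/pF.
The stiff Markov-chain kinetics demand the explicit-Euler substep
Δt_o = 0.0001 ms used throughout the tissue solvers.

Markov-chain occupancy is conserved structurally: one state of each
chain is the algebraic complement of the others, and every transition
appears once with each sign across the chain equations (checked by the
positivity/boundedness tests over long integrations).

The resting state stored here was obtained by integrating the model
quiescently (no stimulus) for 1000 ms from the published initial
conditions and is itself a fixed point to well below 1e-4 mV/ms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .base import IonicModel

__all__ = ["BondarenkoModel", "STATE_NAMES", "MARKOV_CHAINS"]

# --- geometry / physical constants -----------------------------------------
ACAP = 1.534e-4     # capacitive membrane area, cm^2
CM = 1.0            # specific capacitance, μF/cm^2
VMYO = 25.84e-6     # bulk myoplasm volume, μL
VJSR = 0.12e-6      # junctional SR volume, μL
VNSR = 2.098e-6     # network SR volume, μL
VSS = 1.485e-9      # dyadic subspace volume, μL
FARADAY = 96.5      # C/mmol
RTF = 8.314 * 298.0 / 96.5   # mV

KO = 5400.0         # μM
NAO = 140000.0
CAO = 1800.0

# --- calcium handling -------------------------------------------------------
LTRPN_TOT = 70.0
HTRPN_TOT = 140.0
KP_HTRPN = 0.00237
KM_HTRPN = 3.2e-5
KP_LTRPN = 0.0327
KM_LTRPN = 0.0196
CMDN_TOT = 50.0
KM_CMDN = 0.238
CSQN_TOT = 15000.0
KM_CSQN = 800.0
V1_RYR = 4.5        # ms^-1, RyR release
V2_LEAK = 1.74e-5   # ms^-1, SR leak
V3_UP = 0.45        # μM/ms, SERCA
KM_UP = 0.5
TAU_TR = 20.0
TAU_XFER = 8.0
KA_P = 0.006075     # μM^-4 ms^-1
KA_M = 0.07125
KB_P = 0.00405      # μM^-3 ms^-1
KB_M = 0.965
KC_P = 0.009
KC_M = 0.0008

# --- sarcolemmal currents ---------------------------------------------------
GCAL = 0.1729
ECAL = 63.0
KPC_MAX = 0.23324
KPC_HALF = 20.0
KPCB = 0.0005
ICAL_MAX = 7.0
IPCA_MAX = 1.0
KM_PCA = 0.5
KNACA = 292.8
KMNA_NACA = 87500.0
KMCA_NACA = 1380.0
KSAT = 0.1
ETA_NACA = 0.35
GCAB = 0.000367
GNA = 13.0
GNAB = 0.0026
INAK_MAX = 0.88
KM_NAI = 21000.0
KM_KO = 1500.0
GKTOF = 0.4067      # apex
GKTOS = 0.0         # apex (septum only)
GKS = 0.00575
GKUR = 0.16
GKSS = 0.05
GKR = 0.078
KF_KR = 0.023761
KB_KR = 0.036778
GCLCA = 10.0
KM_CL = 10.0
ECL = -40.0

STATE_NAMES = (
    "Cai", "Cass", "CaJSR", "CaNSR", "P_RyR", "LTRPN_Ca", "HTRPN_Ca",
    "P_O1", "P_O2", "P_C2",
    "O_CaL", "C2_CaL", "C3_CaL", "C4_CaL", "I1_CaL", "I2_CaL", "I3_CaL",
    "Nai",
    "C_Na2", "C_Na1", "O_Na", "IF_Na", "I1_Na", "I2_Na", "IC_Na2", "IC_Na3",
    "Ki",
    "ato_f", "ito_f", "ato_s", "ito_s",
    "nKs", "aur", "iur", "aKss", "iKss",
    "C_K1", "C_K2", "O_K", "I_K",
)

# explicit states of each Markov chain; the named complement closes it
MARKOV_CHAINS = {
    "RyR": {"states": (7, 8, 9), "complement": "P_C1"},
    "CaL": {"states": (10, 11, 12, 13, 14, 15, 16), "complement": "C1_CaL"},
    "Na": {"states": (18, 19, 20, 21, 22, 23, 24, 25), "complement": "C_Na3"},
    "Kr": {"states": (36, 37, 38, 39), "complement": "C_K0"},
}

# Published initial conditions (quiescent myocyte); the class below
# relaxes them further, see module docstring.
_INIT_SEED = np.array([
    0.115001, 0.115001, 1299.5, 1299.5, 0.0, 11.2684, 125.29,
    1.49102e-5, 9.51726e-11, 1.6774e-4,
    9.30308e-19, 1.24216e-4, 5.78679e-9, 1.19816e-13, 4.97923e-19,
    3.45847e-14, 1.85106e-14,
    14237.1,
    0.020752, 2.79132e-4, 7.13483e-7, 1.53176e-4, 6.73345e-7,
    1.55787e-9, 0.0113879, 0.34278,
    143720.0,
    2.65563e-3, 0.999977, 4.17069e-4, 0.998543,
    2.62753e-4, 4.17069e-4, 0.998543, 4.17069e-4, 1.0,
    9.92513e-4, 6.41229e-4, 1.75298e-4, 3.19129e-5,
])
_V_SEED = -82.4202


@njit(cache=True)
def _rhs(V, s, d, I_stim):
    """Fill d (dη/dt) for one cell; return dV/dt (mV/ms)."""
    Cai = s[0]; Cass = s[1]; CaJSR = s[2]; CaNSR = s[3]
    PRyR = s[4]; LTRPN = s[5]; HTRPN = s[6]
    PO1 = s[7]; PO2 = s[8]; PC2 = s[9]
    OCa = s[10]; C2c = s[11]; C3c = s[12]; C4c = s[13]
    I1c = s[14]; I2c = s[15]; I3c = s[16]
    Nai = s[17]
    CNa2 = s[18]; CNa1 = s[19]; ONa = s[20]; IFNa = s[21]
    I1Na = s[22]; I2Na = s[23]; ICNa2 = s[24]; ICNa3 = s[25]
    Ki = s[26]
    atof = s[27]; itof = s[28]; atos = s[29]; itos = s[30]
    nKs = s[31]; aur = s[32]; iur = s[33]; aKss = s[34]; iKss = s[35]
    CK1 = s[36]; CK2 = s[37]; OK = s[38]; IK = s[39]

    # reversal potentials
    ENa = RTF * np.log((0.9 * NAO + 0.1 * KO) / (0.9 * Nai + 0.1 * Ki))
    EK = RTF * np.log(KO / Ki)
    ECaN = 0.5 * RTF * np.log(CAO / Cai)
    VFRT = V / RTF

    # membrane currents (pA/pF)
    ICaL = GCAL * OCa * (V - ECAL)
    IpCa = IPCA_MAX * Cai * Cai / (KM_PCA * KM_PCA + Cai * Cai)
    expeta = np.exp(ETA_NACA * VFRT)
    expetam = np.exp((ETA_NACA - 1.0) * VFRT)
    INaCa = (
        KNACA
        / (KMNA_NACA ** 3 + NAO ** 3) / (KMCA_NACA + CAO)
        / (1.0 + KSAT * expetam)
        * (expeta * Nai ** 3 * CAO - expetam * NAO ** 3 * Cai)
    )
    ICab = GCAB * (V - ECaN)
    INa = GNA * ONa * (V - ENa)
    INab = GNAB * (V - ENa)
    sigma_nak = (np.exp(NAO / 67300.0) - 1.0) / 7.0
    fNaK = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * VFRT) + 0.0365 * sigma_nak * np.exp(-VFRT))
    INaK = (
        INAK_MAX * fNaK / (1.0 + (KM_NAI / Nai) ** 1.5) * KO / (KO + KM_KO)
    )
    IKtof = GKTOF * atof ** 3 * itof * (V - EK)
    IKtos = GKTOS * atos * itos * (V - EK)
    IK1 = 0.2938 * KO / (KO + 210.0) * (V - EK) / (1.0 + np.exp(0.0896 * (V - EK)))
    IKs = GKS * nKs * nKs * (V - EK)
    IKur = GKUR * aur * iur * (V - EK)
    IKss = GKSS * aKss * iKss * (V - EK)
    EKr = RTF * np.log((0.98 * KO + 0.02 * NAO) / (0.98 * Ki + 0.02 * Nai))
    IKr = GKR * OK * (V - EKr)
    OClCa = 0.2 / (1.0 + np.exp(-(V - 46.7) / 7.8))
    IClCa = GCLCA * OClCa * Cai / (Cai + KM_CL) * (V - ECL)

    Iion = (
        ICaL + IpCa + INaCa + ICab + INa + INab + INaK
        + IKtof + IKtos + IK1 + IKs + IKur + IKss + IKr + IClCa
    )

    # calcium fluxes and buffering
    Bi = 1.0 / (1.0 + CMDN_TOT * KM_CMDN / ((KM_CMDN + Cai) * (KM_CMDN + Cai)))
    Bss = 1.0 / (1.0 + CMDN_TOT * KM_CMDN / ((KM_CMDN + Cass) * (KM_CMDN + Cass)))
    BJSR = 1.0 / (1.0 + CSQN_TOT * KM_CSQN / ((KM_CSQN + CaJSR) * (KM_CSQN + CaJSR)))
    Jrel = V1_RYR * (PO1 + PO2) * (CaJSR - Cass) * PRyR
    Jtr = (CaNSR - CaJSR) / TAU_TR
    Jxfer = (Cass - Cai) / TAU_XFER
    Jleak = V2_LEAK * (CaNSR - Cai)
    Jup = V3_UP * Cai * Cai / (KM_UP * KM_UP + Cai * Cai)
    dHTRPN = KP_HTRPN * Cai * (HTRPN_TOT - HTRPN) - KM_HTRPN * HTRPN
    dLTRPN = KP_LTRPN * Cai * (LTRPN_TOT - LTRPN) - KM_LTRPN * LTRPN
    Jtrpn = dHTRPN + dLTRPN

    conv_myo = ACAP * CM / (2.0 * VMYO * FARADAY)
    d[0] = Bi * (Jleak + Jxfer - Jup - Jtrpn - (ICab - 2.0 * INaCa + IpCa) * conv_myo)
    d[1] = Bss * (
        Jrel * VJSR / VSS - Jxfer * VMYO / VSS - ICaL * ACAP * CM / (2.0 * VSS * FARADAY)
    )
    d[2] = BJSR * (Jtr - Jrel)
    d[3] = (Jup - Jleak) * VMYO / VNSR - Jtr * VJSR / VNSR
    d[4] = -0.04 * PRyR - 0.1 * (ICaL / ICAL_MAX) * np.exp(-(V - 5.0) * (V - 5.0) / 648.0)
    d[5] = dLTRPN
    d[6] = dHTRPN

    # RyR Markov chain (P_C1 algebraic)
    PC1 = 1.0 - (PC2 + PO1 + PO2)
    ca4 = Cass ** 4
    ca3 = Cass ** 3
    d[7] = (
        KA_P * ca4 * PC1 - KA_M * PO1 - KB_P * ca3 * PO1 + KB_M * PO2
        - KC_P * PO1 + KC_M * PC2
    )
    d[8] = KB_P * ca3 * PO1 - KB_M * PO2
    d[9] = KC_P * PO1 - KC_M * PC2

    # L-type calcium channel Markov chain (C1 algebraic)
    alpha = (
        0.4 * np.exp((V + 12.0) / 10.0)
        * (
            1.0 + 0.7 * np.exp(-(V + 40.0) * (V + 40.0) / 10.0)
            - 0.75 * np.exp(-(V + 20.0) * (V + 20.0) / 400.0)
        )
        / (1.0 + 0.12 * np.exp((V + 12.0) / 10.0))
    )
    beta = 0.05 * np.exp(-(V + 12.0) / 13.0)
    gamma = KPC_MAX * Cass / (KPC_HALF + Cass)
    Kpcf = 13.0 * (1.0 - np.exp(-(V + 14.5) * (V + 14.5) / 100.0))
    C1c = 1.0 - (OCa + C2c + C3c + C4c + I1c + I2c + I3c)
    d[10] = (
        alpha * C4c - 4.0 * beta * OCa + KPCB * I1c - gamma * OCa
        + 0.001 * (alpha * I2c - Kpcf * OCa)
    )
    d[11] = 4.0 * alpha * C1c + 2.0 * beta * C3c - (beta + 3.0 * alpha) * C2c
    d[12] = 3.0 * alpha * C2c + 3.0 * beta * C4c - (2.0 * beta + 2.0 * alpha) * C3c
    d[13] = (
        2.0 * alpha * C3c + 4.0 * beta * OCa - (3.0 * beta + alpha) * C4c
        + 0.01 * (4.0 * KPCB * beta * I1c - alpha * gamma * C4c)
        + 0.002 * (4.0 * beta * I2c - Kpcf * C4c)
        + 4.0 * beta * KPCB * I3c - gamma * Kpcf * C4c
    )
    d[14] = (
        gamma * OCa - KPCB * I1c
        + 0.01 * (alpha * gamma * C4c - 4.0 * KPCB * beta * I1c)
        + 0.001 * (alpha * I3c - Kpcf * I1c)
    )
    d[15] = (
        0.001 * (Kpcf * OCa - alpha * I2c) + KPCB * I3c - gamma * I2c
        + 0.002 * (Kpcf * C4c - 4.0 * beta * I2c)
    )
    d[16] = (
        0.001 * (Kpcf * I1c - alpha * I3c) + gamma * I2c - KPCB * I3c
        + gamma * Kpcf * C4c - 4.0 * beta * KPCB * I3c
    )

    # sodium concentration
    conv_ion = ACAP * CM / (VMYO * FARADAY)
    d[17] = -(INa + INab + 3.0 * INaCa + 3.0 * INaK) * conv_ion

    # fast Na+ channel Markov chain (C_Na3 algebraic)
    aNa11 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 17.0) + 0.20 * np.exp(-(V + 2.5) / 150.0))
    aNa12 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 15.0) + 0.23 * np.exp(-(V + 2.5) / 150.0))
    aNa13 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 12.0) + 0.25 * np.exp(-(V + 2.5) / 150.0))
    bNa11 = 0.1917 * np.exp(-(V + 2.5) / 20.3)
    bNa12 = 0.20 * np.exp(-(V - 2.5) / 20.3)
    bNa13 = 0.22 * np.exp(-(V - 7.5) / 20.3)
    aNa3 = 7.0e-7 * np.exp(-(V + 7.0) / 7.7)
    bNa3 = 0.0084 + 2.0e-5 * (V + 7.0)
    aNa2 = 1.0 / (0.188495 * np.exp(-(V + 7.0) / 16.6) + 0.393956)
    bNa2 = aNa13 * aNa2 * aNa3 / (bNa13 * bNa3)
    aNa4 = aNa2 / 1000.0
    bNa4 = aNa3
    aNa5 = aNa2 / 95000.0
    bNa5 = aNa3 / 50.0
    CNa3 = 1.0 - (CNa2 + CNa1 + ONa + IFNa + I1Na + I2Na + ICNa2 + ICNa3)
    d[18] = (
        aNa11 * CNa3 + bNa12 * CNa1 + aNa3 * ICNa2
        - (bNa11 + aNa12 + bNa3) * CNa2
    )
    d[19] = (
        aNa12 * CNa2 + bNa13 * ONa + aNa3 * IFNa
        - (bNa12 + aNa13 + bNa3) * CNa1
    )
    d[20] = aNa13 * CNa1 + bNa2 * IFNa - (bNa13 + aNa2) * ONa
    d[21] = (
        aNa2 * ONa + bNa3 * CNa1 + bNa4 * I1Na + aNa12 * ICNa2
        - (bNa2 + aNa3 + aNa4 + bNa12) * IFNa
    )
    d[22] = aNa4 * IFNa + bNa5 * I2Na - (bNa4 + aNa5) * I1Na
    d[23] = aNa5 * I1Na - bNa5 * I2Na
    d[24] = (
        aNa11 * ICNa3 + bNa12 * IFNa + bNa3 * CNa2
        - (bNa11 + aNa12 + aNa3) * ICNa2
    )
    d[25] = bNa11 * ICNa2 + bNa3 * CNa3 - (aNa11 + aNa3) * ICNa3

    # potassium concentration (stimulus charge not booked into Ki)
    d[26] = -(IKtof + IKtos + IK1 + IKs + IKur + IKss + IKr - 2.0 * INaK) * conv_ion

    # transient outward, fast (Hodgkin-Huxley)
    aa = 0.18064 * np.exp(0.03577 * (V + 30.0))
    ba = 0.3956 * np.exp(-0.06237 * (V + 30.0))
    d[27] = aa * (1.0 - atof) - ba * atof
    ai_tof = 0.000152 * np.exp(-(V + 13.5) / 7.0) / (
        0.0067083 * np.exp(-(V + 33.5) / 7.0) + 1.0
    )
    bi_tof = 0.00095 * np.exp((V + 33.5) / 7.0) / (
        0.051335 * np.exp((V + 33.5) / 7.0) + 1.0
    )
    d[28] = ai_tof * (1.0 - itof) - bi_tof * itof

    # transient outward, slow
    ass = 1.0 / (1.0 + np.exp(-(V + 22.5) / 7.7))
    iss = 1.0 / (1.0 + np.exp((V + 45.2) / 5.7))
    tau_ta = 0.493 * np.exp(-0.0629 * V) + 2.058
    d[29] = (ass - atos) / tau_ta
    tau_tis = 270.0 + 1050.0 / (1.0 + np.exp((V + 45.2) / 5.7))
    d[30] = (iss - itos) / tau_tis

    # slow delayed rectifier
    dv = V + 26.5
    if np.abs(dv) < 1e-7:
        an = 4.81333e-6 / 0.128  # limit of x/(1-exp(-0.128 x))
    else:
        an = 4.81333e-6 * dv / (1.0 - np.exp(-0.128 * dv))
    bn = 9.53333e-5 * np.exp(-0.038 * dv)
    d[31] = an * (1.0 - nKs) - bn * nKs

    # ultrarapid and noninactivating steady-state K+
    d[32] = (ass - aur) / tau_ta
    tau_iur = 1200.0 - 170.0 / (1.0 + np.exp((V + 45.2) / 5.7))
    d[33] = (iss - iur) / tau_iur
    tau_kss = 39.3 * np.exp(-0.0862 * V) + 13.17
    d[34] = (ass - aKss) / tau_kss
    d[35] = 0.0

    # rapid delayed rectifier Markov chain (C_K0 algebraic)
    CK0 = 1.0 - (CK1 + CK2 + OK + IK)
    aa0 = 0.022348 * np.exp(0.01176 * V)
    ba0 = 0.047002 * np.exp(-0.0631 * V)
    aa1 = 0.013733 * np.exp(0.038198 * V)
    ba1 = 6.89e-5 * np.exp(-0.04178 * V)
    ai_kr = 0.090821 * np.exp(0.023391 * (V + 5.0))
    bi_kr = 0.006497 * np.exp(-0.03268 * (V + 5.0))
    d[36] = aa0 * CK0 - ba0 * CK1 + KB_KR * CK2 - KF_KR * CK1
    d[37] = KF_KR * CK1 - KB_KR * CK2 + ba1 * OK - aa1 * CK2
    d[38] = aa1 * CK2 - ba1 * OK + bi_kr * IK - ai_kr * OK
    d[39] = ai_kr * OK - bi_kr * IK

    return -Iion + I_stim


# Hodgkin-Huxley gates eligible for Rush-Larsen updates: index -> handled
# inside the dedicated kernel below.
_HH_GATES = (27, 28, 29, 30, 31, 32, 33, 34)


@njit(cache=True)
def _step(V, eta, I_stim, dt, n_sub):
    n = V.shape[0]
    d = np.empty(eta.shape[1])
    for _ in range(n_sub):
        for i in range(n):
            dV = _rhs(V[i], eta[i], d, I_stim[i])
            V[i] += dt * dV
            for k in range(eta.shape[1]):
                eta[i, k] += dt * d[k]


@njit(cache=True)
def _gate_inf_tau(V, out_inf, out_tau):
    """Steady states and time constants of the 8 HH-type gates."""
    aa = 0.18064 * np.exp(0.03577 * (V + 30.0))
    ba = 0.3956 * np.exp(-0.06237 * (V + 30.0))
    out_inf[0] = aa / (aa + ba); out_tau[0] = 1.0 / (aa + ba)
    ai = 0.000152 * np.exp(-(V + 13.5) / 7.0) / (0.0067083 * np.exp(-(V + 33.5) / 7.0) + 1.0)
    bi = 0.00095 * np.exp((V + 33.5) / 7.0) / (0.051335 * np.exp((V + 33.5) / 7.0) + 1.0)
    out_inf[1] = ai / (ai + bi); out_tau[1] = 1.0 / (ai + bi)
    ass = 1.0 / (1.0 + np.exp(-(V + 22.5) / 7.7))
    iss = 1.0 / (1.0 + np.exp((V + 45.2) / 5.7))
    tau_ta = 0.493 * np.exp(-0.0629 * V) + 2.058
    out_inf[2] = ass; out_tau[2] = tau_ta
    out_inf[3] = iss; out_tau[3] = 270.0 + 1050.0 / (1.0 + np.exp((V + 45.2) / 5.7))
    dv = V + 26.5
    if np.abs(dv) < 1e-7:
        an = 4.81333e-6 / 0.128
    else:
        an = 4.81333e-6 * dv / (1.0 - np.exp(-0.128 * dv))
    bn = 9.53333e-5 * np.exp(-0.038 * dv)
    out_inf[4] = an / (an + bn); out_tau[4] = 1.0 / (an + bn)
    out_inf[5] = ass; out_tau[5] = tau_ta
    out_inf[6] = iss; out_tau[6] = 1200.0 - 170.0 / (1.0 + np.exp((V + 45.2) / 5.7))
    out_inf[7] = ass; out_tau[7] = 39.3 * np.exp(-0.0862 * V) + 13.17


@njit(cache=True)
def _step_rl(V, eta, I_stim, dt, n_sub):
    n = V.shape[0]
    d = np.empty(eta.shape[1])
    ginf = np.empty(8)
    gtau = np.empty(8)
    for _ in range(n_sub):
        for i in range(n):
            dV = _rhs(V[i], eta[i], d, I_stim[i])
            _gate_inf_tau(V[i], ginf, gtau)
            V[i] += dt * dV
            for k in range(eta.shape[1]):
                eta[i, k] += dt * d[k]
            for g in range(8):
                k = 27 + g
                x_old = eta[i, k] - dt * d[k]
                eta[i, k] = ginf[g] + (x_old - ginf[g]) * np.exp(-dt / gtau[g])


class BondarenkoModel(IonicModel):
    """Mouse ventricular apex myocyte (41 differential variables)."""

    name = "bondarenko"
    n_states = 40
    quiescence_tol = 5e-3      # mV/ms at the relaxed rest state
    default_stim_duration = 2.0
    # twice the tissue-level diastolic threshold of a 2 ms edge-band
    # pulse on the calibrated homogeneous strip (threshold ~= 155 pA/pF
    # by bisection; the single-cell threshold is ~10.4 pA/pF but cannot
    # launch a wave against the gap-junction load)
    default_stim_amplitude = 310.0

    _rest_V: float | None = None
    _rest_eta: np.ndarray | None = None

    def __init__(self) -> None:
        if BondarenkoModel._rest_eta is None:
            V, eta = _relax_to_rest()
            BondarenkoModel._rest_V = V
            BondarenkoModel._rest_eta = eta
        self.V_rest = float(BondarenkoModel._rest_V)

    def initial_state(self) -> np.ndarray:
        return BondarenkoModel._rest_eta.copy()

    def f(self, V, eta):
        V = np.atleast_1d(np.asarray(V, dtype=float))
        eta = np.atleast_2d(np.asarray(eta, dtype=float))
        out = np.empty_like(eta)
        for i in range(V.size):
            _rhs(V[i], eta[i], out[i], 0.0)
        return out

    def I_ion(self, V, eta):
        V = np.atleast_1d(np.asarray(V, dtype=float))
        eta = np.atleast_2d(np.asarray(eta, dtype=float))
        out = np.empty(V.size)
        d = np.empty(self.n_states)
        for i in range(V.size):
            out[i] = -_rhs(V[i], eta[i], d, 0.0)
        return out

    def stepper(self, rush_larsen: bool = False):
        return _step_rl if rush_larsen else _step


def _relax_to_rest(T: float = 1000.0, dt: float = 1e-3) -> tuple[float, np.ndarray]:
    """Integrate quiescently from the published seed to the model's rest.

    Without a stimulus the dynamics are far from the stiff regime, so a
    1 μs substep (10x the stimulated one) is ample; the resulting state
    is verified to be a fixed point by the quiescence tests.
    """
    V = np.array([_V_SEED])
    eta = _INIT_SEED[None, :].copy()
    stim = np.zeros(1)
    _step(V, eta, stim, dt, int(T / dt))
    return float(V[0]), eta[0]
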