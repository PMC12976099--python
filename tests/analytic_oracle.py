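"""Independent expectation oracle for the ward simulator.

Propagates the expected occupancy measure over (los, stage) cells through
the daily transition deterministically — no sampling anywhere.  Valid for
any prediction rule whose per-patient marginal P(p̂ = 1 | los, τ) is known
(deterministic naive rules and confusion-calibrated emulators), because the
per-timepoint KPI expectations depend only on those marginals.

Ignores the flooring of admissions at zero, which is exact whenever the
expected admission total stays positive (always the case at the reference
study's scale).
"""

import numpy as np
import pandas as pd


def naive_marginal(majority):
    """P(p̂=1 | los, τ) for a deterministic per-τ majority rule."""

    def rho(los, tau):
        return float(majority[tau])

    return rho


def emulator_marginal(sensitivity, specificity):
    """P(p̂=1 | los, τ) for a confusion-calibrated stochastic rule."""

    def rho(los, tau):
        if los > tau + 1:
            return float(sensitivity[tau])
        return 1.0 - float(specificity[tau])

    return rho


def expected_kpis(probs, rho, beds, horizon):
    """Expected Npat/Ncor/Nov/Nun at t = 0..horizon.

    probs: LOS class probabilities (LOS = 1..4); rho(los, tau): marginal
    probability of predicting 1; beds: occupancy target B.
    """
    probs = np.asarray(probs, dtype=float)
    mu = np.zeros((4, 4))  # mu[los-1, stage]
    for los in range(1, 5):
        n_preds = min(los, 3)
        for s in range(n_preds):
            mu[los - 1, s] = beds * probs[los - 1] / n_preds
    rows = []
    for t in range(horizon + 1):
        npat = mu.sum()
        ncor = nov = nun = fhat = 0.0
        for los in range(1, 5):
            for s in range(4):
                m = mu[los - 1, s]
                if m == 0.0:
                    continue
                eff = min(s, 2)
                p1 = rho(los, eff)
                truth = 1 if los > eff + 1 else 0
                if truth:
                    ncor += m * p1
                    nun += m * (1.0 - p1)
                else:
                    ncor += m * (1.0 - p1)
                    nov += m * p1
                fhat += m if s == 3 else m * (1.0 - p1)
        rows.append((t, npat, ncor, nov, nun))
        nxt = np.zeros((4, 4))
        for los in range(1, 5):
            for s in range(4):
                m = mu[los - 1, s]
                if m == 0.0 or s == los - 1:  # actual discharge
                    continue
                nxt[los - 1, s + 1] += m
        admissions = fhat + beds - npat
        nxt[:, 0] += admissions * probs
        mu = nxt
    return pd.DataFrame(rows, columns=["t", "Npat", "Ncor", "Nov", "Nun"])
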