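"""Independent brute-force oracles used to validate the package.

These are deliberately written as plain double-loop Python, sharing no
code with the implementations they check.
"""

import math

import numpy as np


def sample_entropy_oracle(x, m=2, r=0.2):
    """-ln(A/B) over all distinct template pairs, self-matches excluded."""
    x = [float(v) for v in x]
    n = len(x)
    sd = float(np.std(x))
    tol = r * sd
    nt = n - m  # templates for which both m and m+1 windows exist
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm <= tol:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) <= tol:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def approximate_entropy_oracle(x, m=2, r=0.2):
    """Phi^m - Phi^{m+1}, self-matches included."""
    x = [float(v) for v in x]
    sd = float(np.std(x))
    tol = r * sd

    def phi(mm):
        nt = len(x) - mm + 1
        total = 0.0
        for i in range(nt):
            c = 0
            for j in range(nt):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= tol:
                    c += 1
            total += math.log(c / nt)
        return total / nt

    return phi(m) - phi(m + 1)


def fuzzy_entropy_oracle(x, m=2, r=0.2, n_fuzzy=2):
    """-ln(phi^{m+1}/phi^m) with exponential membership on
    mean-subtracted templates, distinct pairs only."""
    x = [float(v) for v in x]
    sd = float(np.std(x))
    if sd == 0:
        return float("nan")
    tol = r * sd
    nt = len(x) - m

    def phi(mm):
        templates = []
        for i in range(nt):
            t = [x[i + k] for k in range(mm)]
            mean = sum(t) / mm
            templates.append([v - mean for v in t])
        total = 0.0
        count = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                d = max(
                    abs(templates[i][k] - templates[j][k]) for k in range(mm)
                )
                total += math.exp(-((d / tol) ** n_fuzzy))
                count += 1
        return total / count

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        return float("nan")
    return -math.log(p_m1 / p_m)


def hrv_oracle(rr):
    """Direct-summation HRV statistics with the source denominators."""
    rr = [float(v) for v in rr]
    n = len(rr)
    rmssd = math.sqrt(
        sum((rr[i + 1] - rr[i]) ** 2 for i in range(n - 1)) / (n - 1)
    )
    avrr = sum(rr) / n
    sdrr = math.sqrt(sum((v - avrr) ** 2 for v in rr) / (n - 1))
    if sdrr == 0:
        return rmssd, avrr, sdrr, float("nan"), float("nan")
    skew = sum((v - avrr) ** 3 for v in rr) / (n * sdrr**3)
    kurt = sum((v - avrr) ** 4 for v in rr) / (n * sdrr**4) - 3.0
    return rmssd, avrr, sdrr, skew, kurt


def match_peaks(true_times, detected_times, tol_s=0.05):
    """Greedy one-to-one matching; returns (recall, precision)."""
    true_times = list(true_times)
    detected = list(detected_times)
    matched = 0
    used = set()
    for t in true_times:
        best, best_d = None, tol_s
        for i, d in enumerate(detected):
            if i in used:
                continue
            if abs(d - t) <= best_d:
                best, best_d = i, abs(d - t)
        if best is not None:
            used.add(best)
            matched += 1
    recall = matched / len(true_times) if true_times else 0.0
    precision = matched / len(detected) if detected else 0.0
    return recall, precision
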