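"""Independent reference implementations used only as test oracles.

Deliberately naive: explicit Python loops transcribed from the original
co-occurrence-statistics formulas, with no code shared with the package.
"""

import math

import numpy as np


def naive_glcm(img, d, dy_dx, symmetric=True):
    """Co-occurrence counts for a single (dy, dx) offset, by enumeration."""
    img = np.asarray(img)
    G = int(img.max()) + 1
    h, w = img.shape
    dy, dx = dy_dx
    P = np.zeros((G, G))
    for i in range(h):
        for j in range(w):
            i2, j2 = i + dy * d, j + dx * d
            if 0 <= i2 < h and 0 <= j2 < w:
                P[img[i, j], img[i2, j2]] += 1
    if symmetric:
        P = P + P.T
    return P


def naive_haralick(P):
    """The 13 co-occurrence statistics from a normalized GLCM, by loops.

    Same documented conventions as the package (entropies base 2, IMC2
    from natural-log entropies); everything else computed longhand.
    """
    P = np.asarray(P, dtype=float)
    G = P.shape[0]
    px = [sum(P[i][j] for j in range(G)) for i in range(G)]
    py = [sum(P[i][j] for i in range(G)) for j in range(G)]
    mu_x = sum(i * px[i] for i in range(G))
    mu_y = sum(j * py[j] for j in range(G))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(G))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(G))

    p_sum = [0.0] * (2 * G - 1)
    p_diff = [0.0] * G
    for i in range(G):
        for j in range(G):
            p_sum[i + j] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]

    def h2(ps):
        return -sum(p * math.log2(p) for p in ps if p > 0)

    def hn(ps):
        return -sum(p * math.log(p) for p in ps if p > 0)

    asm = sum(P[i][j] ** 2 for i in range(G) for j in range(G))
    contrast = sum(k * k * p_diff[k] for k in range(G))
    idm = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G))
    variance = sum((i - mu_x) ** 2 * P[i][j] for i in range(G) for j in range(G))
    entropy = h2(P.ravel())
    sum_entropy = h2(p_sum)
    sum_average = sum(k * p_sum[k] for k in range(2 * G - 1))
    sum_variance = sum((k - sum_average) ** 2 * p_sum[k] for k in range(2 * G - 1))
    diff_mean = sum(k * p_diff[k] for k in range(G))
    diff_variance = sum((k - diff_mean) ** 2 * p_diff[k] for k in range(G))
    diff_entropy = h2(p_diff)

    if var_x > 0 and var_y > 0:
        corr = (
            sum((i - mu_x) * (j - mu_y) * P[i][j] for i in range(G) for j in range(G))
            / math.sqrt(var_x * var_y)
        )
        hx, hy, hxy = hn(px), hn(py), hn(P.ravel())
        hxy1 = -sum(
            P[i][j] * math.log(px[i] * py[j])
            for i in range(G)
            for j in range(G)
            if P[i][j] > 0 and px[i] * py[j] > 0
        )
        hxy2 = -sum(
            px[i] * py[j] * math.log(px[i] * py[j])
            for i in range(G)
            for j in range(G)
            if px[i] * py[j] > 0
        )
        imc1 = (hxy - hxy1) / max(hx, hy)
        imc2 = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    else:
        corr = imc1 = imc2 = float("nan")

    return {
        "ASM": asm,
        "contrast": contrast,
        "correlation": corr,
        "sum_of_squares": variance,
        "IDM": idm,
        "entropy": entropy,
        "sum_entropy": sum_entropy,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "difference_variance": diff_variance,
        "difference_entropy": diff_entropy,
        "IMC1": imc1,
        "IMC2": imc2,
    }


def naive_run_lengths(img, axis_lines):
    """Run-length counts from a list of 1-D lines, by explicit scanning."""
    counts = {}
    for line in axis_lines:
        line = list(line)
        k = 0
        while k < len(line):
            g = line[k]
            length = 1
            while k + length < len(line) and line[k + length] == g:
                length += 1
            counts[(g, length)] = counts.get((g, length), 0) + 1
            k += length
    return counts
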