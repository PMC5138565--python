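"""Independent brute-force oracles shared across test modules."""

import numpy as np


def haralick_oracle(P):
    """Independent term-by-term double-loop evaluation of the 14 statistics."""
    k = P.shape[0]
    px = [sum(P[i, j] for j in range(k)) for i in range(k)]
    py = [sum(P[i, j] for i in range(k)) for j in range(k)]
    mu_x = sum(i * px[i] for i in range(k))
    mu_y = sum(j * py[j] for j in range(k))
    sd_x = sum((i - mu_x) ** 2 * px[i] for i in range(k)) ** 0.5
    sd_y = sum((j - mu_y) ** 2 * py[j] for j in range(k)) ** 0.5
    ent = lambda p: -sum(v * np.log2(v) for v in p if v > 0)

    asm = con = cor = var = idm = hxy = 0.0
    for i in range(k):
        for j in range(k):
            p = P[i, j]
            asm += p * p
            con += (i - j) ** 2 * p
            var += (i - mu_x) ** 2 * p
            idm += p / (1 + (i - j) ** 2)
            if sd_x > 0 and sd_y > 0:
                cor += (i - mu_x) * (j - mu_y) * p / (sd_x * sd_y)
            if p > 0:
                hxy -= p * np.log2(p)
    psum = [0.0] * (2 * k - 1)
    pdif = [0.0] * k
    for i in range(k):
        for j in range(k):
            psum[i + j] += P[i, j]
            pdif[abs(i - j)] += P[i, j]
    sa = sum(s * psum[s] for s in range(2 * k - 1))
    sv = sum((s - sa) ** 2 * psum[s] for s in range(2 * k - 1))
    se = ent(psum)
    dm = sum(d * pdif[d] for d in range(k))
    dv = sum((d - dm) ** 2 * pdif[d] for d in range(k))
    de = ent(pdif)
    hxy1 = -sum(
        P[i, j] * np.log2(px[i] * py[j])
        for i in range(k)
        for j in range(k)
        if px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log2(px[i] * py[j])
        for i in range(k)
        for j in range(k)
        if px[i] * py[j] > 0
    )
    hx, hy = ent(px), ent(py)
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))
    live = [i for i in range(k) if px[i] > 0]
    livec = [j for j in range(k) if py[j] > 0]
    if len(live) >= 2 and len(livec) >= 2:
        Q = np.zeros((len(live), len(livec)))
        for a, i in enumerate(live):
            for b, j in enumerate(livec):
                Q[a, b] = sum(
                    P[i, m] * P[j, m] / (px[i] * py[m]) for m in livec
                )
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = np.sqrt(max(0.0, ev[-2]))
    else:
        mcc = 0.0
    return np.array([asm, con, cor, var, idm, sa, sv, se, hxy, dv, de, imc1, imc2, mcc])


def random_glcm(rng, k=4):
    M = rng.random((k, k))
    M = M + M.T
    return M / M.sum()
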