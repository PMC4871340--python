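"""Literal, loop-based reference implementations of the fluctuation
statistics, kept deliberately independent of the production code paths."""

import math


def rmsf_oracle(coords):
    """Per-atom RMSF via explicit frame loops. coords: (F, N, 3) nested-indexable."""
    F = len(coords)
    N = len(coords[0])
    out = []
    for i in range(N):
        mean = [0.0, 0.0, 0.0]
        for t in range(F):
            for a in range(3):
                mean[a] += coords[t][i][a] / F
        acc = 0.0
        for t in range(F):
            for a in range(3):
                d = coords[t][i][a] - mean[a]
                acc += d * d / F
        out.append(math.sqrt(acc))
    return out


def pcc_oracle(coords, i, j):
    """Scalar PCC of one atom pair via explicit loops (sum normalization)."""
    F = len(coords)

    def series(atom, axis):
        return [coords[t][atom][axis] for t in range(F)]

    def mean(xs):
        return sum(xs) / len(xs)

    total = 0.0
    for a in range(3):
        for b in range(3):
            xi = series(i, a)
            yj = series(j, b)
            mi, mj = mean(xi), mean(yj)
            cov = sum((x - mi) * (y - mj) for x, y in zip(xi, yj)) / F
            vi = sum((x - mi) ** 2 for x in xi) / F
            vj = sum((y - mj) ** 2 for y in yj) / F
            if vi == 0.0 or vj == 0.0:
                continue
            rho = cov / math.sqrt(vi * vj)
            total += rho * rho
    return math.sqrt(total)


def pearson_oracle(xs, ys):
    """Pearson r from the definition."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    dx = math.sqrt(sum((x - mx) ** 2 for x in xs))
    dy = math.sqrt(sum((y - my) ** 2 for y in ys))
    return num / (dx * dy)
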