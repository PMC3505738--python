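"""Independent brute-force reference implementation of the moment descriptors.

Written with explicit loops and the ``math`` module only, sharing no code
with the production path, so it can serve as an oracle in equivalence tests.
"""

import math


def _dist(a, b):
    return math.sqrt(sum((a[k] - b[k]) ** 2 for k in range(3)))


def reference_points(coords):
    n = len(coords)
    ctd = [sum(c[k] for c in coords) / n for k in range(3)]
    d_ctd = [_dist(c, ctd) for c in coords]
    cst = coords[d_ctd.index(min(d_ctd))]
    fct = coords[d_ctd.index(max(d_ctd))]
    d_fct = [_dist(c, fct) for c in coords]
    ftf = coords[d_fct.index(max(d_fct))]
    return [ctd, cst, fct, ftf]


def moment_triple(values):
    n = len(values)
    mu = sum(values) / n
    var = sum((v - mu) ** 2 for v in values) / n
    sigma = math.sqrt(var)
    third = sum((v - mu) ** 3 for v in values) / n
    # flush cancellation noise below the summation rounding error to zero,
    # matching the documented kappa definition
    eps = 2.220446049250313e-16
    max_c = max(abs(v - mu) for v in values)
    if abs(third) < 32.0 * n * eps * max_c**2 * max(abs(mu), max_c):
        third = 0.0
    kappa = math.copysign(abs(third) ** (1.0 / 3.0), third)
    return [mu, sigma, kappa]


def usr_vector(coords):
    out = []
    for point in reference_points(coords):
        out.extend(moment_triple([_dist(c, point) for c in coords]))
    return out


def usrcat_vector(coords, hydrophobic, aromatic, acceptor, donor):
    """60-moment vector; subset blocks in the order hydrophobic, aromatic,
    acceptor, donor, each measured against the all-atom reference points."""
    refs = reference_points(coords)
    out = []
    for point in refs:
        out.extend(moment_triple([_dist(c, point) for c in coords]))
    for idxs in (hydrophobic, aromatic, acceptor, donor):
        if not idxs:
            out.extend([0.0] * 12)
            continue
        sub = [coords[i] for i in sorted(idxs)]
        for point in refs:
            out.extend(moment_triple([_dist(c, point) for c in sub]))
    return out


def usrcat_similarity(vi, vj, ow, hw, rw, aw, dw):
    weights = [ow, hw, rw, aw, dw]
    total = 0.0
    for b in range(5):
        block = sum(abs(vi[12 * b + l] - vj[12 * b + l]) for l in range(12)) / 12.0
        total += weights[b] * block
    return 1.0 / (1.0 + total)
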