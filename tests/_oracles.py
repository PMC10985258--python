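"""Independent brute-force reference implementations used to cross-check
the package. Everything here is deliberately naive — plain loops and the
most literal formula — and shares no code with the library paths it
verifies."""

import numpy as np

PB_ORDER = "abcdefghijklmnop"


def wrap_magnitude(a, b):
    """Minimal angular separation |a - b| on the circle."""
    d = abs(float(a) - float(b)) % 360.0
    return min(d, 360.0 - d)


def dihedral_reference(p0, p1, p2, p3):
    """Torsion angle via the two-plane-normal atan2 formulation (IUPAC
    sign), written independently of the package's projection method."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    return np.degrees(np.arctan2(y, x))


def assign_window_reference(window, prototypes):
    """Exhaustive 16-prototype scorer: RMSDA per prototype by explicit
    loops, minimum with alphabetical tie-break."""
    best_label, best_score = None, None
    for p in range(16):
        total = 0.0
        for k in range(8):
            d = wrap_magnitude(window[k], prototypes[p, k])
            total += d * d
        score = (total / 8.0) ** 0.5
        if best_score is None or score < best_score - 1e-12:
            best_label, best_score = PB_ORDER[p], score
    return best_label, best_score


def delta_pb_reference(f1, f2):
    """16-term hand summation of |f1_x - f2_x|."""
    total = 0.0
    for x in range(16):
        total += abs(float(f1[x]) - float(f2[x]))
    return total


def pearson_reference(x, y):
    """Covariance-ratio Pearson coefficient, by explicit sums."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def frequency_tally_reference(labels):
    """Naive double-loop per-position PB frequency tally, Z excluded.

    ``labels`` is a frames x positions array of letters; returns
    (freq, n_obs) with NaN rows at all-Z positions.
    """
    n_frames, n_pos = labels.shape
    freq = np.full((n_pos, 16), np.nan)
    n_obs = np.zeros(n_pos, dtype=int)
    for i in range(n_pos):
        counts = {}
        for f in range(n_frames):
            lab = labels[f, i]
            if lab == "Z":
                continue
            counts[lab] = counts.get(lab, 0) + 1
        n = sum(counts.values())
        n_obs[i] = n
        if n:
            freq[i] = [counts.get(c, 0) / n for c in PB_ORDER]
    return freq, n_obs
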