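"""Literal brute-force reference implementations used as test oracles.

Everything here is written as plain per-pixel loops straight from the
mathematical definitions — deliberately slow and independent of the package's
vectorized implementations.
"""

import numpy as np


def median_filter_bf(img: np.ndarray, k: int) -> np.ndarray:
    """Per-pixel sort-and-pick-middle median with edge replication."""
    h, w = img.shape
    p = k // 2
    padded = np.pad(img, p, mode="edge")
    out = np.empty_like(img, dtype=np.float64)
    for r in range(h):
        for c in range(w):
            window = sorted(padded[r : r + k, c : c + k].ravel().tolist())
            out[r, c] = window[len(window) // 2]
    return out


def correlate_bf(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """3x3 correlation with edge replication, written as explicit loops."""
    h, w = img.shape
    padded = np.pad(img, 1, mode="edge")
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for dr in range(3):
                for dc in range(3):
                    acc += kernel[dr, dc] * padded[r + dr, c + dc]
            out[r, c] = acc
    return out


def kirsch_bf(img: np.ndarray, kernels) -> np.ndarray:
    """Maximum over the eight directional correlations."""
    responses = [correlate_bf(img, k) for k in kernels]
    return np.max(np.stack(responses), axis=0)


def sobel_field_bf(img: np.ndarray):
    """Gradient magnitude/angle from explicit Sobel loops."""
    sx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
    gx = correlate_bf(img, sx)
    gy = correlate_bf(img, sx.T)
    mag = np.sqrt(gx**2 + gy**2)
    ang = np.zeros_like(mag)
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            if gx[r, c] == 0:
                ang[r, c] = 0.0 if gy[r, c] == 0 else np.pi / 2
            else:
                ang[r, c] = np.arctan(gy[r, c] / gx[r, c])
    return mag, ang


def otsu_bf(img: np.ndarray, levels: int = 256) -> int:
    """Exhaustive between-class-variance scan, one threshold at a time."""
    vals = np.rint(img).astype(int).ravel()
    best_t, best_var = 0, -1.0
    n = vals.size
    for t in range(levels):
        lo = vals[vals < t]
        hi = vals[vals >= t]
        if lo.size == 0 or hi.size == 0:
            var = 0.0
        else:
            w0, w1 = lo.size / n, hi.size / n
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def erode_bf(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """A (-) B: x kept iff every element offset lands on foreground."""
    h, w = mask.shape
    kh, kw = se.shape
    ch, cw = kh // 2, kw // 2
    out = np.zeros_like(mask, dtype=bool)
    for r in range(h):
        for c in range(w):
            keep = True
            for dr in range(kh):
                for dc in range(kw):
                    if not se[dr, dc]:
                        continue
                    rr, cc = r + dr - ch, c + dc - cw
                    val = mask[rr, cc] if 0 <= rr < h and 0 <= cc < w else False
                    if not val:
                        keep = False
                        break
                if not keep:
                    break
            out[r, c] = keep
    return out


def dilate_bf(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """A (+) B: union of the element translated to every foreground pixel."""
    h, w = mask.shape
    kh, kw = se.shape
    ch, cw = kh // 2, kw // 2
    out = np.zeros_like(mask, dtype=bool)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr in range(kh):
                for dc in range(kw):
                    if not se[dr, dc]:
                        continue
                    rr, cc = r + dr - ch, c + dc - cw
                    if 0 <= rr < h and 0 <= cc < w:
                        out[rr, cc] = True
    return out


def open_bf(mask, se):
    """Full-plane opening restricted to the window (padded domain)."""
    p = max(se.shape) // 2
    padded = np.pad(mask, p, mode="constant")
    out = dilate_bf(erode_bf(padded, se), se)
    return out[p:-p, p:-p] if p else out


def close_bf(mask, se):
    """Full-plane closing restricted to the window (padded domain)."""
    p = max(se.shape) // 2
    padded = np.pad(mask, p, mode="constant")
    out = erode_bf(dilate_bf(padded, se), se)
    return out[p:-p, p:-p] if p else out


def gray_dilate_bf(img: np.ndarray, se: np.ndarray, values: np.ndarray) -> np.ndarray:
    """(f (+) b)(x) = sup_y [f(y) + b(x - y)] with edge replication."""
    h, w = img.shape
    kh, kw = se.shape
    ch, cw = kh // 2, kw // 2
    out = np.empty_like(img, dtype=np.float64)
    for r in range(h):
        for c in range(w):
            best = -np.inf
            for dr in range(kh):
                for dc in range(kw):
                    if not se[dr, dc]:
                        continue
                    rr = min(max(r - (dr - ch), 0), h - 1)
                    cc = min(max(c - (dc - cw), 0), w - 1)
                    cand = img[rr, cc] + values[dr, dc]
                    if cand > best:
                        best = cand
            out[r, c] = best
    return out


def histogram_equalize_bf(channel: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Plain histogram equalization: m(i) = (L-1) * cdf(i), by counting loops."""
    vals = channel.astype(int)
    counts = [0] * nbins
    for v in vals.ravel():
        counts[v] += 1
    n = vals.size
    cdf, acc = [], 0
    for cnt in counts:
        acc += cnt
        cdf.append(acc / n)
    mapping = [(nbins - 1) * p for p in cdf]
    out = np.empty(vals.shape, dtype=np.float64)
    for r in range(vals.shape[0]):
        for c in range(vals.shape[1]):
            out[r, c] = mapping[vals[r, c]]
    return out
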