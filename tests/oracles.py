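"""Independent brute-force oracles for the texture-feature engine.

Everything here is written for clarity at tiny image sizes (nested Python
loops, explicit flood fill, literal formula sums) and deliberately shares
no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_pairs_oracle(levels, mask, n_bins, offset, symmetric=True):
    """Exhaustive in-mask ordered-pair enumeration for one GLCM offset."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    H, W = levels.shape
    dr, dc = offset
    mat = np.zeros((n_bins, n_bins))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W and mask[r, c] and mask[r2, c2]:
                mat[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    if symmetric:
        mat = mat + mat.T
    return mat / mat.sum() if mat.sum() else mat


def glszm_floodfill_oracle(levels, mask, connectivity=8):
    """Zone enumeration by explicit flood fill; returns {(level, size): count}."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    H, W = levels.shape
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros((H, W), dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for r in range(H):
        for c in range(W):
            if not mask[r, c] or seen[r, c]:
                continue
            lvl = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in neigh:
                    r2, c2 = rr + dr, cc + dc
                    if (
                        0 <= r2 < H
                        and 0 <= c2 < W
                        and mask[r2, c2]
                        and not seen[r2, c2]
                        and levels[r2, c2] == lvl
                    ):
                        seen[r2, c2] = True
                        stack.append((r2, c2))
            zones[(int(lvl), size)] = zones.get((int(lvl), size), 0) + 1
    return zones


def lbp_oracle(frame, radius, n_points):
    """Per-pixel neighbour-threshold enumeration with periodic wrap.

    Bilinear interpolation is done by hand; offsets within 1e-9 of an
    integer are snapped, matching the implementation's tie handling.
    """
    frame = np.asarray(frame, dtype=float)
    H, W = frame.shape

    def sample(r, c):
        r %= H
        c %= W
        r0, c0 = int(math.floor(r)), int(math.floor(c))
        fr, fc = r - r0, c - c0
        r1, c1 = (r0 + 1) % H, (c0 + 1) % W
        return (
            frame[r0, c0] * (1 - fr) * (1 - fc)
            + frame[r0, c1] * (1 - fr) * fc
            + frame[r1, c0] * fr * (1 - fc)
            + frame[r1, c1] * fr * fc
        )

    codes = np.zeros((H, W), dtype=int)
    for r in range(H):
        for c in range(W):
            bits = []
            for p in range(n_points):
                theta = 2 * math.pi * p / n_points
                dr = radius * math.sin(theta)
                dc = radius * math.cos(theta)
                if abs(dr - round(dr)) < 1e-9:
                    dr = round(dr)
                if abs(dc - round(dc)) < 1e-9:
                    dc = round(dc)
                bits.append(1 if sample(r + dr, c + dc) >= frame[r, c] else 0)
            transitions = sum(
                bits[i] != bits[(i - 1) % n_points] for i in range(n_points)
            )
            codes[r, c] = sum(bits) if transitions <= 2 else n_points + 1
    return codes


def haar_subbands_oracle(frame):
    """Direct periodic correlation with the stated Haar kernels."""
    frame = np.asarray(frame, dtype=float)
    H, W = frame.shape
    s = math.sqrt(2.0)

    def conv(img, axis, kernel):
        out = np.zeros_like(img)
        for r in range(H):
            for c in range(W):
                acc = 0.0
                for k, w in enumerate(kernel):
                    if axis == 0:
                        acc += w * img[(r + k) % H, c]
                    else:
                        acc += w * img[r, (c + k) % W]
                out[r, c] = acc
        return out

    lo = [1 / s, 1 / s]
    hi = [1 / s, -1 / s]
    out = {}
    for rk, rker in (("L", lo), ("H", hi)):
        tmp = conv(frame, 0, rker)
        for ck, cker in (("L", lo), ("H", hi)):
            out[rk + ck] = conv(tmp, 1, cker)
    return out


def glcm_features_oracle(p):
    """Literal formula sums over one co-occurrence probability matrix."""
    p = np.asarray(p, dtype=float)
    B = p.shape[0]
    feats = {k: 0.0 for k in (
        "JointAverage", "JointEnergy", "JointEntropy", "Contrast",
        "Correlation", "Idm", "Idn", "Imc1", "Imc2")}
    px = [sum(p[i, j] for j in range(B)) for i in range(B)]
    py = [sum(p[i, j] for i in range(B)) for j in range(B)]
    hxy = hxy1 = hxy2 = 0.0
    for i in range(B):
        for j in range(B):
            pij = p[i, j]
            feats["JointAverage"] += (i + 1) * pij
            feats["JointEnergy"] += pij**2
            feats["Contrast"] += (i - j) ** 2 * pij
            feats["Idm"] += pij / (1 + (i - j) ** 2)
            feats["Idn"] += pij / (1 + abs(i - j) / B)
            if pij > 0:
                hxy -= pij * math.log2(pij)
            if px[i] * py[j] > 0:
                hxy1 -= pij * math.log2(px[i] * py[j])
                hxy2 -= px[i] * py[j] * math.log2(px[i] * py[j])
    mu_x = sum((i + 1) * px[i] for i in range(B))
    mu_y = sum((j + 1) * py[j] for j in range(B))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(B)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(B)))
    if sig_x * sig_y > 0:
        num = sum(
            (i + 1) * (j + 1) * p[i, j] for i in range(B) for j in range(B)
        ) - mu_x * mu_y
        feats["Correlation"] = num / (sig_x * sig_y)
    else:
        feats["Correlation"] = 1.0
    feats["JointEntropy"] = hxy
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hy = -sum(v * math.log2(v) for v in py if v > 0)
    feats["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    feats["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    return feats


def glszm_features_oracle(zones, n_pixels):
    """Literal formula sums from a {(level, size): count} zone dict."""
    n_z = sum(zones.values())
    sae = sum(cnt / size**2 for (_, size), cnt in zones.items()) / n_z
    lae = sum(cnt * size**2 for (_, size), cnt in zones.items()) / n_z
    by_level: dict[int, float] = {}
    by_size: dict[int, float] = {}
    for (lvl, size), cnt in zones.items():
        by_level[lvl] = by_level.get(lvl, 0) + cnt
        by_size[size] = by_size.get(size, 0) + cnt
    gln = sum(v**2 for v in by_level.values()) / n_z
    szn = sum(v**2 for v in by_size.values()) / n_z
    zp = n_z / n_pixels
    zent = -sum((c / n_z) * math.log2(c / n_z) for c in zones.values())
    return {
        "SmallAreaEmphasis": sae,
        "LargeAreaEmphasis": lae,
        "GrayLevelNonUniformity": gln,
        "SizeZoneNonUniformity": szn,
        "ZonePercentage": zp,
        "ZoneEntropy": zent,
    }
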