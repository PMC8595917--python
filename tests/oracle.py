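"""Independent brute-force oracles for the texture features.

Everything here is deliberately naive (triple loops, flood fills, direct
formula evaluation) and shares no code with the package implementation,
so agreement is evidence of correctness rather than of shared bugs.
"""

import math

import numpy as np

DIRS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1),
    (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _inside(shape, z, y, x):
    return 0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]


def brute_glcm(levels, ng, distance=1, directions=DIRS_13):
    """Symmetric merged co-occurrence probabilities by pair enumeration."""
    counts = np.zeros((ng, ng))
    shape = levels.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                a = levels[z, y, x]
                if a == 0:
                    continue
                for dz, dy, dx in directions:
                    zz, yy, xx = z + dz * distance, y + dy * distance, x + dx * distance
                    if not _inside(shape, zz, yy, xx):
                        continue
                    b = levels[zz, yy, xx]
                    if b == 0:
                        continue
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def brute_glcm_features(p):
    ng = p.shape[0]
    mu = sum((i + 1) * p[i, :].sum() for i in range(ng))
    f = {"contrast": 0.0, "cluster_tendency": 0.0, "cluster_prominence": 0.0,
         "joint_energy": 0.0, "joint_entropy": 0.0, "sum_squares": 0.0}
    cov = 0.0
    for i in range(ng):
        for j in range(ng):
            pij = p[i, j]
            ii, jj = i + 1, j + 1
            f["contrast"] += pij * (ii - jj) ** 2
            f["cluster_tendency"] += pij * (ii + jj - 2 * mu) ** 2
            f["cluster_prominence"] += pij * (ii + jj - 2 * mu) ** 4
            f["joint_energy"] += pij * pij
            if pij > 0:
                f["joint_entropy"] -= pij * math.log2(pij)
            f["sum_squares"] += pij * (ii - mu) ** 2
            cov += pij * (ii - mu) * (jj - mu)
    f["maximum_probability"] = p.max()
    f["correlation"] = cov / f["sum_squares"] if f["sum_squares"] > 0 else 1.0
    return f


def brute_glrlm(levels, ng, directions=DIRS_13):
    """Run counts by walking every maximal run from its start voxel."""
    shape = levels.shape
    lmax = max(shape)
    r = np.zeros((ng, lmax))
    for dz, dy, dx in directions:
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    lv = levels[z, y, x]
                    if lv == 0:
                        continue
                    pz, py, px = z - dz, y - dy, x - dx
                    if _inside(shape, pz, py, px) and levels[pz, py, px] == lv:
                        continue  # not a run start
                    length = 1
                    zz, yy, xx = z + dz, y + dy, x + dx
                    while _inside(shape, zz, yy, xx) and levels[zz, yy, xx] == lv:
                        length += 1
                        zz, yy, xx = zz + dz, yy + dy, xx + dx
                    r[lv - 1, length - 1] += 1
    return r


def brute_glrlm_features(r):
    nr = r.sum()
    srlgle = lrlgle = 0.0
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            if r[i, j]:
                srlgle += r[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
                lrlgle += r[i, j] * (j + 1) ** 2 / (i + 1) ** 2
    return {"short_run_low_gray_level_emphasis": srlgle / nr,
            "long_run_low_gray_level_emphasis": lrlgle / nr}


def brute_glszm(levels, ng):
    """Zone counts by explicit 26-connected flood fill per level."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    zones = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                lv = levels[z, y, x]
                if lv == 0 or visited[z, y, x]:
                    continue
                stack = [(z, y, x)]
                visited[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                if dz == dy == dx == 0:
                                    continue
                                nz, ny, nx = cz + dz, cy + dy, cx + dx
                                if (_inside(shape, nz, ny, nx)
                                        and not visited[nz, ny, nx]
                                        and levels[nz, ny, nx] == lv):
                                    visited[nz, ny, nx] = True
                                    stack.append((nz, ny, nx))
                zones.append((lv, size))
    smax = max(s for _, s in zones)
    s_mat = np.zeros((ng, smax))
    for lv, size in zones:
        s_mat[lv - 1, size - 1] += 1
    return s_mat


def brute_glszm_features(s_mat, n_voxels):
    nz = s_mat.sum()
    sae = lae = 0.0
    for i in range(s_mat.shape[0]):
        for j in range(s_mat.shape[1]):
            if s_mat[i, j]:
                sae += s_mat[i, j] / (j + 1) ** 2
                lae += s_mat[i, j] * (j + 1) ** 2
    return {"zone_percentage": nz / n_voxels,
            "small_area_emphasis": sae / nz,
            "large_area_emphasis": lae / nz}


def brute_ngtdm(levels, ng):
    """Per-level neighborhood-difference sums by direct averaging."""
    shape = levels.shape
    s_i = np.zeros(ng)
    n_i = np.zeros(ng)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                lv = levels[z, y, x]
                if lv == 0:
                    continue
                nb = []
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if dz == dy == dx == 0:
                                continue
                            nz, ny, nx = z + dz, y + dy, x + dx
                            if _inside(shape, nz, ny, nx) and levels[nz, ny, nx] > 0:
                                nb.append(levels[nz, ny, nx])
                if nb:
                    s_i[lv - 1] += abs(lv - sum(nb) / len(nb))
                    n_i[lv - 1] += 1
    return s_i, n_i


def brute_auc(labels, scores):
    """Concordance probability by exhaustive pair counting (midrank ties)."""
    pos = [s for l, s in zip(labels, scores) if l]
    neg = [s for l, s in zip(labels, scores) if not l]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_spearman(x, y):
    """Spearman via average ranks and the Pearson formula."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
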