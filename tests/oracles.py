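"""Independent brute-force reference implementations used only by tests.

Everything here works by explicit neighbor-offset enumeration and
breadth-first search on numpy arrays — no scipy.ndimage, no code shared
with the package — so agreement with the package is a genuine check.
"""

from __future__ import annotations

from collections import deque

import numpy as np

OFFS6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def ball_offsets(steps: float) -> list[tuple[int, int, int]]:
    """Integer offsets within the Euclidean ball of radius steps + 0.5."""
    r = steps + 0.5
    n = int(np.floor(r))
    return [
        (dz, dy, dx)
        for dz in range(-n, n + 1)
        for dy in range(-n, n + 1)
        for dx in range(-n, n + 1)
        if dz * dz + dy * dy + dx * dx <= r * r
    ]


def _shift(a: np.ndarray, off: tuple[int, int, int]) -> np.ndarray:
    """Shift without wraparound; vacated cells are False."""
    out = np.zeros_like(a)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, o in enumerate(off):
        if o > 0:
            dst[ax], src[ax] = slice(o, None), slice(None, -o)
        elif o < 0:
            dst[ax], src[ax] = slice(None, o), slice(-o, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


def bf_dilate(a: np.ndarray, offsets) -> np.ndarray:
    out = np.zeros_like(a)
    for off in offsets:
        out |= _shift(a, off)
    return out


def bf_erode(a: np.ndarray, offsets) -> np.ndarray:
    # outside the lattice counts as background, as in the package
    out = np.ones_like(a)
    for off in offsets:
        out &= _shift(a, off)
    return out


def bf_dilate6(a: np.ndarray, steps: int) -> np.ndarray:
    for _ in range(steps):
        a = a | bf_dilate(a, OFFS6)
    return a


def bf_erode6(a: np.ndarray, steps: int) -> np.ndarray:
    for _ in range(steps):
        a = a & bf_erode(a, OFFS6)
    return a


def bf_label(mask: np.ndarray, offsets=OFFS6) -> tuple[np.ndarray, int]:
    """BFS connected-component labeling."""
    labels = np.zeros(mask.shape, dtype=np.int32)
    n = 0
    shape = mask.shape
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        n += 1
        labels[start] = n
        q = deque([start])
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in offsets:
                w = (z + dz, y + dy, x + dx)
                if (
                    0 <= w[0] < shape[0]
                    and 0 <= w[1] < shape[1]
                    and 0 <= w[2] < shape[2]
                    and mask[w]
                    and not labels[w]
                ):
                    labels[w] = n
                    q.append(w)
    return labels, n


def bf_close_and_fill(structure: np.ndarray, steps: int) -> np.ndarray:
    """Euclidean-ball closing with border-connected background fill."""
    pad = steps + 1
    a = np.pad(structure, pad)
    offs = ball_offsets(steps)
    d = bf_dilate(a, offs) | a
    # fill: background voxels not reachable from the border (6-connectivity)
    bg = ~d
    border = np.zeros_like(bg)
    border[0], border[-1] = True, True
    border[:, 0], border[:, -1] = True, True
    border[:, :, 0], border[:, :, -1] = True, True
    seed_mask = bg & border
    reach = np.zeros_like(bg)
    q = deque(zip(*np.nonzero(seed_mask)))
    for s in zip(*np.nonzero(seed_mask)):
        reach[s] = True
    shape = bg.shape
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in OFFS6:
            w = (z + dz, y + dy, x + dx)
            if (
                0 <= w[0] < shape[0]
                and 0 <= w[1] < shape[1]
                and 0 <= w[2] < shape[2]
                and bg[w]
                and not reach[w]
            ):
                reach[w] = True
                q.append(w)
    filled = d | (bg & ~reach)
    closed = bf_erode(filled, offs) & filled
    return closed[pad:-pad, pad:-pad, pad:-pad]


def bf_fill_cavities(mask: np.ndarray) -> np.ndarray:
    bg = ~mask
    labels, n = bf_label(bg)
    border_labels = set()
    for face in (
        labels[0], labels[-1], labels[:, 0], labels[:, -1], labels[:, :, 0], labels[:, :, -1]
    ):
        border_labels |= set(np.unique(face[face > 0]).tolist())
    out = mask.copy()
    for i in range(1, n + 1):
        if i not in border_labels:
            out |= labels == i
    return out


def bf_build_mask(solid: np.ndarray, thickness: int):
    """Returns (shell, periosteal_face, endosteal_face)."""
    interior = bf_erode6(solid, thickness)
    shell = solid & ~interior
    peri = shell & bf_dilate(~solid, OFFS6)
    endo = shell & bf_dilate(interior, OFFS6)
    return shell, peri, endo


def bf_detect(
    bone: np.ndarray,
    shell: np.ndarray,
    peri: np.ndarray,
    endo: np.ndarray,
    radius: int = 1,
    min_voxels: int = 20,
):
    """Reference interruption detector; returns (final labeled sets, counts).

    Output: list of frozensets of voxel index tuples, one per surviving
    component, in no particular order.
    """
    cb = bone & shell
    void = shell & ~bf_dilate6(cb, radius)
    labels, n = bf_label(void)
    kept = np.zeros_like(void)
    for i in range(1, n + 1):
        comp = labels == i
        if (comp & peri).any() and (comp & endo).any():
            kept |= comp
    restored = bf_dilate6(kept, radius) & shell & ~bone
    final, m = bf_label(restored)
    comps = []
    for i in range(1, m + 1):
        vox = np.argwhere(final == i)
        if len(vox) >= min_voxels:
            comps.append(frozenset(map(tuple, vox)))
    return comps


def bf_gauss_threshold(
    data: np.ndarray, sigma: float, support: int, thresh: float
) -> np.ndarray:
    """Direct-convolution truncated-Gaussian smoothing + threshold."""
    rng = range(-support, support + 1)
    w1 = np.array([np.exp(-0.5 * (d / sigma) ** 2) for d in rng])
    w1 /= w1.sum()
    pad = support
    # replicate-pad to match the package's 'nearest' boundary mode
    ap = np.pad(data.astype(float), pad, mode="edge")
    out = np.zeros_like(data, dtype=float)
    nz, ny, nx = data.shape
    for i, dz in enumerate(rng):
        for j, dy in enumerate(rng):
            for k, dx in enumerate(rng):
                w = w1[i] * w1[j] * w1[k]
                out += w * ap[
                    pad + dz : pad + dz + nz,
                    pad + dy : pad + dy + ny,
                    pad + dx : pad + dx + nx,
                ]
    return out >= thresh


def bf_anova_icc21(x: np.ndarray) -> float:
    """ICC(2,1) by direct summation of the two-way ANOVA sums of squares."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sse = sum(
        (x[i, j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def exhaustive_match(overlaps: dict[tuple[int, int], int], min_overlap: int):
    """Maximum one-to-one assignment: most pairs, then largest total overlap.

    ``overlaps`` maps (label_a, label_b) -> voxel overlap.  Exponential;
    for tiny instances only.
    """
    cands = [(a, b, o) for (a, b), o in overlaps.items() if o >= min_overlap]

    best = (0, 0)

    def rec(i, used_a, used_b, npairs, tot):
        nonlocal best
        if i == len(cands):
            best = max(best, (npairs, tot))
            return
        rec(i + 1, used_a, used_b, npairs, tot)
        a, b, o = cands[i]
        if a not in used_a and b not in used_b:
            rec(i + 1, used_a | {a}, used_b | {b}, npairs + 1, tot + o)

    rec(0, frozenset(), frozenset(), 0, 0)
    return best
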