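import numpy as np
import pytest

from hyperrad.imaging import DiscretizedROI, LesionMask, LesionVolume


@pytest.fixture
def unit_grid():
    """Factory for 1-mm-iso volumes/masks from plain arrays."""

    def _make(values, mask=None, modality="PET"):
        values = np.asarray(values, dtype=float)
        vol = LesionVolume(values, (1, 1, 1), (0, 0, 0), modality)
        msk = LesionMask(np.ones(values.shape, bool) if mask is None
                         else np.asarray(mask, bool), (1, 1, 1), (0, 0, 0))
        return vol, msk

    return _make


@pytest.fixture
def roi_from_bins():
    """Build a DiscretizedROI directly from an integer bin grid (0=outside)."""

    def _make(bins):
        bins = np.asarray(bins, dtype=np.int64)
        while bins.ndim < 3:
            bins = bins[np.newaxis]
        return DiscretizedROI(bins, 1.0, 0.0, bins > 0)

    return _make


# ---------------------------------------------------------------------------
# Independent oracles, used to cross-check the implementation paths.


def brute_force_glcm(bins: np.ndarray, directions) -> np.ndarray:
    """Exhaustive symmetric pair enumeration over the given directions."""
    bins = np.asarray(bins)
    ng = int(bins.max())
    counts = np.zeros((ng, ng))
    nz, ny, nx = bins.shape
    for d in directions:
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    if bins[z, y, x] == 0:
                        continue
                    z2, y2, x2 = z + d[0], y + d[1], x + d[2]
                    if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                        continue
                    if bins[z2, y2, x2] == 0:
                        continue
                    a, b = bins[z, y, x] - 1, bins[z2, y2, x2] - 1
                    counts[a, b] += 1
                    counts[b, a] += 1
    total = counts.sum()
    return counts / total if total else counts


def brute_force_glrlm(bins: np.ndarray, directions) -> np.ndarray:
    """Exhaustive run enumeration over the given directions."""
    bins = np.asarray(bins)
    ng = int(bins.max())
    R = np.zeros((ng, max(bins.shape)))
    nz, ny, nx = bins.shape
    if not directions:  # single-voxel bounding box: one run per voxel
        for g in bins[bins > 0]:
            R[g - 1, 0] += 1
        return R

    def inside(p):
        return 0 <= p[0] < nz and 0 <= p[1] < ny and 0 <= p[2] < nx

    for d in directions:
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    g = bins[z, y, x]
                    if g == 0:
                        continue
                    prev = (z - d[0], y - d[1], x - d[2])
                    if inside(prev) and bins[prev] == g:
                        continue  # not a run start
                    length, nxt = 1, (z + d[0], y + d[1], x + d[2])
                    while inside(nxt) and bins[nxt] == g:
                        length += 1
                        nxt = (nxt[0] + d[0], nxt[1] + d[1], nxt[2] + d[2])
                    R[g - 1, length - 1] += 1
    return R


def hand_product_limit(times, events):
    """Kaplan-Meier by direct product over distinct event times.

    Returns (event_times, S_at_those_times, median) with the
    first-crossing-0.5 median convention.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out_t, out_s = [], []
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    median = np.inf
    for t, sv in zip(out_t, out_s):
        if sv <= 0.5:
            median = t
            break
    return np.array(out_t), np.array(out_s), median
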