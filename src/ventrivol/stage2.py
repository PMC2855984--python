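"""Stage II segmentation: KS-test region merging and region selection.

Stage I deliberately oversegments.  Stage II treats each region as a
texture sample and merges adjacent regions whose pixel-value distributions
agree, using the two-sample Kolmogorov-Smirnov statistic on two images:
the original slice and a *texture map* (the slice reconstructed from
detail subbands only, approximation zeroed), giving similarities S_ks2 and
S_ks1 respectively.  They combine as

    S_ks = S_ks2 * exp(S_ks1 - 1)

so the original-image similarity dominates and the texture similarity
modulates.  The pair with the largest S_ks merges; the loop stops when the
remaining adjacent pairs all look alike (max equals min within tolerance),
when only one region is left, or when no pair clears the similarity floor
(an extension preventing a monotone cascade from merging the whole image).

Segmenting the whole image says nothing about which regions are ventricle;
a user (or an automated stand-in) then picks regions by label or by seed
point, and the union of picked regions is the ventricle mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dtcwt import dtcwt_forward, dtcwt_inverse

__all__ = [
    "texture_map", "ks_similarity", "similarity_matrices", "SimilarityMatrix",
    "merge_until_stable", "select_regions", "relabel",
]

MAX_SAMPLES = 5000  # per-region pixel sample cap for the KS statistic


def texture_map(img: np.ndarray, levels: int = 4) -> np.ndarray:
    """Detail-only reconstruction: forward DT-CWT, zero the approximation
    bands, invert.  By linearity this equals the original image minus the
    approximation-only reconstruction, so it carries the texture content.
    """
    sb = dtcwt_forward(np.asarray(img, dtype=np.float64), levels)
    return dtcwt_inverse(sb, zero_lowpass=True)


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic: sup distance between empirical CDFs."""
    a = np.sort(np.asarray(a, dtype=np.float64).ravel())
    b = np.sort(np.asarray(b, dtype=np.float64).ravel())
    grid = np.concatenate([a, b])
    ca = np.searchsorted(a, grid, side="right") / a.size
    cb = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(ca - cb).max())


def ks_similarity(values_a, values_b) -> float:
    """Distributional similarity 1 - D_KS in [0, 1].

    1 for identical empirical distributions, 0 for disjoint supports.  The
    statistic (not its p-value) is used: on the large pixel samples
    involved, p-values saturate at 0 and lose the ordering the merge loop
    needs, while the statistic is rank-based and preserves it.
    """
    a = np.asarray(values_a, dtype=np.float64).ravel()
    b = np.asarray(values_b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty region sample")
    return 1.0 - _ks_statistic(a, b)


def _adjacent_pairs(labels: np.ndarray) -> set:
    """8-connected label adjacency of a 2-D label map."""
    pairs = set()
    H, W = labels.shape
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0, r1 = max(0, -dr), H - max(0, dr)
        c0, c1 = max(0, -dc), W - max(0, dc)
        a = labels[r0:r1, c0:c1]
        b = labels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        diff = a != b
        if np.any(diff):
            lo = np.minimum(a[diff], b[diff])
            hi = np.maximum(a[diff], b[diff])
            pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


@dataclass
class SimilarityMatrix:
    """Similarity scores over region pairs of one label map."""

    labels: np.ndarray            # region ids, sorted
    s_ks1: np.ndarray             # texture-map similarity, dense symmetric
    s_ks2: np.ndarray             # original-image similarity
    s_ks: np.ndarray              # combined
    adjacency: np.ndarray         # bool, which pairs are spatially adjacent
    index: dict = field(default_factory=dict)  # label -> row


def combine_similarity(s_ks1, s_ks2):
    """S_ks = S_ks2 * exp(S_ks1 - 1): original image dominates."""
    return s_ks2 * np.exp(s_ks1 - 1.0)


def _region_samples(values: np.ndarray, labels: np.ndarray, rng) -> dict:
    order = np.argsort(labels.ravel(), kind="stable")
    flat = values.ravel()[order]
    lab = labels.ravel()[order]
    uniq, starts = np.unique(lab, return_index=True)
    out = {}
    for i, l in enumerate(uniq):
        stop = starts[i + 1] if i + 1 < len(starts) else lab.size
        v = flat[starts[i]:stop]
        if v.size > MAX_SAMPLES:
            v = rng.choice(v, MAX_SAMPLES, replace=False)
        out[int(l)] = np.sort(v)
    return out


def similarity_matrices(img: np.ndarray, tmap: np.ndarray,
                        labels: np.ndarray, seed: int = 0) -> SimilarityMatrix:
    """KS similarities for every adjacent region pair of ``labels``.

    S_ks1 compares texture-map distributions, S_ks2 original-image
    distributions; non-adjacent pairs and the diagonal are left at 0 and
    excluded from the merge search.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    samp_i = _region_samples(np.asarray(img, float), labels, rng)
    samp_t = _region_samples(np.asarray(tmap, float), labels, rng)
    ids = np.array(sorted(samp_i), dtype=int)
    n = len(ids)
    index = {int(l): i for i, l in enumerate(ids)}
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    adj = np.zeros((n, n), dtype=bool)
    for (la, lb) in _adjacent_pairs(labels):
        i, j = index[int(la)], index[int(lb)]
        v1 = ks_similarity(samp_t[int(la)], samp_t[int(lb)])
        v2 = ks_similarity(samp_i[int(la)], samp_i[int(lb)])
        s1[i, j] = s1[j, i] = v1
        s2[i, j] = s2[j, i] = v2
        adj[i, j] = adj[j, i] = True
    return SimilarityMatrix(
        labels=ids, s_ks1=s1, s_ks2=s2,
        s_ks=np.where(adj, combine_similarity(s1, s2), 0.0),
        adjacency=adj, index=index,
    )


def relabel(labels: np.ndarray) -> np.ndarray:
    """Contiguous labels 1..n preserving region identity order."""
    uniq, inv = np.unique(labels, return_inverse=True)
    return (inv + 1).reshape(labels.shape).astype(np.int32)


def merge_until_stable(img: np.ndarray, tmap: np.ndarray, labels: np.ndarray,
                       eps: float = 1e-6, floor: float = 0.5,
                       seed: int = 0, return_trace: bool = False):
    """Iteratively merge the most similar adjacent region pair.

    Each iteration recomputes similarities involving the newly merged
    region (others are cached), merges the argmax pair of S_ks and
    repeats.  Termination: one region left, all remaining adjacent pairs
    equally similar (max - min <= eps), or no pair reaches ``floor``.
    Ties at the maximum break toward the smallest label pair.  Region
    count strictly decreases every iteration, so at most n-1 merges occur.
    """
    labels = relabel(np.asarray(labels))
    rng = np.random.default_rng(seed)
    img = np.asarray(img, dtype=np.float64)
    tmap = np.asarray(tmap, dtype=np.float64)
    samples_i = _region_samples(img, labels, rng)
    samples_t = _region_samples(tmap, labels, rng)
    # adjacency as dict of sets
    adj: dict[int, set] = {l: set() for l in samples_i}
    for (a, b) in _adjacent_pairs(labels):
        adj[int(a)].add(int(b))
        adj[int(b)].add(int(a))
    cache: dict[tuple, float] = {}

    def score(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in cache:
            s1 = ks_similarity(samples_t[a], samples_t[b])
            s2 = ks_similarity(samples_i[a], samples_i[b])
            cache[key] = float(combine_similarity(s1, s2))
        return cache[key]

    # region pixel membership for the final relabel
    region_of = labels.copy()
    trace = []
    while len(adj) > 1:
        pairs = [(a, b) for a in adj for b in adj[a] if a < b]
        if not pairs:
            break
        scores = np.array([score(a, b) for (a, b) in pairs])
        # deterministic tie-break toward the smallest pair
        best = scores.max()
        tied = [p for p, s in zip(pairs, scores) if s >= best - 1e-15]
        a, b = min(tied)
        if best < floor:
            break
        if len(pairs) > 1 and best - scores.min() <= eps:
            break
        # merge b into a
        merged_i = np.concatenate([samples_i[a], samples_i[b]])
        merged_t = np.concatenate([samples_t[a], samples_t[b]])
        if merged_i.size > MAX_SAMPLES:
            sel = rng.choice(merged_i.size, MAX_SAMPLES, replace=False)
            merged_i = merged_i[sel]
            merged_t_sel = rng.choice(merged_t.size, MAX_SAMPLES, replace=False)
            merged_t = merged_t[merged_t_sel]
        samples_i[a] = np.sort(merged_i)
        samples_t[a] = np.sort(merged_t)
        del samples_i[b], samples_t[b]
        region_of[region_of == b] = a
        neighbours = (adj[a] | adj[b]) - {a, b}
        for n_ in adj[b]:
            adj[n_].discard(b)
        del adj[b]
        for n_ in neighbours:
            adj[n_].add(a)
            adj[a].add(n_)
        adj[a] -= {a, b}
        cache = {k_: v for k_, v in cache.items() if a not in k_ and b not in k_}
        trace.append((a, b, float(best)))
    out = relabel(region_of)
    if return_trace:
        return out, trace
    return out


def select_regions(labels: np.ndarray, picks=None, seeds=None) -> np.ndarray:
    """Binary mask of the union of chosen regions.

    ``picks`` are region labels; ``seeds`` are (row, col) points whose
    containing regions are selected (the two may be combined).  Unknown
    labels or out-of-bounds seeds raise.
    """
    labels = np.asarray(labels)
    chosen = set()
    if picks is not None:
        present = set(np.unique(labels).tolist())
        for p in picks:
            if int(p) not in present:
                raise ValueError(f"label {p} not present in the label map")
            chosen.add(int(p))
    if seeds is not None:
        for (r, c) in seeds:
            r, c = int(r), int(c)
            if not (0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]):
                raise ValueError(f"seed ({r}, {c}) outside the image")
            chosen.add(int(labels[r, c]))
    mask = np.zeros(labels.shape, dtype=bool)
    for l in chosen:
        mask |= labels == l
    return mask
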